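"""Domain types shared by every pipeline stage.

The records mirror what a month-granular claims feed actually carries:
per-person monthly enrollment, diagnoses that may embed a gestational age in
completed weeks, a two-tier hierarchy of delivery-related entries, and drug
dispensing records with ATC code and days of supply.  Codes are opaque
strings; no code dictionary is interpreted.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

from .config import StudyConfig
from .dates import PartialDate, YearMonth

# -- controlled string enums -------------------------------------------------

FEMALE = "female"
MALE = "male"

TIER_SELECTED = "selected"
TIER_OTHER = "other"

CATEGORY_EXTRACT = "extract_formula"
CATEGORY_CRUDE = "crude_drug"

PROV_DISPENSING = "dispensing"
PROV_HOSPITALIZATION = "hospitalization"
PROV_MID_MONTH = "mid_month"

METHOD_SELECTED = "selected_entries"
METHOD_OTHER = "other_entries"
METHOD_FALLBACK = "mid_month_fallback"

WINDOW_PRE = "pre"
WINDOW_PREGNANCY = "pregnancy"
WINDOW_POST = "post"
WINDOWS = (WINDOW_PRE, WINDOW_PREGNANCY, WINDOW_POST)

GA_WEEKS_MAX = 44  # exceeds the 42-week post-term threshold with margin


@dataclass(frozen=True)
class Person:
    person_id: str
    sex: str
    birth_ym: PartialDate
    insurer_id: str
    enrollment_months: frozenset[YearMonth]

    def __post_init__(self) -> None:
        if self.sex not in (FEMALE, MALE):
            raise ValueError(f"sex must be female|male, got {self.sex!r}")
        if not self.enrollment_months:
            raise ValueError("enrollment_months must be non-empty")

    @property
    def first_enrollment_month(self) -> YearMonth:
        return min(self.enrollment_months)


@dataclass(frozen=True)
class MotherInfantLink:
    mother_id: str
    infant_id: str
    infant_birth_ym: PartialDate

    def __post_init__(self) -> None:
        if self.infant_birth_ym.is_full:
            # infant day of birth is withheld in the source to avoid re-identification
            raise ValueError("infant_birth_ym must be month-granular")


@dataclass(frozen=True)
class DiagnosisRecord:
    person_id: str
    date: PartialDate
    code: str
    gestational_age_weeks: int | None = None
    is_suspected: bool = False
    is_main: bool = False

    def __post_init__(self) -> None:
        w = self.gestational_age_weeks
        if w is not None and not 0 <= w <= GA_WEEKS_MAX:
            raise ValueError(f"gestational_age_weeks out of [0, {GA_WEEKS_MAX}]: {w}")


@dataclass(frozen=True)
class DeliveryEntry:
    person_id: str
    date: PartialDate
    tier: str
    code: str

    def __post_init__(self) -> None:
        if self.tier not in (TIER_SELECTED, TIER_OTHER):
            raise ValueError(f"tier must be selected|other, got {self.tier!r}")


@dataclass(frozen=True)
class DrugRecord:
    person_id: str
    atc_code: str
    drug_code: str
    formula_name: str
    claim_ym: PartialDate
    days_supply: int
    category: str
    dispensing_date: PartialDate | None = None
    hospitalization_date: PartialDate | None = None

    def __post_init__(self) -> None:
        if self.days_supply < 1:
            raise ValueError(f"days_supply must be >= 1, got {self.days_supply}")
        if self.category not in (CATEGORY_EXTRACT, CATEGORY_CRUDE):
            raise ValueError(f"unknown drug category {self.category!r}")


@dataclass
class ClaimsBundle:
    """The validated in-memory form of one claims extract."""

    persons: dict[str, Person]
    links: list[MotherInfantLink]
    diagnoses: list[DiagnosisRecord]
    delivery_entries: list[DeliveryEntry]
    drugs: list[DrugRecord]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ClaimsBundle):
            return NotImplemented
        return (self.persons == other.persons and self.links == other.links
                and self.diagnoses == other.diagnoses
                and self.delivery_entries == other.delivery_entries
                and self.drugs == other.drugs)


# -- derived analysis types --------------------------------------------------

@dataclass(frozen=True)
class ResolvedDate:
    """A drug record's event date plus where it came from."""

    date: dt.date
    provenance: str  # dispensing | hospitalization | mid_month


def resolve_event_date(record: DrugRecord, config: StudyConfig) -> ResolvedDate:
    """Pick the event date of a drug record by source preference.

    The dispensing date is preferred; failing that the hospitalization date;
    failing both, the claim's year-month with the configured fallback day
    (the 15th by default) assigned.
    """
    if record.dispensing_date is not None and record.dispensing_date.is_full:
        return ResolvedDate(record.dispensing_date.to_date(), PROV_DISPENSING)
    if record.hospitalization_date is not None and record.hospitalization_date.is_full:
        return ResolvedDate(record.hospitalization_date.to_date(), PROV_HOSPITALIZATION)
    y, m = record.claim_ym.ym()
    return ResolvedDate(dt.date(y, m, config.fallback_day_of_month), PROV_MID_MONTH)


@dataclass(frozen=True)
class PregnancyEpisode:
    """One linked mother's estimated pregnancy, with estimation provenance.

    ``onset_raw_date`` is the onset implied by the gestational-age
    subtraction before the post-term cap is applied; when ``onset_capped``
    is set, ``onset_date`` equals ``delivery_date`` minus the cap.
    """

    mother_id: str
    onset_date: dt.date
    delivery_date: dt.date
    delivery_method: str
    onset_capped: bool
    onset_raw_date: dt.date
    ga_weeks_used: int | None = None
    ga_diagnosis_date: dt.date | None = None
    delivery_codes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.onset_date < self.delivery_date:
            raise ValueError("onset_date must precede delivery_date")

    @property
    def gestation_days(self) -> int:
        return (self.delivery_date - self.onset_date).days


@dataclass(frozen=True)
class PrescriptionEvent:
    """A drug record resolved to an exposure interval [start_date, end_date]."""

    person_id: str
    formula_name: str
    category: str
    start_date: dt.date
    end_date: dt.date
    date_provenance: str

    def __post_init__(self) -> None:
        if self.end_date < self.start_date:
            raise ValueError("end_date must be >= start_date")


@dataclass(frozen=True)
class WindowAssignment:
    """The set of exposure windows one person's formula was dispensed in."""

    person_id: str
    formula_name: str
    category: str
    windows: frozenset[str]

    def __post_init__(self) -> None:
        bad = self.windows - set(WINDOWS)
        if bad:
            raise ValueError(f"unknown windows: {sorted(bad)}")
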