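"""Synthetic linked mother-infant claims with known ground truth.

The generator emulates the observation process of a month-granular Japanese
claims feed: a true pregnancy (gestation drawn from a truncated normal,
mean 270.1 days, SD 13.5) is observed only through gestational-age-coded
antenatal diagnoses (GA recorded in completed weeks), a two-tier set of
delivery-related entries dated on the true delivery day, monthly enrollment
spans, and drug dispensing records under ATC V03AX with days of supply.
Every draw is reproducible: each mother consumes her own substream derived
from ``(seed, mother index)``, so output is invariant to generation order.

:func:`degrade_dates` applies the missingness layer separately — blanking
dispensing/hospitalization dates to the configured provenance mix and
optionally removing delivery entries — so tests can compare clean and
degraded observations of the same truth.
"""
from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import StudyConfig
from .dates import PartialDate, add_months, month_range, months_spanned
from .model import (
    CATEGORY_CRUDE,
    CATEGORY_EXTRACT,
    FEMALE,
    MALE,
    TIER_OTHER,
    TIER_SELECTED,
    WINDOW_POST,
    WINDOW_PRE,
    WINDOW_PREGNANCY,
    WINDOWS,
    ClaimsBundle,
    DeliveryEntry,
    DiagnosisRecord,
    DrugRecord,
    MotherInfantLink,
    Person,
)

GA_DIAGNOSIS_CODE = "dx-ga"
OTHER_DIAGNOSIS_CODE = "dx-other"
SELECTED_DELIVERY_CODE = "delivery-selected-proc"
OTHER_DELIVERY_CODE = "delivery-other-entry"

INELIGIBLE_MODES = ("late_infant_enrollment", "pre_birth_gap", "window_gap", "undatable")


@dataclass(frozen=True)
class FormulaSpec:
    """One catalog entry: per-window prescription probabilities for a formula."""

    name: str
    p_pre: float
    p_pregnancy: float
    p_post: float
    category: str = CATEGORY_EXTRACT
    days_supply_choices: tuple[int, ...] = (5, 7, 14, 21, 28)

    @property
    def window_probs(self) -> dict[str, float]:
        return {WINDOW_PRE: self.p_pre, WINDOW_PREGNANCY: self.p_pregnancy,
                WINDOW_POST: self.p_post}


def _default_catalog() -> list[FormulaSpec]:
    # per-window probabilities anchored to observed distinct-person prevalences
    crude = {"category": CATEGORY_CRUDE}
    return [
        FormulaSpec("kakkonto", 0.020, 0.075, 0.077),
        FormulaSpec("shoseiryuto", 0.015, 0.107, 0.041),
        FormulaSpec("tokishakuyakusan", 0.023, 0.080, 0.009),
        FormulaSpec("bakumondoto", 0.012, 0.060, 0.022),
        FormulaSpec("saireito", 0.004, 0.029, 0.026),
        FormulaSpec("goreisan", 0.007, 0.015, 0.012),
        FormulaSpec("maobushisaishinto", 0.006, 0.005, 0.008),
        FormulaSpec("unkeito", 0.007, 0.004, 0.0001),
        FormulaSpec("keishibukuryogan", 0.004, 0.003, 0.002),
        FormulaSpec("mashiningan", 0.0005, 0.004, 0.002),
        FormulaSpec("poria sclerotium", 0.0008, 0.0012, 0.0005, **crude),
        FormulaSpec("glycyrrhiza root", 0.0009, 0.0011, 0.0006, **crude),
        FormulaSpec("peony root", 0.0010, 0.0011, 0.0003, **crude),
    ]


@dataclass
class SimParams:
    """Generation parameters; defaults reproduce the study conditions."""

    n_mothers: int = 1000
    seed: int = 0
    gestation_mean_days: float = 270.1
    gestation_sd_days: float = 13.5
    gestation_min_days: int = 150
    gestation_max_days: int = 310
    age_mean_years: float = 32.3
    age_sd_years: float = 4.5
    p_ga_diagnosis_at_delivery: float = 0.9
    p_selected_delivery_entry: float = 0.371
    p_other_delivery_entry: float = 0.235
    p_dispensing_date_present: float = 0.864
    p_hospitalization_date_present: float = 0.014
    p_remove_delivery_entries: float = 0.0
    p_ineligible: float = 0.15
    p_non_kampo_drug: float = 0.4
    # antenatal schedule: 4-weekly from week 8, 2-weekly from week 24
    visit_start_week: int = 8
    visit_switch_week: int = 24
    visit_interval_early_weeks: int = 4
    visit_interval_late_weeks: int = 2
    enrollment_margin_months: int = 2
    delivery_period_start: dt.date = dt.date(2008, 1, 1)
    delivery_period_end: dt.date = dt.date(2015, 6, 30)
    formula_catalog: list[FormulaSpec] = field(default_factory=_default_catalog)

    def __post_init__(self) -> None:
        if self.n_mothers < 1:
            raise ValueError("n_mothers must be >= 1")
        if self.gestation_sd_days < 0 or self.age_sd_years < 0:
            raise ValueError("standard deviations must be non-negative")
        for name in ("p_ga_diagnosis_at_delivery", "p_selected_delivery_entry",
                     "p_other_delivery_entry", "p_dispensing_date_present",
                     "p_hospitalization_date_present", "p_remove_delivery_entries",
                     "p_ineligible", "p_non_kampo_drug"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.p_dispensing_date_present + self.p_hospitalization_date_present > 1.0:
            raise ValueError("date-provenance probabilities must sum to <= 1")
        for spec in self.formula_catalog:
            for p in (spec.p_pre, spec.p_pregnancy, spec.p_post):
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"{spec.name}: probabilities must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimParams":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "formula_catalog" in raw:
            raw["formula_catalog"] = [
                FormulaSpec(
                    name=s["name"], p_pre=s["p_pre"], p_pregnancy=s["p_pregnancy"],
                    p_post=s["p_post"], category=s.get("category", CATEGORY_EXTRACT),
                    days_supply_choices=tuple(s.get("days_supply_choices",
                                                    (5, 7, 14, 21, 28))))
                for s in raw["formula_catalog"]]
        for key in ("delivery_period_start", "delivery_period_end"):
            if key in raw:
                raw[key] = dt.date.fromisoformat(str(raw[key]))
        return cls(**raw)


@dataclass(frozen=True)
class TrueEpisode:
    mother_id: str
    onset: dt.date
    delivery: dt.date
    gestation_days: int
    eligible: bool
    ineligible_mode: str | None
    rx: dict[str, frozenset[str]]  # window -> formulas truly prescribed

    def __post_init__(self) -> None:
        assert (self.delivery - self.onset).days == self.gestation_days


@dataclass
class GroundTruth:
    """The generator's truth, kept outside the bundle for recovery testing."""

    episodes: dict[str, TrueEpisode]

    def write_csv(self, path: str | Path) -> None:
        rows = [{
            "mother_id": ep.mother_id,
            "true_onset": ep.onset.isoformat(),
            "true_delivery": ep.delivery.isoformat(),
            "gestation_days": ep.gestation_days,
            "eligible": str(ep.eligible).lower(),
            "ineligible_mode": ep.ineligible_mode or "",
            "pre_formulas": ";".join(sorted(ep.rx[WINDOW_PRE])),
            "pregnancy_formulas": ";".join(sorted(ep.rx[WINDOW_PREGNANCY])),
            "post_formulas": ";".join(sorted(ep.rx[WINDOW_POST])),
        } for ep in self.episodes.values()]
        pd.DataFrame(rows).to_csv(path, index=False, lineterminator="\n")

    @classmethod
    def read_csv(cls, path: str | Path) -> "GroundTruth":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        episodes = {}
        for r in df.itertuples(index=False):
            rx = {w: frozenset(x for x in getattr(r, f"{name}_formulas").split(";") if x)
                  for w, name in ((WINDOW_PRE, "pre"), (WINDOW_PREGNANCY, "pregnancy"),
                                  (WINDOW_POST, "post"))}
            episodes[r.mother_id] = TrueEpisode(
                r.mother_id, dt.date.fromisoformat(r.true_onset),
                dt.date.fromisoformat(r.true_delivery), int(r.gestation_days),
                r.eligible == "true", r.ineligible_mode or None, rx)
        return cls(episodes)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float) -> float:
    if sd == 0:
        return float(min(max(mean, lo), hi))
    while True:
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)


def _uniform_date(rng: np.random.Generator, lo: dt.date, hi: dt.date) -> dt.date:
    return lo + dt.timedelta(days=int(rng.integers(0, (hi - lo).days + 1)))


def simulate_bundle(
    params: SimParams, config: StudyConfig | None = None
) -> tuple[ClaimsBundle, GroundTruth]:
    """Draw a fully observed bundle plus its ground truth.

    The emitted bundle carries complete day-level dates everywhere; apply
    :func:`degrade_dates` afterwards to model missingness.
    """
    config = config or StudyConfig()
    study_months = set(month_range(config.study_start_ym.ym(), config.study_end_ym.ym()))
    persons: dict[str, Person] = {}
    links: list[MotherInfantLink] = []
    diagnoses: list[DiagnosisRecord] = []
    delivery_entries: list[DeliveryEntry] = []
    drugs: list[DrugRecord] = []
    truth: dict[str, TrueEpisode] = {}
    day = dt.timedelta(days=1)

    for i in range(params.n_mothers):
        rng = np.random.default_rng([params.seed, i])
        mother_id, infant_id = f"m{i:05d}", f"i{i:05d}"

        gestation = int(round(_truncated_normal(
            rng, params.gestation_mean_days, params.gestation_sd_days,
            params.gestation_min_days, params.gestation_max_days)))
        delivery = _uniform_date(rng, params.delivery_period_start,
                                 params.delivery_period_end)
        onset = delivery - dt.timedelta(days=gestation)
        birth_ym_infant = (delivery.year, delivery.month)

        age = _truncated_normal(rng, params.age_mean_years, params.age_sd_years, 18, 45)
        mother_birth = delivery - dt.timedelta(days=int(round(age * 365.25)))

        ineligible_mode: str | None = None
        if rng.random() < params.p_ineligible:
            ineligible_mode = INELIGIBLE_MODES[int(rng.integers(len(INELIGIBLE_MODES)))]

        # antenatal visits carrying GA in completed weeks
        visit_days = list(range(params.visit_start_week * 7,
                                min(params.visit_switch_week * 7, gestation), 7 * params.visit_interval_early_weeks))
        visit_days += list(range(params.visit_switch_week * 7, gestation,
                                 7 * params.visit_interval_late_weeks))
        ga_visit_days = [d for d in visit_days if d < gestation]
        if rng.random() < params.p_ga_diagnosis_at_delivery:
            ga_visit_days.append(gestation)
        for d in ga_visit_days:
            visit_date = onset + dt.timedelta(days=d)
            ga_weeks = None if ineligible_mode == "undatable" else d // 7
            code = OTHER_DIAGNOSIS_CODE if ga_weeks is None else GA_DIAGNOSIS_CODE
            diagnoses.append(DiagnosisRecord(
                mother_id, PartialDate.from_date(visit_date), code, ga_weeks,
                is_suspected=False, is_main=True))
        for _ in range(int(rng.integers(0, 3))):  # incidental non-GA diagnoses
            d = _uniform_date(rng, onset - dt.timedelta(days=config.pre_window_days),
                              delivery + dt.timedelta(days=config.post_window_days))
            diagnoses.append(DiagnosisRecord(
                mother_id, PartialDate.from_date(d), OTHER_DIAGNOSIS_CODE, None,
                is_suspected=bool(rng.random() < 0.2), is_main=False))

        if rng.random() < params.p_selected_delivery_entry:
            delivery_entries.append(DeliveryEntry(
                mother_id, PartialDate.from_date(delivery), TIER_SELECTED,
                SELECTED_DELIVERY_CODE))
        if rng.random() < params.p_other_delivery_entry:
            delivery_entries.append(DeliveryEntry(
                mother_id, PartialDate.from_date(delivery), TIER_OTHER,
                OTHER_DELIVERY_CODE))

        # drug dispensing: per formula, per window, supply interval kept inside
        # the true window so the truth label is exact
        windows = {
            WINDOW_PRE: (onset - dt.timedelta(days=config.pre_window_days), onset - day),
            WINDOW_PREGNANCY: (onset, delivery),
            WINDOW_POST: (delivery + day,
                          delivery + dt.timedelta(days=config.post_window_days)),
        }
        rx: dict[str, set[str]] = {w: set() for w in WINDOWS}
        for spec in params.formula_catalog:
            for w, p in spec.window_probs.items():
                if p <= 0 or rng.random() >= p:
                    continue
                rx[w].add(spec.name)
                n_rx = 1 + int(rng.random() < 0.3)
                for _ in range(n_rx):
                    ds = int(rng.choice(spec.days_supply_choices))
                    lo, hi = windows[w]
                    hi_start = max(lo, hi - dt.timedelta(days=ds - 1))
                    start = _uniform_date(rng, lo, hi_start)
                    drugs.append(DrugRecord(
                        mother_id, "V03AX", f"kampo-{spec.name.replace(' ', '-')}",
                        spec.name, PartialDate(start.year, start.month), ds,
                        spec.category, dispensing_date=PartialDate.from_date(start)))
        if rng.random() < params.p_non_kampo_drug:
            start = _uniform_date(rng, windows[WINDOW_PRE][0], windows[WINDOW_POST][1])
            drugs.append(DrugRecord(
                mother_id, "N02BE", "analgesic-01", "acetaminophen",
                PartialDate(start.year, start.month), 7, CATEGORY_EXTRACT,
                dispensing_date=PartialDate.from_date(start)))

        # enrollment spans: eligible mothers cover the pre-birth months and the
        # full exposure span with margin; ineligible ones get targeted defects
        first_needed = min(
            months_spanned(windows[WINDOW_PRE][0], windows[WINDOW_PRE][0])[0],
            add_months(birth_ym_infant, -config.pre_birth_enrollment_months))
        last_needed = months_spanned(windows[WINDOW_POST][1], windows[WINDOW_POST][1])[0]
        months = set(month_range(add_months(first_needed, -params.enrollment_margin_months),
                                 add_months(last_needed, params.enrollment_margin_months)))
        if ineligible_mode == "pre_birth_gap":
            gap = add_months(birth_ym_infant,
                             -int(rng.integers(1, config.pre_birth_enrollment_months + 1)))
            months.discard(gap)
        elif ineligible_mode == "window_gap":
            mid = onset - dt.timedelta(days=90)
            months.discard((mid.year, mid.month))
        months &= study_months
        persons[mother_id] = Person(
            mother_id, FEMALE, PartialDate(mother_birth.year, mother_birth.month),
            "ins-01", frozenset(months))

        infant_start = birth_ym_infant
        if ineligible_mode == "late_infant_enrollment":
            infant_start = add_months(birth_ym_infant, 1)
        infant_months = frozenset(
            set(month_range(infant_start, add_months(infant_start, 3))) & study_months)
        persons[infant_id] = Person(
            infant_id, MALE if rng.random() < 0.5 else FEMALE,
            PartialDate(*birth_ym_infant), "ins-01", infant_months)

        links.append(MotherInfantLink(mother_id, infant_id,
                                      PartialDate(*birth_ym_infant)))
        truth[mother_id] = TrueEpisode(
            mother_id, onset, delivery, gestation,
            eligible=ineligible_mode is None, ineligible_mode=ineligible_mode,
            rx={w: frozenset(s) for w, s in rx.items()})

    bundle = ClaimsBundle(persons, links, diagnoses, delivery_entries, drugs)
    return bundle, GroundTruth(truth)


def degrade_dates(bundle: ClaimsBundle, params: SimParams) -> ClaimsBundle:
    """Apply the date-missingness layer to a fully observed bundle.

    Each drug record keeps its dispensing date with probability
    ``p_dispensing_date_present``, is switched to a hospitalization date with
    probability ``p_hospitalization_date_present``, and otherwise loses both
    (forcing the mid-month fallback downstream; the claim year-month always
    survives).  Delivery entries are removed for a
    ``p_remove_delivery_entries`` fraction of mothers.
    """
    rng = np.random.default_rng([params.seed, 1_000_003])
    drugs = []
    for rec in bundle.drugs:
        if rec.dispensing_date is None:
            drugs.append(rec)
            continue
        u = rng.random()
        if u < params.p_dispensing_date_present:
            drugs.append(rec)
        elif u < params.p_dispensing_date_present + params.p_hospitalization_date_present:
            drugs.append(dataclasses.replace(
                rec, hospitalization_date=rec.dispensing_date, dispensing_date=None))
        else:
            drugs.append(dataclasses.replace(
                rec, dispensing_date=None, hospitalization_date=None))
    mothers_with_entries = sorted({e.person_id for e in bundle.delivery_entries})
    removed = {m for m in mothers_with_entries
               if rng.random() < params.p_remove_delivery_entries}
    entries = [e for e in bundle.delivery_entries if e.person_id not in removed]
    return ClaimsBundle(dict(bundle.persons), list(bundle.links),
                        list(bundle.diagnoses), entries, drugs)
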