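"""Estimation of pregnancy onset and delivery dates from coded claims.

Delivery is anchored on delivery-related entries dated within the infant's
birth month: preferred (tier ``selected``) diagnoses/surgical procedures are
consulted first and their earliest date taken; only if none exist is the
earliest date among any other delivery-related entry used; with neither, the
15th of the birth month stands in (uninsured normal deliveries leave no
claims trace).

Onset is the date of a gestational-age-coded diagnosis minus the recorded
completed weeks; when several visits carry a GA, the longest GA wins because
the estimate recorded nearest delivery is clinically the most accurate.
Estimated gestations beyond the post-term threshold (294 days) are reset to
exactly the cap by moving the onset to ``delivery - cap``.
"""
from __future__ import annotations

import datetime as dt
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .config import StudyConfig
from .dates import PartialDate, mid_month
from .model import (
    METHOD_FALLBACK,
    METHOD_OTHER,
    METHOD_SELECTED,
    TIER_OTHER,
    TIER_SELECTED,
    ClaimsBundle,
    DeliveryEntry,
    DiagnosisRecord,
    MotherInfantLink,
    PregnancyEpisode,
)


class UndatableEpisodeError(ValueError):
    """The mother's pregnancy cannot be dated from her claims."""


@dataclass(frozen=True)
class DeliveryEstimate:
    date: dt.date
    method: str  # selected_entries | other_entries | mid_month_fallback
    codes: tuple[str, ...]  # all entry codes carrying the chosen date


@dataclass(frozen=True)
class OnsetEstimate:
    date: dt.date
    raw_date: dt.date  # before the post-term cap
    capped: bool
    ga_weeks: int
    ga_diagnosis_date: dt.date


def estimate_delivery(
    entries: list[DeliveryEntry], infant_birth_ym: PartialDate, config: StudyConfig
) -> DeliveryEstimate:
    """Two-tier earliest-date rule restricted to the infant's birth month."""
    in_month = [e for e in entries
                if e.date.is_full and e.date.ym() == infant_birth_ym.ym()]
    for tier, method in ((TIER_SELECTED, METHOD_SELECTED), (TIER_OTHER, METHOD_OTHER)):
        dates = [e.date.to_date() for e in in_month if e.tier == tier]
        if dates:
            earliest = min(dates)
            codes = tuple(sorted(e.code for e in in_month
                                 if e.tier == tier and e.date.to_date() == earliest))
            return DeliveryEstimate(earliest, method, codes)
    return DeliveryEstimate(
        mid_month(infant_birth_ym.ym(), config.fallback_day_of_month), METHOD_FALLBACK, ())


def estimate_onset(
    diagnoses: list[DiagnosisRecord], delivery_date: dt.date, config: StudyConfig
) -> OnsetEstimate:
    """Longest-GA subtraction with the post-term cap.

    Only day-dated diagnoses carrying a gestational age are usable (the
    subtraction is day-granular).  Ties on the maximal GA go to the latest
    diagnosis date.  Raises :class:`UndatableEpisodeError` when no usable
    diagnosis exists or the implied onset does not precede delivery.
    """
    usable = [d for d in diagnoses
              if d.gestational_age_weeks is not None and d.date.is_full]
    if not usable:
        raise UndatableEpisodeError("no day-dated diagnosis carrying a gestational age")
    best = max(usable, key=lambda d: (d.gestational_age_weeks, d.date.to_date()))
    raw = best.date.to_date() - dt.timedelta(days=7 * best.gestational_age_weeks)
    if raw >= delivery_date:
        raise UndatableEpisodeError("implied onset does not precede the delivery date")
    if (delivery_date - raw).days > config.post_term_cap_days:
        capped = delivery_date - dt.timedelta(days=config.post_term_cap_days)
        return OnsetEstimate(capped, raw, True,
                             best.gestational_age_weeks, best.date.to_date())
    return OnsetEstimate(raw, raw, False,
                         best.gestational_age_weeks, best.date.to_date())


def primary_links(bundle: ClaimsBundle) -> tuple[dict[str, MotherInfantLink], int]:
    """One link per mother (earliest infant birth month; infant_id tie-break).

    Returns the mapping and the number of additional links dropped.
    """
    by_mother: dict[str, list[MotherInfantLink]] = defaultdict(list)
    for link in bundle.links:
        by_mother[link.mother_id].append(link)
    chosen: dict[str, MotherInfantLink] = {}
    dropped = 0
    for mother_id, links in by_mother.items():
        links = sorted(links, key=lambda l: (l.infant_birth_ym.ym(), l.infant_id))
        chosen[mother_id] = links[0]
        dropped += len(links) - 1
    return chosen, dropped


def estimate_episodes(
    bundle: ClaimsBundle, config: StudyConfig
) -> dict[str, PregnancyEpisode | None]:
    """Date every linked mother's pregnancy; ``None`` marks undatable mothers."""
    links, _ = primary_links(bundle)
    diag_by: dict[str, list[DiagnosisRecord]] = defaultdict(list)
    for d in bundle.diagnoses:
        diag_by[d.person_id].append(d)
    entries_by: dict[str, list[DeliveryEntry]] = defaultdict(list)
    for e in bundle.delivery_entries:
        entries_by[e.person_id].append(e)

    episodes: dict[str, PregnancyEpisode | None] = {}
    for mother_id, link in links.items():
        delivery = estimate_delivery(entries_by.get(mother_id, []),
                                     link.infant_birth_ym, config)
        try:
            onset = estimate_onset(diag_by.get(mother_id, []), delivery.date, config)
        except UndatableEpisodeError:
            episodes[mother_id] = None
            continue
        episodes[mother_id] = PregnancyEpisode(
            mother_id=mother_id,
            onset_date=onset.date,
            delivery_date=delivery.date,
            delivery_method=delivery.method,
            onset_capped=onset.capped,
            onset_raw_date=onset.raw_date,
            ga_weeks_used=onset.ga_weeks,
            ga_diagnosis_date=onset.ga_diagnosis_date,
            delivery_codes=delivery.codes,
        )
    return episodes


# -- episode table serialization --------------------------------------------

EPISODE_COLUMNS = ["mother_id", "onset_date", "delivery_date", "delivery_method",
                   "onset_capped", "onset_raw_date", "ga_weeks_used"]


def write_episodes_csv(episodes: dict[str, PregnancyEpisode | None],
                       path: str | Path) -> None:
    rows = []
    for mother_id, ep in episodes.items():
        if ep is None:
            rows.append({"mother_id": mother_id, "onset_date": "", "delivery_date": "",
                         "delivery_method": "", "onset_capped": "", "onset_raw_date": "",
                         "ga_weeks_used": ""})
        else:
            rows.append({"mother_id": mother_id,
                         "onset_date": ep.onset_date.isoformat(),
                         "delivery_date": ep.delivery_date.isoformat(),
                         "delivery_method": ep.delivery_method,
                         "onset_capped": str(ep.onset_capped).lower(),
                         "onset_raw_date": ep.onset_raw_date.isoformat(),
                         "ga_weeks_used":
                             "" if ep.ga_weeks_used is None else ep.ga_weeks_used})
    pd.DataFrame(rows, columns=EPISODE_COLUMNS).to_csv(path, index=False,
                                                       lineterminator="\n")


def read_episodes_csv(path: str | Path) -> dict[str, PregnancyEpisode | None]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    episodes: dict[str, PregnancyEpisode | None] = {}
    for r in df.itertuples(index=False):
        if not r.onset_date:
            episodes[r.mother_id] = None
            continue
        episodes[r.mother_id] = PregnancyEpisode(
            mother_id=r.mother_id,
            onset_date=dt.date.fromisoformat(r.onset_date),
            delivery_date=dt.date.fromisoformat(r.delivery_date),
            delivery_method=r.delivery_method,
            onset_capped=r.onset_capped == "true",
            onset_raw_date=dt.date.fromisoformat(r.onset_raw_date),
            ga_weeks_used=int(r.ga_weeks_used) if r.ga_weeks_used else None,
        )
    return episodes
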