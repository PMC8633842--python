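"""Cohort selection: the four eligibility criteria and the attrition report.

A mother enters the analysis set only if (1) her linked infant's first
enrollment month equals the infant's birth month, (2) she was continuously
enrolled for the 11 calendar months preceding the birth month, (3) her
pregnancy could be dated, and (4) she was enrolled in every calendar month
intersecting the span from 180 days before onset to 180 days after delivery.
Enrollment is evaluated at calendar-month granularity — the database's
native unit — so a window partially covering a month requires that month.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .config import StudyConfig
from .dates import add_months, month_range, months_spanned
from .model import ClaimsBundle, PregnancyEpisode
from .dating import primary_links


@dataclass
class AttritionReport:
    """Ordered step-by-step cohort counts, mirroring a selection flowchart."""

    steps: list[tuple[str, int]]
    cohort_ids: list[str]
    n_extra_links_dropped: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["criterion", "n_remaining"])


def select_cohort(
    bundle: ClaimsBundle,
    episodes: dict[str, PregnancyEpisode | None],
    config: StudyConfig,
) -> tuple[list[str], AttritionReport]:
    """Apply the four criteria in order and report attrition after each."""
    links, dropped = primary_links(bundle)
    remaining = sorted(links)
    steps = [("linked mother-infant pairs", len(remaining))]

    def keep(label: str, pred) -> None:
        nonlocal remaining
        remaining = [m for m in remaining if pred(m)]
        steps.append((label, len(remaining)))

    def infant_enrolled_from_birth(mother_id: str) -> bool:
        link = links[mother_id]
        infant = bundle.persons.get(link.infant_id)
        return (infant is not None
                and infant.first_enrollment_month == link.infant_birth_ym.ym())

    keep("infant enrolled from birth month", infant_enrolled_from_birth)

    def pre_birth_enrollment(mother_id: str) -> bool:
        mother = bundle.persons.get(mother_id)
        if mother is None:
            return False
        birth = links[mother_id].infant_birth_ym.ym()
        needed = month_range(add_months(birth, -config.pre_birth_enrollment_months),
                             add_months(birth, -1))
        return all(m in mother.enrollment_months for m in needed)

    keep(f"enrolled {config.pre_birth_enrollment_months} months before birth",
         pre_birth_enrollment)

    keep("pregnancy datable", lambda m: episodes.get(m) is not None)

    def window_enrollment(mother_id: str) -> bool:
        mother = bundle.persons[mother_id]
        ep = episodes[mother_id]
        start = ep.onset_date - dt.timedelta(days=config.pre_window_days)
        end = ep.delivery_date + dt.timedelta(days=config.post_window_days)
        return all(m in mother.enrollment_months for m in months_spanned(start, end))

    keep("enrolled across the full exposure span", window_enrollment)

    return remaining, AttritionReport(steps, remaining, dropped)


def write_cohort_csv(cohort_ids: list[str], path: str | Path) -> None:
    pd.DataFrame({"mother_id": cohort_ids}).to_csv(path, index=False,
                                                   lineterminator="\n")


def read_cohort_csv(path: str | Path) -> list[str]:
    return pd.read_csv(path, dtype=str)["mother_id"].tolist()
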