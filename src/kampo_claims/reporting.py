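"""Frequency tables, threshold filtering, cautionary flags, descriptives.

Percentages are distinct-person counts over the cohort denominator, rounded
half-up to one decimal; the reporting cut-offs (0.4% for extract formulas,
0.1% for crude decoction drugs) are applied to the *rounded* total
percentage, so a raw 0.4007% survives a 0.4% threshold.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .config import StudyConfig
from .dates import mid_month
from .ingredients import IngredientMap
from .model import (
    CATEGORY_CRUDE,
    CATEGORY_EXTRACT,
    ClaimsBundle,
    PregnancyEpisode,
    PrescriptionEvent,
)


def percent(n: int, denominator: int, decimals: int = 1) -> float:
    """100·n/denominator rounded half-up to ``decimals`` places."""
    if denominator <= 0:
        raise ValueError("denominator must be >= 1")
    q = Decimal(1).scaleb(-decimals)
    return float((Decimal(n) * 100 / Decimal(denominator))
                 .quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class FrequencyTable:
    """Formula × window counts and percentages over a cohort denominator.

    ``table`` holds every formula (sorted by total count descending, name
    ascending on ties); ``filtered`` keeps only rows whose rounded total
    percentage reaches the category's reporting threshold.
    """

    table: pd.DataFrame
    filtered: pd.DataFrame
    denominator: int


_PCT_OF = {"total_pct": "total_n", "pre_pct": "pre_n",
           "pregnancy_pct": "pregnancy_n", "post_pct": "post_n"}


def tabulate(counts: pd.DataFrame, denominator: int, config: StudyConfig) -> FrequencyTable:
    """Attach percentages, sort, and threshold-filter a dedup-count table."""
    if denominator <= 0:
        raise ValueError("denominator must be >= 1")
    df = counts.copy()
    for n_col in ("total_n", "pre_n", "pregnancy_n", "post_n"):
        if (df[n_col] > denominator).any() or (df[n_col] < 0).any():
            raise ValueError(f"{n_col} outside [0, denominator]")
    for pct_col, n_col in _PCT_OF.items():
        df[pct_col] = [percent(n, denominator) for n in df[n_col]]
    df = df.sort_values(["total_n", "formula_name"], ascending=[False, True],
                        kind="stable").reset_index(drop=True)
    thresholds = {CATEGORY_EXTRACT: config.formula_report_threshold_pct,
                  CATEGORY_CRUDE: config.crude_report_threshold_pct}
    keep = [row.total_pct >= thresholds[row.category] - 1e-9
            for row in df.itertuples(index=False)]
    return FrequencyTable(df, df[keep].reset_index(drop=True), denominator)


def flag_cautionary(
    freq: FrequencyTable, ingredient_map: IngredientMap
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Annotate a frequency table with cautionary-ingredient flags.

    Returns the annotated full table and a secondary table restricted to
    flagged formulas with their pregnancy-window counts.  A formula missing
    from the map is marked as having unknown ingredients — never silently
    unflagged.
    """
    annotated = freq.table.copy()
    flag_strs, known = [], []
    for name in annotated["formula_name"]:
        flags = ingredient_map.flags(name)
        known.append(flags is not None)
        flag_strs.append("" if flags is None else ";".join(sorted(flags)))
    annotated["cautionary_ingredients"] = flag_strs
    annotated["ingredients_known"] = known
    flagged = annotated[(annotated["ingredients_known"])
                        & (annotated["cautionary_ingredients"] != "")]
    cautionary = flagged[["formula_name", "category", "cautionary_ingredients",
                          "pregnancy_n", "pregnancy_pct"]].reset_index(drop=True)
    return annotated, cautionary


def _mean_sd(values: list[float]) -> tuple[float, float]:
    if not values:
        raise ValueError("empty sample")
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    return mean, sd


def describe_cohort(
    episodes: dict[str, PregnancyEpisode | None],
    cohort_ids: list[str],
    bundle: ClaimsBundle,
    events: list[PrescriptionEvent] | None = None,
) -> dict:
    """Cohort descriptives: age, gestation, cap rate, provenance tallies.

    Maternal age at delivery uses the 15th of the mother's birth month as
    the birthdate proxy (only year-month is recorded) and a 365.25-day year.
    """
    if not cohort_ids:
        raise ValueError("empty cohort")
    eps = [episodes[m] for m in cohort_ids]
    if any(e is None for e in eps):
        raise ValueError("cohort contains an undatable mother")
    gestations = [float(e.gestation_days) for e in eps]
    ages = []
    for e in eps:
        birth = mid_month(bundle.persons[e.mother_id].birth_ym.ym())
        ages.append((e.delivery_date - birth).days / 365.25)
    mean_age, sd_age = _mean_sd(ages)
    mean_g, sd_g = _mean_sd(gestations)
    n_capped = sum(e.onset_capped for e in eps)
    out = {
        "n_cohort": len(cohort_ids),
        "mean_age_years": mean_age,
        "sd_age_years": sd_age,
        "mean_gestation_days": mean_g,
        "sd_gestation_days": sd_g,
        "n_capped": n_capped,
        "capped_fraction": n_capped / len(cohort_ids),
        "delivery_method_counts": dict(Counter(e.delivery_method for e in eps)),
    }
    if events is not None:
        out["date_provenance_counts"] = dict(
            Counter(ev.date_provenance for ev in events))
    return out


def describe_to_frame(descriptives: dict) -> pd.DataFrame:
    """Flatten the descriptives dict to a two-column key/value frame."""
    rows = []
    for key, value in descriptives.items():
        if isinstance(value, dict):
            for sub, v in sorted(value.items()):
                rows.append({"statistic": f"{key}.{sub}", "value": v})
        else:
            rows.append({"statistic": key,
                         "value": round(value, 4) if isinstance(value, float) else value})
    return pd.DataFrame(rows, columns=["statistic", "value"])
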