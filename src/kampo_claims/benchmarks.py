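"""Published reference counts used as benchmark fixtures.

A nationwide Japanese claims analysis of 33,941 linked pregnancies reported
distinct-person prescription counts per exposure window for Kampo extract
formulas (listed at a 0.4% total-frequency cut-off) and for crude decoction
drugs (0.1% cut-off), together with cohort descriptives.  The counts are
embedded here so that the tabulation code path can be validated against
every printed percentage, and so that synthetic-data defaults can be
anchored to realistic prevalences.

Each row is (name, total_n, pre_n, pregnancy_n, post_n); the paired
``*_PCTS`` rows hold the percentages as printed, in the same order
(total, pre, pregnancy, post).
"""
from __future__ import annotations

import pandas as pd

from .model import CATEGORY_CRUDE, CATEGORY_EXTRACT

REFERENCE_DENOMINATOR = 33941

REFERENCE_EXTRACT_COUNTS: list[tuple[str, int, int, int, int]] = [
    ("kakkonto", 5075, 678, 2535, 2605),
    ("shoseiryuto", 4833, 526, 3629, 1379),
    ("tokishakuyakusan", 3162, 781, 2724, 311),
    ("bakumondoto", 2856, 412, 2043, 741),
    ("saireito", 1522, 125, 1000, 873),
    ("goreisan", 994, 228, 500, 422),
    ("shohangekabukuryoto", 612, 14, 597, 8),
    ("maoto", 567, 187, 182, 224),
    ("maobushisaishinto", 551, 207, 162, 255),
    ("kikyoto", 539, 129, 239, 239),
    ("kakkontokasenkyusin'i", 528, 155, 245, 196),
    ("hangekobokuto", 480, 82, 366, 74),
    ("daikenchuto", 412, 47, 154, 300),
    ("shakuyakukanzoto", 374, 88, 249, 78),
    ("rikkunshito", 357, 96, 213, 89),
    ("hochuekkito", 280, 110, 86, 130),
    ("unkeito", 271, 244, 129, 4),
    ("shosaikotokakikyosekko", 263, 83, 113, 103),
    ("keishibukuryogan", 234, 129, 85, 80),
    ("keishito", 224, 46, 118, 72),
    ("kamishoyosan", 219, 155, 78, 53),
    ("kyukichoketsuin", 213, 22, 70, 181),
    ("goshuyuto", 201, 36, 151, 39),
    ("hangeshashinto", 190, 53, 97, 48),
    ("saikokeishito", 186, 66, 71, 69),
    ("mashiningan", 186, 17, 147, 59),
    ("choreito", 173, 53, 60, 66),
    ("shishihakuhito", 163, 46, 76, 63),
    ("ninjin'yoeito", 158, 13, 118, 70),
    ("kososan", 155, 25, 94, 45),
    ("makyokansekito", 148, 33, 79, 54),
    ("otsujito", 142, 14, 75, 91),
    ("kikyosekko", 138, 56, 50, 58),
]

REFERENCE_EXTRACT_PCTS: list[tuple[float, float, float, float]] = [
    (15.0, 2.0, 7.5, 7.7),
    (14.2, 1.5, 10.7, 4.1),
    (9.3, 2.3, 8.0, 0.9),
    (8.4, 1.2, 6.0, 2.2),
    (4.5, 0.4, 2.9, 2.6),
    (2.9, 0.7, 1.5, 1.2),
    (1.8, 0.0, 1.8, 0.0),
    (1.7, 0.6, 0.5, 0.7),
    (1.6, 0.6, 0.5, 0.8),
    (1.6, 0.4, 0.7, 0.7),
    (1.6, 0.5, 0.7, 0.6),
    (1.4, 0.2, 1.1, 0.2),
    (1.2, 0.1, 0.5, 0.9),
    (1.1, 0.3, 0.7, 0.2),
    (1.1, 0.3, 0.6, 0.3),
    (0.8, 0.3, 0.3, 0.4),
    (0.8, 0.7, 0.4, 0.0),
    (0.8, 0.2, 0.3, 0.3),
    (0.7, 0.4, 0.3, 0.2),
    (0.7, 0.1, 0.3, 0.2),
    (0.6, 0.5, 0.2, 0.2),
    (0.6, 0.1, 0.2, 0.5),
    (0.6, 0.1, 0.4, 0.1),
    (0.6, 0.2, 0.3, 0.1),
    (0.5, 0.2, 0.2, 0.2),
    (0.5, 0.1, 0.4, 0.2),
    (0.5, 0.2, 0.2, 0.2),
    (0.5, 0.1, 0.2, 0.2),
    (0.5, 0.0, 0.3, 0.2),
    (0.5, 0.1, 0.3, 0.1),
    (0.4, 0.1, 0.2, 0.2),
    (0.4, 0.0, 0.2, 0.3),
    (0.4, 0.2, 0.1, 0.2),
]

REFERENCE_CRUDE_COUNTS: list[tuple[str, int, int, int, int]] = [
    ("poria sclerotium", 61, 28, 42, 16),
    ("glycyrrhiza root", 58, 29, 37, 20),
    ("peony root", 54, 34, 39, 9),
    ("cinnamon bark", 44, 24, 26, 9),
    ("cnidium rhizome", 43, 28, 29, 8),
    ("alisma tuber", 43, 20, 34, 9),
    ("japanese angelica root", 43, 29, 34, 6),
    ("processed aconite root", 40, 25, 27, 5),
    ("atractylodes rhizome", 38, 17, 29, 8),
    ("red ginseng root", 35, 25, 24, 4),
    ("ginger rhizome", 34, 16, 21, 10),
    ("ginseng root", 31, 18, 21, 9),
    ("atractylodes lancea rhizome", 30, 15, 20, 8),
    ("jujube fruit", 29, 11, 19, 10),
    ("bupleurum root", 27, 11, 17, 10),
    ("gentian root", 25, 12, 8, 11),
    ("rhubarb", 25, 11, 14, 5),
    ("pinellia tuber", 23, 11, 16, 5),
    ("rehmannia root", 22, 16, 14, 4),
    ("saffron stigma", 21, 16, 11, 3),
    ("processed ginger rhizome", 20, 12, 11, 7),
    ("scutellaria root", 18, 5, 10, 7),
]

REFERENCE_CRUDE_PCTS: list[tuple[float, float, float, float]] = [
    (0.2, 0.1, 0.1, 0.0),
    (0.2, 0.1, 0.1, 0.1),
    (0.2, 0.1, 0.1, 0.0),
    (0.1, 0.1, 0.1, 0.0),
    (0.1, 0.1, 0.1, 0.0),
    (0.1, 0.1, 0.1, 0.0),
    (0.1, 0.1, 0.1, 0.0),
    (0.1, 0.1, 0.1, 0.0),
    (0.1, 0.1, 0.1, 0.0),
    (0.1, 0.1, 0.1, 0.0),
    (0.1, 0.0, 0.1, 0.0),
    (0.1, 0.1, 0.1, 0.0),
    (0.1, 0.0, 0.1, 0.0),
    (0.1, 0.0, 0.1, 0.0),
    (0.1, 0.0, 0.1, 0.0),
    (0.1, 0.0, 0.0, 0.0),
    (0.1, 0.0, 0.0, 0.0),
    (0.1, 0.0, 0.0, 0.0),
    (0.1, 0.0, 0.0, 0.0),
    (0.1, 0.0, 0.0, 0.0),
    (0.1, 0.0, 0.0, 0.0),
    (0.1, 0.0, 0.0, 0.0),
]

# headline cohort descriptives of the same analysis
REFERENCE_SUMMARY = {
    "n_cohort": 33941,
    "n_delivery_selected": 12604,
    "n_delivery_other": 5014,
    "n_delivery_fallback": 16323,
    "n_capped": 569,
    "n_drug_records": 119521,
    "n_dispensing_dated": 103285,
    "n_hospitalization_dated": 1614,
    "n_mid_month_dated": 14622,
    "mean_age_years": 32.3,
    "sd_age_years": 4.5,
    "mean_gestation_days": 270.1,
    "sd_gestation_days": 13.5,
}


def reference_counts_frame() -> pd.DataFrame:
    """Both benchmark tables in the shape produced by ``dedup_count``."""
    rows = [
        {"formula_name": name, "category": cat, "total_n": t, "pre_n": a,
         "pregnancy_n": b, "post_n": c}
        for cat, table in ((CATEGORY_EXTRACT, REFERENCE_EXTRACT_COUNTS),
                           (CATEGORY_CRUDE, REFERENCE_CRUDE_COUNTS))
        for (name, t, a, b, c) in table
    ]
    return pd.DataFrame(rows, columns=["formula_name", "category", "total_n",
                                       "pre_n", "pregnancy_n", "post_n"])
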