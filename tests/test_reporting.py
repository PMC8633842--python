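"""Percentage arithmetic, threshold filtering, flags, descriptives."""
import datetime as dt
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_bundle

from kampo_claims import (
    IngredientMap,
    PartialDate,
    Person,
    PregnancyEpisode,
    describe_cohort,
    flag_cautionary,
    percent,
    tabulate,
)


def _counts(rows):
    return pd.DataFrame(rows, columns=["formula_name", "category", "total_n",
                                       "pre_n", "pregnancy_n", "post_n"])


@pytest.mark.parametrize("n, expected", [
    (5075, 15.0),   # largest-formula benchmark cell
    (136, 0.4),     # 0.4007 rounds down to the threshold boundary
    (0, 0.0),
])
def test_percent_examples(n, expected):
    assert percent(n, 33941) == expected


@given(st.integers(0, 50000), st.integers(1, 50000))
def test_percent_matches_decimal_oracle(n, d):
    expected = float((Decimal(n) * 100 / Decimal(d))
                     .quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
    assert percent(n, d) == expected


class TestTabulate:
    def test_threshold_applied_to_rounded_total(self, config):
        counts = _counts([("a", "extract_formula", 136, 0, 136, 0),
                          ("b", "extract_formula", 135, 0, 135, 0)])
        freq = tabulate(counts, 33941, config)
        # 136 -> 0.4007 -> 0.4 retained; 135 -> 0.3977 -> 0.4 retained too
        assert freq.filtered["formula_name"].tolist() == ["a", "b"]
        below = tabulate(_counts([("c", "extract_formula", 100, 0, 100, 0)]),
                         33941, config)
        assert below.filtered.empty  # 0.295 -> 0.3 < 0.4

    def test_category_specific_thresholds(self, config):
        counts = _counts([("herb", "crude_drug", 40, 10, 30, 5),
                          ("formula", "extract_formula", 40, 10, 30, 5)])
        freq = tabulate(counts, 33941, config)
        # 40/33941 -> 0.1%: enough for a crude drug, not for an extract
        assert freq.filtered["formula_name"].tolist() == ["herb"]

    def test_sorted_by_total_then_name(self, config):
        counts = _counts([("b", "extract_formula", 200, 0, 200, 0),
                          ("a", "extract_formula", 200, 0, 200, 0),
                          ("c", "extract_formula", 300, 0, 300, 0)])
        freq = tabulate(counts, 1000, config)
        assert freq.table["formula_name"].tolist() == ["c", "a", "b"]

    def test_filter_is_idempotent(self, config):
        counts = _counts([("a", "extract_formula", 500, 100, 300, 200),
                          ("b", "extract_formula", 10, 5, 5, 5)])
        once = tabulate(counts, 33941, config)
        twice = tabulate(once.filtered[counts.columns], 33941, config)
        pd.testing.assert_frame_equal(once.filtered, twice.filtered)

    def test_zero_denominator_rejected(self, config):
        with pytest.raises(ValueError):
            tabulate(_counts([]), 0, config)


class TestCautionaryFlags:
    @pytest.mark.parametrize("formula, expected", [
        ("mashiningan", {"rhubarb"}),
        ("keishibukuryogan", {"peach kernel", "moutan bark"}),
        ("maobushisaishinto", {"processed aconite root"}),
        ("kyukichoketsuin", {"peach kernel", "moutan bark", "safflower"}),
    ])
    def test_known_formula_flags(self, formula, expected):
        assert IngredientMap().flags(formula) == expected

    def test_unknown_formula_flagged_not_silently_passed(self, config):
        counts = _counts([("mystery-formula", "extract_formula", 500, 0, 500, 0),
                          ("mashiningan", "extract_formula", 400, 0, 400, 0)])
        freq = tabulate(counts, 33941, config)
        annotated, cautionary = flag_cautionary(freq, IngredientMap())
        row = annotated.set_index("formula_name").loc["mystery-formula"]
        assert not row.ingredients_known
        assert cautionary["formula_name"].tolist() == ["mashiningan"]
        assert cautionary.iloc[0].cautionary_ingredients == "rhubarb"


def _cohort_of(gestations):
    persons, episodes, ids = [], {}, []
    for i, g in enumerate(gestations):
        mid = f"m{i}"
        delivery = dt.date(2014, 6, 15)
        onset = delivery - dt.timedelta(days=g)
        persons.append(Person(mid, "female", PartialDate(1982, 6), "ins-01",
                              frozenset({(2014, 6)})))
        episodes[mid] = PregnancyEpisode(mid, onset, delivery, "selected_entries",
                                         False, onset)
        ids.append(mid)
    return make_bundle(persons), episodes, ids


class TestDescribeCohort:
    def test_single_member_has_zero_sd(self):
        bundle, episodes, ids = _cohort_of([270])
        desc = describe_cohort(episodes, ids, bundle)
        assert desc["mean_gestation_days"] == 270.0
        assert desc["sd_gestation_days"] == 0.0

    def test_sample_sd_closed_form(self):
        bundle, episodes, ids = _cohort_of([260, 280])
        desc = describe_cohort(episodes, ids, bundle)
        assert desc["mean_gestation_days"] == 270.0
        assert desc["sd_gestation_days"] == pytest.approx(14.142, abs=1e-3)

    def test_age_uses_mid_month_birth_proxy(self):
        bundle, episodes, ids = _cohort_of([270])
        desc = describe_cohort(episodes, ids, bundle)
        # born 1982-06-15, delivered 2014-06-15: exactly 32 years of days
        assert desc["mean_age_years"] == pytest.approx(32.0, abs=0.05)

    def test_capped_fraction(self):
        bundle, episodes, ids = _cohort_of([270, 280])
        episodes = {m: PregnancyEpisode(m, e.onset_date, e.delivery_date,
                                        e.delivery_method, True, e.onset_raw_date)
                    for m, e in episodes.items()}
        desc = describe_cohort(episodes, ids, bundle)
        assert desc["capped_fraction"] == 1.0
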