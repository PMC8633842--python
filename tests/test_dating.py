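"""Onset/delivery estimation: tier precedence, longest-GA rule, cap."""
import datetime as dt

import pytest
from hypothesis import given
from hypothesis import strategies as st

from kampo_claims import (
    METHOD_FALLBACK,
    METHOD_OTHER,
    METHOD_SELECTED,
    DeliveryEntry,
    DiagnosisRecord,
    PartialDate,
    UndatableEpisodeError,
    estimate_delivery,
    estimate_onset,
)


def _entry(iso, tier, code="c"):
    return DeliveryEntry("m1", PartialDate.parse(iso), tier, code)


def _ga(iso, weeks):
    return DiagnosisRecord("m1", PartialDate.parse(iso), "dx-ga", weeks)


BIRTH_MONTH = PartialDate(2014, 6)


class TestDeliveryEstimation:
    def test_selected_tier_beats_earlier_other_tier(self, config):
        est = estimate_delivery([_entry("2014-06-20", "selected"),
                                 _entry("2014-06-05", "other")], BIRTH_MONTH, config)
        assert est.date == dt.date(2014, 6, 20)
        assert est.method == METHOD_SELECTED

    def test_earliest_within_tier(self, config):
        est = estimate_delivery([_entry("2014-06-20", "other"),
                                 _entry("2014-06-05", "other")], BIRTH_MONTH, config)
        assert est.date == dt.date(2014, 6, 5)
        assert est.method == METHOD_OTHER

    def test_entries_outside_birth_month_ignored(self, config):
        est = estimate_delivery([_entry("2014-05-30", "selected")], BIRTH_MONTH, config)
        assert est.date == dt.date(2014, 6, 15)
        assert est.method == METHOD_FALLBACK

    def test_no_entries_falls_back_to_mid_month(self, config):
        est = estimate_delivery([], BIRTH_MONTH, config)
        assert est.date == dt.date(2014, 6, 15)
        assert est.method == METHOD_FALLBACK

    def test_month_granular_entry_unusable(self, config):
        est = estimate_delivery([_entry("2014-06", "selected")], BIRTH_MONTH, config)
        assert est.method == METHOD_FALLBACK

    def test_all_codes_on_chosen_date_recorded(self, config):
        est = estimate_delivery([_entry("2014-06-05", "selected", "a"),
                                 _entry("2014-06-05", "selected", "b"),
                                 _entry("2014-06-09", "selected", "c")],
                                BIRTH_MONTH, config)
        assert est.codes == ("a", "b")


class TestOnsetEstimation:
    def test_week39_subtraction(self, config):
        """A week-39 diagnosis means 273 days are subtracted."""
        est = estimate_onset([_ga("2020-09-25", 39)], dt.date(2020, 9, 25), config)
        assert est.date == dt.date(2020, 9, 25) - dt.timedelta(days=273)
        assert est.date == dt.date(2019, 12, 27)
        assert not est.capped

    def test_longest_ga_wins_regardless_of_date(self, config):
        est = estimate_onset([_ga("2020-03-01", 10), _ga("2020-09-20", 39)],
                             dt.date(2020, 9, 25), config)
        assert est.ga_weeks == 39
        assert est.date == dt.date(2020, 9, 20) - dt.timedelta(days=273)

    def test_tie_on_ga_uses_latest_date(self, config):
        # later recording is the more accurate obstetric estimate
        est = estimate_onset([_ga("2020-09-18", 39), _ga("2020-09-25", 39)],
                             dt.date(2020, 9, 25), config)
        assert est.ga_diagnosis_date == dt.date(2020, 9, 25)

    def test_post_term_cap_anchors_on_delivery(self, config):
        delivery = dt.date(2020, 9, 25)
        diag = delivery - dt.timedelta(days=6)
        est = estimate_onset([_ga(diag.isoformat(), 42)], delivery, config)
        assert est.raw_date == delivery - dt.timedelta(days=300)
        assert est.capped
        assert est.date == delivery - dt.timedelta(days=294)

    def test_zero_ga_is_identity(self, config):
        est = estimate_onset([_ga("2020-02-01", 0)], dt.date(2020, 9, 25), config)
        assert est.date == dt.date(2020, 2, 1)

    def test_month_granular_ga_diagnosis_excluded(self, config):
        with pytest.raises(UndatableEpisodeError):
            estimate_onset([DiagnosisRecord("m1", PartialDate(2020, 6), "dx-ga", 20)],
                           dt.date(2020, 9, 25), config)

    def test_no_ga_diagnosis_is_undatable(self, config):
        with pytest.raises(UndatableEpisodeError):
            estimate_onset([DiagnosisRecord("m1", PartialDate(2020, 6, 1), "dx", None)],
                           dt.date(2020, 9, 25), config)

    def test_onset_on_or_after_delivery_is_undatable(self, config):
        with pytest.raises(UndatableEpisodeError):
            estimate_onset([_ga("2020-09-25", 0)], dt.date(2020, 9, 25), config)


ga_diagnoses = st.lists(
    st.tuples(st.integers(0, 280), st.integers(0, 42)), min_size=1, max_size=10)


@given(ga_diagnoses)
def test_onset_equals_brute_force_scan(config, diags):
    """The estimator must agree with an exhaustive scan maximizing GA weeks
    (ties to the latest diagnosis date)."""
    delivery = dt.date(2020, 9, 25)
    records = [_ga((delivery - dt.timedelta(days=off)).isoformat(), weeks)
               for off, weeks in diags]
    best = max(records,
               key=lambda r: (r.gestational_age_weeks, r.date.to_date()))
    expected_raw = best.date.to_date() - dt.timedelta(
        days=7 * best.gestational_age_weeks)
    try:
        est = estimate_onset(records, delivery, config)
    except UndatableEpisodeError:
        assert expected_raw >= delivery
        return
    assert est.raw_date == expected_raw
    gestation = (delivery - est.date).days
    assert 1 <= gestation <= config.post_term_cap_days


@given(ga_diagnoses, st.integers(0, 280), st.integers(0, 42))
def test_adding_smaller_ga_never_changes_onset(config, diags, off, smaller_weeks):
    delivery = dt.date(2020, 9, 25)
    records = [_ga((delivery - dt.timedelta(days=o)).isoformat(), w)
               for o, w in diags]
    max_weeks = max(r.gestational_age_weeks for r in records)
    if smaller_weeks >= max_weeks:
        smaller_weeks = max(0, max_weeks - 1)
    if smaller_weeks == max_weeks:  # max_weeks == 0, nothing strictly smaller
        return
    extra = _ga((delivery - dt.timedelta(days=off)).isoformat(), smaller_weeks)

    def run(recs):
        try:
            return estimate_onset(recs, delivery, config).date
        except UndatableEpisodeError:
            return None

    assert run(records) == run(records + [extra])
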