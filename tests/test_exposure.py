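"""Exposure intervals, window assignment vs a per-day oracle, dedup counts."""
import datetime as dt

from hypothesis import given
from hypothesis import strategies as st

from kampo_claims import (
    WINDOWS,
    DrugRecord,
    PartialDate,
    PregnancyEpisode,
    PrescriptionEvent,
    StudyConfig,
    WindowAssignment,
    assign_windows,
    build_events,
    dedup_count,
    episode_windows,
)

ONSET = dt.date(2014, 1, 10)
DELIVERY = dt.date(2014, 10, 7)
EPISODE = PregnancyEpisode("m1", ONSET, DELIVERY, "selected_entries", False, ONSET)


def _drug(atc="V03AX", dispensing="2014-03-02", days=14, formula="kakkonto"):
    return DrugRecord("m1", atc, "d1", formula, PartialDate(2014, 3), days,
                      "extract_formula",
                      dispensing_date=PartialDate.parse(dispensing))


def _event(start, end, formula="kakkonto"):
    return PrescriptionEvent("m1", formula, "extract_formula", start, end,
                             "dispensing")


class TestBuildEvents:
    def test_interval_from_days_supply(self, config):
        (ev,) = build_events([_drug()], config)
        assert (ev.start_date, ev.end_date) == (dt.date(2014, 3, 2),
                                                dt.date(2014, 3, 15))

    def test_non_matching_atc_excluded(self, config):
        assert build_events([_drug(atc="N02BE")], config) == []

    def test_one_day_supply_is_single_day(self, config):
        (ev,) = build_events([_drug(days=1)], config)
        assert ev.start_date == ev.end_date


class TestAssignWindows:
    def _windows_of(self, start_off, end_off, config):
        ev = _event(ONSET + dt.timedelta(days=start_off),
                    ONSET + dt.timedelta(days=end_off))
        out = assign_windows([ev], EPISODE, config)
        return out[0].windows if out else frozenset()

    def test_contained_event(self, config):
        assert self._windows_of(5, 18, config) == {"pregnancy"}

    def test_boundary_spanning_event_joins_both(self, config):
        assert self._windows_of(-10, 3, config) == {"pre", "pregnancy"}

    def test_event_outside_all_windows_dropped(self, config):
        gest = (DELIVERY - ONSET).days
        assert self._windows_of(gest + 181, gest + 194, config) == frozenset()

    def test_start_date_mode_assigns_single_window(self):
        config = StudyConfig(window_assignment="start")
        assert self._windows_of(-10, 3, config) == {"pre"}

    def test_windows_tile_exposure_span(self, config):
        ws = episode_windows(EPISODE, config)
        pre, preg, post = ws["pre"], ws["pregnancy"], ws["post"]
        assert pre[1] + dt.timedelta(days=1) == preg[0]
        assert preg[1] + dt.timedelta(days=1) == post[0]
        total = (post[1] - pre[0]).days + 1
        assert total == 2 * 180 + EPISODE.gestation_days + 1


@given(st.integers(-250, 500), st.integers(1, 120))
def test_assignment_equals_per_day_membership_scan(config, start_off, days):
    """Interval assignment must agree with brute-force per-day membership."""
    start = ONSET + dt.timedelta(days=start_off)
    end = start + dt.timedelta(days=days - 1)
    out = assign_windows([_event(start, end)], EPISODE, config)
    assigned = out[0].windows if out else frozenset()
    windows = episode_windows(EPISODE, config)
    brute = {name for name, (lo, hi) in windows.items()
             if any(lo <= start + dt.timedelta(days=k) <= hi for k in range(days))}
    assert assigned == brute


class TestDedupCount:
    def test_repeat_prescriptions_count_once(self, config):
        events = [_event(ONSET + dt.timedelta(days=k), ONSET + dt.timedelta(days=k + 6))
                  for k in (5, 40, 90)]
        counts = dedup_count(assign_windows(events, EPISODE, config), ["m1"])
        row = counts.iloc[0]
        assert (row.total_n, row.pregnancy_n) == (1, 1)

    def test_simultaneous_formulas_each_count(self, config):
        events = [_event(ONSET + dt.timedelta(days=5), ONSET + dt.timedelta(days=11), f)
                  for f in ("kakkonto", "shoseiryuto")]
        counts = dedup_count(assign_windows(events, EPISODE, config), ["m1"])
        assert counts["pregnancy_n"].tolist() == [1, 1]

    def test_pre_and_post_contribute_total_once(self, config):
        events = [_event(ONSET - dt.timedelta(days=30), ONSET - dt.timedelta(days=24)),
                  _event(DELIVERY + dt.timedelta(days=30),
                         DELIVERY + dt.timedelta(days=36))]
        counts = dedup_count(assign_windows(events, EPISODE, config), ["m1"])
        row = counts.iloc[0]
        assert (row.total_n, row.pre_n, row.pregnancy_n, row.post_n) == (1, 1, 0, 1)


@given(st.lists(st.tuples(st.integers(0, 30), st.sampled_from(WINDOWS)),
                max_size=40))
def test_union_bounds_on_counts(picks):
    """Per formula: max window count <= total <= sum of window counts."""
    assignments = {}
    for person, window in picks:
        key = f"p{person}"
        assignments.setdefault(key, set()).add(window)
    alist = [WindowAssignment(pid, "kakkonto", "extract_formula", frozenset(ws))
             for pid, ws in assignments.items()]
    counts = dedup_count(alist, sorted(assignments))
    if counts.empty:
        return
    row = counts.iloc[0]
    parts = (row.pre_n, row.pregnancy_n, row.post_n)
    assert max(parts) <= row.total_n <= sum(parts)
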