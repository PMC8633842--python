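"""Exposure classification of Kampo drug records.

Kampo products are extracted by ATC prefix (V03AX), resolved to an exposure
interval (event date plus days of supply), assigned to the pre-pregnancy /
pregnancy / postpartum windows, and deduplicated so that a formula counts at
most once per person per window regardless of how often it was dispensed.
"""
from __future__ import annotations

import datetime as dt
from collections import defaultdict
from pathlib import Path

import pandas as pd

from .config import StudyConfig
from .model import (
    WINDOW_POST,
    WINDOW_PRE,
    WINDOW_PREGNANCY,
    WINDOWS,
    DrugRecord,
    PregnancyEpisode,
    PrescriptionEvent,
    WindowAssignment,
    resolve_event_date,
)


def build_events(drugs: list[DrugRecord], config: StudyConfig) -> list[PrescriptionEvent]:
    """Resolve ATC-matching drug records to exposure intervals.

    The interval is [event date, event date + days_supply - 1]: a one-day
    supply is a single-day interval.
    """
    events = []
    for rec in drugs:
        if not rec.atc_code.startswith(config.atc_prefix):
            continue
        resolved = resolve_event_date(rec, config)
        events.append(PrescriptionEvent(
            person_id=rec.person_id,
            formula_name=rec.formula_name,
            category=rec.category,
            start_date=resolved.date,
            end_date=resolved.date + dt.timedelta(days=rec.days_supply - 1),
            date_provenance=resolved.provenance,
        ))
    return events


def episode_windows(
    episode: PregnancyEpisode, config: StudyConfig
) -> dict[str, tuple[dt.date, dt.date]]:
    """The three inclusive exposure windows around one episode.

    Onset and delivery days both belong to the pregnancy window; the three
    windows are pairwise disjoint and tile the full exposure span.
    """
    onset, delivery = episode.onset_date, episode.delivery_date
    day = dt.timedelta(days=1)
    return {
        WINDOW_PRE: (onset - dt.timedelta(days=config.pre_window_days), onset - day),
        WINDOW_PREGNANCY: (onset, delivery),
        WINDOW_POST: (delivery + day, delivery + dt.timedelta(days=config.post_window_days)),
    }


def assign_windows(
    events: list[PrescriptionEvent],
    episode: PregnancyEpisode,
    config: StudyConfig,
) -> list[WindowAssignment]:
    """Assign one person's events to exposure windows, unioned per formula.

    Under the default ``overlap`` rule an event joins every window its
    supply interval intersects (a supply spanning a boundary counts in
    both); under ``start`` only the window containing the start date.
    Events wholly outside all windows are dropped.
    """
    windows = episode_windows(episode, config)
    per_formula: dict[tuple[str, str], set[str]] = defaultdict(set)
    for ev in events:
        if ev.person_id != episode.mother_id:
            raise ValueError(f"event for {ev.person_id} against episode "
                             f"{episode.mother_id}")
        for name, (lo, hi) in windows.items():
            if config.window_assignment == "start":
                hit = lo <= ev.start_date <= hi
            else:
                hit = ev.start_date <= hi and ev.end_date >= lo
            if hit:
                per_formula[(ev.formula_name, ev.category)].add(name)
    return [WindowAssignment(episode.mother_id, formula, category, frozenset(ws))
            for (formula, category), ws in sorted(per_formula.items()) if ws]


def classify_bundle(
    drugs: list[DrugRecord],
    episodes: dict[str, PregnancyEpisode | None],
    cohort_ids: list[str],
    config: StudyConfig,
) -> tuple[list[WindowAssignment], list[PrescriptionEvent]]:
    """Run event building and window assignment for every cohort mother.

    Returns the assignments and the resolved events of cohort members (the
    latter retained for date-provenance tallies in reporting).
    """
    cohort = set(cohort_ids)
    events = [e for e in build_events(drugs, config) if e.person_id in cohort]
    by_person: dict[str, list[PrescriptionEvent]] = defaultdict(list)
    for ev in events:
        by_person[ev.person_id].append(ev)
    assignments: list[WindowAssignment] = []
    for mother_id in cohort_ids:
        ep = episodes.get(mother_id)
        if ep is None:
            continue
        assignments.extend(assign_windows(by_person.get(mother_id, []), ep, config))
    return assignments, events


def dedup_count(
    assignments: list[WindowAssignment], cohort_ids: list[str]
) -> pd.DataFrame:
    """Distinct-person counts per (formula, window) plus an any-window total.

    A person contributes at most 1 to each window count of a formula and at
    most 1 to its total, however many dispensings occurred.
    """
    cohort = set(cohort_ids)
    persons: dict[tuple[str, str], dict[str, set[str]]] = defaultdict(
        lambda: {w: set() for w in (*WINDOWS, "total")})
    for a in assignments:
        if a.person_id not in cohort:
            raise ValueError(f"assignment for non-cohort person {a.person_id}")
        slot = persons[(a.formula_name, a.category)]
        for w in a.windows:
            slot[w].add(a.person_id)
        if a.windows:
            slot["total"].add(a.person_id)
    rows = [{
        "formula_name": formula,
        "category": category,
        "total_n": len(slot["total"]),
        "pre_n": len(slot[WINDOW_PRE]),
        "pregnancy_n": len(slot[WINDOW_PREGNANCY]),
        "post_n": len(slot[WINDOW_POST]),
    } for (formula, category), slot in sorted(persons.items())]
    return pd.DataFrame(rows, columns=["formula_name", "category", "total_n",
                                       "pre_n", "pregnancy_n", "post_n"])


# -- assignment table serialization ------------------------------------------

def write_assignments_csv(assignments: list[WindowAssignment],
                          path: str | Path) -> None:
    rows = [{"person_id": a.person_id, "formula_name": a.formula_name,
             "category": a.category,
             "windows": ";".join(w for w in WINDOWS if w in a.windows)}
            for a in assignments]
    pd.DataFrame(rows, columns=["person_id", "formula_name", "category",
                                "windows"]).to_csv(path, index=False,
                                                   lineterminator="\n")


def read_assignments_csv(path: str | Path) -> list[WindowAssignment]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return [WindowAssignment(r.person_id, r.formula_name, r.category,
                             frozenset(w for w in r.windows.split(";") if w))
            for r in df.itertuples(index=False)]
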