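"""Delimited-text readers and writers for the five claims tables.

Files are comma-separated UTF-8 with a header row; dates are serialized
ISO-8601 (``YYYY-MM`` for month-granular fields, ``YYYY-MM-DD`` otherwise).
Claims feeds are dirty in practice, so reading is fail-soft: rows violating a
type invariant are rejected individually, counted, and reported with their
line number; the load succeeds as long as the schema is right.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .config import StudyConfig
from .dates import PartialDate, month_range
from .model import (
    ClaimsBundle,
    DeliveryEntry,
    DiagnosisRecord,
    DrugRecord,
    MotherInfantLink,
    Person,
)

TABLE_FILES = {
    "enrollment": "enrollment.csv",
    "links": "links.csv",
    "diagnoses": "diagnoses.csv",
    "delivery_entries": "delivery_entries.csv",
    "drugs": "drugs.csv",
}

_SCHEMAS = {
    "enrollment": ["person_id", "sex", "birth_ym", "insurer_id", "month"],
    "links": ["mother_id", "infant_id", "infant_birth_ym"],
    "diagnoses": ["person_id", "date", "code", "ga_weeks", "is_suspected", "is_main"],
    "delivery_entries": ["person_id", "date", "tier", "code"],
    "drugs": ["person_id", "atc_code", "drug_code", "formula_name", "claim_ym",
              "dispensing_date", "hospitalization_date", "days_supply", "category"],
}


class SchemaError(ValueError):
    """A table is missing a required column."""


@dataclass(frozen=True)
class RowError:
    table: str
    line: int  # 1-based line number in the file, header = line 1
    message: str


@dataclass
class LoadReport:
    """Row counts and per-row rejection diagnostics for one bundle load."""

    row_counts: dict[str, int] = field(default_factory=dict)
    accepted_counts: dict[str, int] = field(default_factory=dict)
    errors: list[RowError] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.errors)


def _read_table(path: Path, table: str) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _SCHEMAS[table] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing} in {table}")
    return df


def _parse_bool(text: str) -> bool:
    t = text.strip().lower()
    if t in ("true", "1", "yes"):
        return True
    if t in ("false", "0", "no", ""):
        return False
    raise ValueError(f"not a boolean: {text!r}")


def _opt_date(text: str) -> PartialDate | None:
    return PartialDate.parse(text) if text.strip() else None


def read_claims_bundle(
    paths: str | Path | dict[str, str | Path], config: StudyConfig
) -> tuple[ClaimsBundle, LoadReport]:
    """Load and validate the five tables.

    ``paths`` may be a directory holding the conventional file names or a
    mapping from table name to file path.  Returns the validated bundle and
    a :class:`LoadReport` with row counts and rejection diagnostics.
    """
    if isinstance(paths, (str, Path)):
        base = Path(paths)
        paths = {t: base / f for t, f in TABLE_FILES.items()}
    report = LoadReport()
    study_months = set(month_range(config.study_start_ym.ym(), config.study_end_ym.ym()))

    def rows(table: str):
        df = _read_table(Path(paths[table]), table)
        report.row_counts[table] = len(df)
        # header is line 1, so data row i sits at line i + 2
        for i, row in enumerate(df.itertuples(index=False)):
            yield i + 2, row

    # enrollment: one row per person-month, person attributes repeated
    person_attrs: dict[str, tuple[str, PartialDate, str]] = {}
    person_months: dict[str, set] = {}
    for line, r in rows("enrollment"):
        try:
            birth = PartialDate.parse(r.birth_ym)
            month = PartialDate.parse(r.month)
            if month.is_full:
                raise ValueError("enrollment month must be YYYY-MM")
            if month.ym() not in study_months:
                raise ValueError(f"enrollment month {month} outside study window")
            attrs = (r.sex, birth, r.insurer_id)
            prev = person_attrs.setdefault(r.person_id, attrs)
            if prev != attrs:
                raise ValueError(f"inconsistent attributes for person {r.person_id}")
            person_months.setdefault(r.person_id, set()).add(month.ym())
        except ValueError as e:
            report.errors.append(RowError("enrollment", line, str(e)))
    persons: dict[str, Person] = {}
    for pid, (sex, birth, insurer) in person_attrs.items():
        months = person_months.get(pid, set())
        if not months:
            continue
        try:
            persons[pid] = Person(pid, sex, birth, insurer, frozenset(months))
        except ValueError as e:
            report.errors.append(RowError("enrollment", 0, f"person {pid}: {e}"))
    report.accepted_counts["enrollment"] = sum(len(m) for m in person_months.values())

    def known(pid: str) -> str:
        if pid not in persons:
            raise ValueError(f"unknown person_id {pid!r}")
        return pid

    links: list[MotherInfantLink] = []
    for line, r in rows("links"):
        try:
            links.append(MotherInfantLink(known(r.mother_id), r.infant_id,
                                          PartialDate.parse(r.infant_birth_ym)))
        except ValueError as e:
            report.errors.append(RowError("links", line, str(e)))

    diagnoses: list[DiagnosisRecord] = []
    for line, r in rows("diagnoses"):
        try:
            ga = int(r.ga_weeks) if str(r.ga_weeks).strip() else None
            diagnoses.append(DiagnosisRecord(known(r.person_id), PartialDate.parse(r.date),
                                             r.code, ga, _parse_bool(r.is_suspected),
                                             _parse_bool(r.is_main)))
        except ValueError as e:
            report.errors.append(RowError("diagnoses", line, str(e)))

    delivery_entries: list[DeliveryEntry] = []
    for line, r in rows("delivery_entries"):
        try:
            delivery_entries.append(DeliveryEntry(known(r.person_id),
                                                  PartialDate.parse(r.date), r.tier, r.code))
        except ValueError as e:
            report.errors.append(RowError("delivery_entries", line, str(e)))

    drugs: list[DrugRecord] = []
    for line, r in rows("drugs"):
        try:
            drugs.append(DrugRecord(
                known(r.person_id), r.atc_code, r.drug_code, r.formula_name,
                PartialDate.parse(r.claim_ym), int(r.days_supply), r.category,
                _opt_date(r.dispensing_date), _opt_date(r.hospitalization_date)))
        except ValueError as e:
            report.errors.append(RowError("drugs", line, str(e)))

    for table in ("links", "diagnoses", "delivery_entries", "drugs"):
        rejected = sum(1 for e in report.errors if e.table == table)
        report.accepted_counts[table] = report.row_counts[table] - rejected

    bundle = ClaimsBundle(persons, links, diagnoses, delivery_entries, drugs)
    return bundle, report


def write_claims_bundle(bundle: ClaimsBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write the five tables; deterministic row order for byte-stable output."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {t: out / f for t, f in TABLE_FILES.items()}

    enr = [
        {"person_id": p.person_id, "sex": p.sex, "birth_ym": p.birth_ym.isoformat(),
         "insurer_id": p.insurer_id, "month": f"{y:04d}-{m:02d}"}
        for p in bundle.persons.values()
        for (y, m) in sorted(p.enrollment_months)
    ]
    _write(pd.DataFrame(enr, columns=_SCHEMAS["enrollment"]), paths["enrollment"])

    _write(pd.DataFrame(
        [{"mother_id": l.mother_id, "infant_id": l.infant_id,
          "infant_birth_ym": l.infant_birth_ym.isoformat()} for l in bundle.links],
        columns=_SCHEMAS["links"]), paths["links"])

    _write(pd.DataFrame(
        [{"person_id": d.person_id, "date": d.date.isoformat(), "code": d.code,
          "ga_weeks": "" if d.gestational_age_weeks is None else d.gestational_age_weeks,
          "is_suspected": str(d.is_suspected).lower(),
          "is_main": str(d.is_main).lower()} for d in bundle.diagnoses],
        columns=_SCHEMAS["diagnoses"]), paths["diagnoses"])

    _write(pd.DataFrame(
        [{"person_id": e.person_id, "date": e.date.isoformat(), "tier": e.tier,
          "code": e.code} for e in bundle.delivery_entries],
        columns=_SCHEMAS["delivery_entries"]), paths["delivery_entries"])

    _write(pd.DataFrame(
        [{"person_id": d.person_id, "atc_code": d.atc_code, "drug_code": d.drug_code,
          "formula_name": d.formula_name, "claim_ym": d.claim_ym.isoformat(),
          "dispensing_date": d.dispensing_date.isoformat() if d.dispensing_date else "",
          "hospitalization_date":
              d.hospitalization_date.isoformat() if d.hospitalization_date else "",
          "days_supply": d.days_supply, "category": d.category} for d in bundle.drugs],
        columns=_SCHEMAS["drugs"]), paths["drugs"])
    return paths


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, lineterminator="\n")
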