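"""Study configuration: every numeric rule parameter of the pipeline."""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .dates import PartialDate


@dataclass(frozen=True)
class StudyConfig:
    """Parameters of the episode-dating and exposure-window rules.

    Attributes
    ----------
    pre_window_days, post_window_days
        Length in days of the pre-pregnancy and postpartum exposure windows
        (default 180 each).
    post_term_cap_days
        Hard cap on estimated gestation length; 294 days is the 42-week
        post-term threshold at which labour induction is recommended.
        Raw gestations beyond it are uniformly reset to the cap by moving
        the onset to ``delivery - cap``.
    pre_birth_enrollment_months
        Number of calendar months before the infant's birth month in which
        the mother must be continuously enrolled (default 11).
    formula_report_threshold_pct, crude_report_threshold_pct
        Reporting cut-offs applied to the *rounded* total prescription
        percentage for extract formulas (0.4%) and crude decoction drugs
        (0.1%).
    atc_prefix
        ATC code prefix identifying Kampo products (default ``V03AX``).
    fallback_day_of_month
        Day assigned when only a year-month is known (default 15).
    window_assignment
        ``"overlap"`` assigns a supply interval to every window it
        intersects; ``"start"`` assigns by the start date only.
    study_start_ym, study_end_ym
        Bounds of the observation period covered by the claims feed.
    """

    pre_window_days: int = 180
    post_window_days: int = 180
    post_term_cap_days: int = 294
    pre_birth_enrollment_months: int = 11
    formula_report_threshold_pct: float = 0.4
    crude_report_threshold_pct: float = 0.1
    atc_prefix: str = "V03AX"
    fallback_day_of_month: int = 15
    window_assignment: str = "overlap"
    study_start_ym: PartialDate = field(default_factory=lambda: PartialDate(2005, 1))
    study_end_ym: PartialDate = field(default_factory=lambda: PartialDate(2016, 8))

    def __post_init__(self) -> None:
        for name in ("pre_window_days", "post_window_days", "post_term_cap_days",
                     "pre_birth_enrollment_months"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("formula_report_threshold_pct", "crude_report_threshold_pct"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must lie in [0, 100]")
        if not 1 <= self.fallback_day_of_month <= 28:
            raise ValueError("fallback_day_of_month must be a day every month has")
        if self.window_assignment not in ("overlap", "start"):
            raise ValueError("window_assignment must be 'overlap' or 'start'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in raw:
                continue
            v = raw[f.name]
            if f.name in ("study_start_ym", "study_end_ym"):
                v = PartialDate.parse(str(v))
            kwargs[f.name] = v
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["study_start_ym"] = self.study_start_ym.isoformat()
        d["study_end_ym"] = self.study_end_ym.isoformat()
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
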