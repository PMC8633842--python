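"""Partial (year-month) and full calendar dates for month-granular claims data.

Japanese health-insurance claims are filed monthly; many fields carry only a
year and month, while a few (dispensing dates, some diagnosis dates) carry a
day.  :class:`PartialDate` makes the distinction explicit so that day-level
arithmetic is only ever performed on dates that actually have a day.
"""
from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass

_YM_RE = re.compile(r"^(\d{4})-(\d{2})$")
_YMD_RE = re.compile(r"^(\d{4})-(\d{2})-(\d{2})$")

YearMonth = tuple[int, int]


@dataclass(frozen=True)
class PartialDate:
    """A calendar date that may lack its day component.

    Ordering and day arithmetic are defined only for full dates (via
    :meth:`to_date`); month-level comparison goes through :meth:`ym`.
    """

    year: int
    month: int
    day: int | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.month <= 12:
            raise ValueError(f"month out of range: {self.month}")
        if self.day is not None:
            # dt.date raises on an invalid (year, month, day) combination
            dt.date(self.year, self.month, self.day)

    @property
    def is_full(self) -> bool:
        return self.day is not None

    def to_date(self) -> dt.date:
        if self.day is None:
            raise ValueError(f"{self} is month-granular and has no day")
        return dt.date(self.year, self.month, self.day)

    def ym(self) -> YearMonth:
        return (self.year, self.month)

    @classmethod
    def from_date(cls, d: dt.date) -> "PartialDate":
        return cls(d.year, d.month, d.day)

    @classmethod
    def parse(cls, text: str) -> "PartialDate":
        """Parse ISO-8601 ``YYYY-MM`` or ``YYYY-MM-DD``."""
        m = _YMD_RE.match(text)
        if m:
            return cls(int(m[1]), int(m[2]), int(m[3]))
        m = _YM_RE.match(text)
        if m:
            return cls(int(m[1]), int(m[2]))
        raise ValueError(f"not an ISO year-month or date: {text!r}")

    def isoformat(self) -> str:
        if self.day is None:
            return f"{self.year:04d}-{self.month:02d}"
        return f"{self.year:04d}-{self.month:02d}-{self.day:02d}"

    def __str__(self) -> str:
        return self.isoformat()


def add_months(ym: YearMonth, k: int) -> YearMonth:
    y, m = ym
    t = y * 12 + (m - 1) + k
    return (t // 12, t % 12 + 1)


def month_range(start: YearMonth, end: YearMonth) -> list[YearMonth]:
    """All calendar months from ``start`` through ``end``, inclusive."""
    if start > end:
        return []
    out = []
    ym = start
    while ym <= end:
        out.append(ym)
        ym = add_months(ym, 1)
    return out


def months_spanned(start: dt.date, end: dt.date) -> list[YearMonth]:
    """Calendar months intersecting the inclusive day interval [start, end]."""
    if start > end:
        return []
    return month_range((start.year, start.month), (end.year, end.month))


def mid_month(ym: YearMonth, day: int = 15) -> dt.date:
    """The conventional fallback day within a month-granular date."""
    return dt.date(ym[0], ym[1], day)
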