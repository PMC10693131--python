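"""Epidemiological-week calendar features.

Weeks are Sunday-through-Saturday blocks. Week 1 of a year is the block
containing that year's first Wednesday (the MMWR convention). Indices run
1..52: a 53rd block in a long year is merged into index 52, and days that
precede week 1 of their own calendar year belong to week 52 of the previous
year. The two other calendar confounders are the day offset from the Unix
epoch (1970-01-01) and the number of public holidays falling inside a week.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

EPOCH = dt.date(1970, 1, 1)

__all__ = ["EpiWeek", "week_of_year", "days_since_epoch", "holidays_per_week", "week_start"]


@dataclass(frozen=True, order=True)
class EpiWeek:
    """One epidemiological week: (year, index) plus its 7-day span."""

    year: int
    week_index: int
    start_date: dt.date
    end_date: dt.date

    def __post_init__(self) -> None:
        if not 1 <= self.week_index <= 52:
            raise ValueError(f"week_index must be in [1, 52], got {self.week_index}")
        if (self.end_date - self.start_date).days != 6:
            raise ValueError("an epidemiological week spans exactly 7 days")

    @property
    def key(self) -> tuple[int, int]:
        return (self.year, self.week_index)


def _first_wednesday(year: int) -> dt.date:
    d = dt.date(year, 1, 1)
    # Monday=0 .. Sunday=6; Wednesday=2
    return d + dt.timedelta(days=(2 - d.weekday()) % 7)


def _sunday_on_or_before(day: dt.date) -> dt.date:
    # Sunday has weekday() == 6
    return day - dt.timedelta(days=(day.weekday() + 1) % 7)


def week1_start(year: int) -> dt.date:
    """Sunday starting week 1 of `year` (the block holding the first Wednesday)."""
    return _sunday_on_or_before(_first_wednesday(year))


def week_start(week: EpiWeek) -> dt.date:
    return week.start_date


def week_of_year(day: dt.date) -> EpiWeek:
    """Map a calendar day to its epidemiological week.

    Late-December days can fall in the block holding the next year's first
    Wednesday; they get week 1 of that next year. Days before their own
    year's week 1 are folded into week 52 of the previous year, and any
    53rd block keeps index 52 so indices never exceed 52.
    """
    if day >= week1_start(day.year + 1):
        year = day.year + 1
    elif day >= week1_start(day.year):
        year = day.year
    else:
        year = day.year - 1
    idx = (day - week1_start(year)).days // 7 + 1
    start = _sunday_on_or_before(day)
    return EpiWeek(year=year, week_index=min(idx, 52), start_date=start,
                   end_date=start + dt.timedelta(days=6))


def days_since_epoch(day: dt.date) -> int:
    """Day count since 1970-01-01 (negative before the epoch)."""
    return (day - EPOCH).days


def holidays_per_week(week: EpiWeek, holidays) -> int:
    """Number of holiday dates falling inside the week's 7-day span."""
    n = sum(1 for h in holidays if week.start_date <= h <= week.end_date)
    if not 0 <= n <= 7:  # pragma: no cover - guarded by the span length
        raise AssertionError("holiday count outside [0, 7]")
    return n
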