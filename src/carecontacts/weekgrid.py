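"""Study week grid.

All weekly aggregation in this package happens on a fixed grid of
consecutive 7-day blocks anchored on Sunday 2017-01-01.  The key policy
dates of the UK's first COVID-19 lockdown (March 8, March 29, April 26 and
June 28 2020) all fall on Sundays of this grid, and the default study end
(Saturday July 18 2020) closes the final block exactly, so the grid makes
every period boundary a whole number of weeks.
"""

from __future__ import annotations

import datetime as dt
from typing import Iterable

import numpy as np
import pandas as pd

#: First day of the first study week (a Sunday).
GRID_ANCHOR = dt.date(2017, 1, 1)

#: Default last day of follow-up (a Saturday, closing week index 184).
STUDY_END = dt.date(2020, 7, 18)


def as_date(d) -> dt.date:
    """Coerce str / datetime / Timestamp / date to ``datetime.date``."""
    if isinstance(d, dt.datetime):
        return d.date()
    if isinstance(d, dt.date):
        return d
    return pd.Timestamp(d).date()


def week_start(d) -> dt.date:
    """Sunday opening the grid week that contains ``d``."""
    d = as_date(d)
    return d - dt.timedelta(days=(d - GRID_ANCHOR).days % 7)


def week_index(d) -> int:
    """Zero-based index of the grid week containing ``d`` (anchor week = 0)."""
    return (week_start(d) - GRID_ANCHOR).days // 7


def week_grid(start=GRID_ANCHOR, end=STUDY_END) -> pd.DatetimeIndex:
    """All grid week-start dates from the week containing ``start`` up to
    the last week starting on or before ``end``."""
    start, end = as_date(start), as_date(end)
    first = week_start(start)
    if first < start:  # partial leading week: begin at the next grid Sunday
        first = first + dt.timedelta(days=7)
    n = (end - first).days // 7 + 1
    if n <= 0:
        return pd.DatetimeIndex([], name="week_start")
    return pd.DatetimeIndex(
        [pd.Timestamp(first) + pd.Timedelta(days=7 * i) for i in range(n)],
        name="week_start",
    )


def week_of_year(week_starts: Iterable) -> np.ndarray:
    """Ordinal week-of-year index (1-based) on the grid.

    Weeks are numbered by their position among grid weeks whose start date
    falls in the same calendar year; because the grid is anchored on a
    Sunday the numbering drifts against calendar dates by weekday, which is
    exactly what aligning "the same week of the year" across 2017-20
    requires.
    """
    ws = pd.DatetimeIndex(week_starts)
    out = np.empty(len(ws), dtype=int)
    for year in ws.year.unique():
        sel = ws.year == year
        first_idx = week_index(dt.date(int(year), 1, 1))
        if week_start(dt.date(int(year), 1, 1)) < dt.date(int(year), 1, 1):
            first_idx += 1
        out[sel] = np.array([week_index(w) for w in ws[sel]]) - first_idx + 1
    return out
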