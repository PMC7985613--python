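"""Weekly series assembly: counts over denominators, historical averages
and small-cell suppression.

The central container is :class:`WeeklySeries` — one condition/stratum's
weekly event count, dynamic denominator and proportion on the study week
grid.  Suppression follows the disclosure-control convention that weekly
counts of 1-4 are masked in published outputs while true zeros are shown;
internal model fitting always uses unsuppressed counts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import IntegrityError, ValidationError
from .weekgrid import week_of_year, week_start

_REQUIRED = ["week_start", "count", "denominator", "proportion"]


@dataclass
class WeeklySeries:
    """Weekly (count, denominator, proportion) rows for one condition and
    stratum; ``truth`` optionally carries the generating oracle (eta, p)."""

    condition: str
    stratum: str
    data: pd.DataFrame
    truth: pd.DataFrame | None = None

    def __post_init__(self):
        df = self.data
        if "proportion" not in df.columns:
            df = df.assign(
                proportion=np.where(
                    df["denominator"] > 0, df["count"] / df["denominator"], 0.0
                )
            )
        missing = [c for c in _REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"weekly series missing column(s) {missing}")
        df = df.sort_values("week_start", kind="stable").reset_index(drop=True)
        counts = df["count"]
        if counts.notna().any():
            valid = counts.dropna()
            if (valid < 0).any():
                raise ValidationError("negative weekly count")
            over = valid > df.loc[valid.index, "denominator"]
            if over.any():
                raise ValidationError("count exceeds denominator")
        self.data = df

    def __len__(self) -> int:
        return len(self.data)

    def scaled(self, factor: int) -> "WeeklySeries":
        """Multiply counts and denominators by a common factor (proportions
        unchanged)."""
        df = self.data.assign(
            count=self.data["count"] * factor,
            denominator=self.data["denominator"] * factor,
        )
        return replace(self, data=df)


def _denominator_frame(denominators, calendar: pd.DatetimeIndex) -> pd.Series:
    """Coerce the supported denominator representations to a per-week
    Series aligned with ``calendar``."""
    if isinstance(denominators, (int, np.integer)):
        return pd.Series(int(denominators), index=calendar)
    if isinstance(denominators, pd.Series):
        return denominators.reindex(calendar).fillna(0).astype(int)
    df = denominators
    if "stratifier" in df.columns:
        df = df[df["stratifier"] == "overall"]
    s = df.set_index(pd.DatetimeIndex(df["week_start"]))["count"]
    return s.reindex(calendar).fillna(0).astype(int)


def weekly_series(
    outcome_events: pd.DataFrame,
    denominators,
    calendar: pd.DatetimeIndex,
    condition: str = "outcome",
    stratum: str = "all",
) -> WeeklySeries:
    """Count distinct persons with an episode starting in each grid week.

    ``outcome_events`` needs ``event_date`` and (when present) ``patient_id``
    columns; weeks without events are zero-filled over ``calendar``.  An
    event in a week whose denominator is zero signals a cohort/extraction
    mismatch and raises :class:`IntegrityError`.
    """
    calendar = pd.DatetimeIndex(calendar)
    denom = _denominator_frame(denominators, calendar)
    if len(outcome_events):
        ev = outcome_events.copy()
        ev["week_start"] = pd.DatetimeIndex(
            [week_start(d) for d in ev["event_date"]]
        )
        ev = ev[ev["week_start"].isin(calendar)]
        if "patient_id" in ev.columns:
            counts = ev.groupby("week_start")["patient_id"].nunique()
        else:
            counts = ev.groupby("week_start").size()
        counts = counts.reindex(calendar).fillna(0).astype(int)
    else:
        counts = pd.Series(0, index=calendar)
    bad = (counts > 0) & (denom == 0)
    if bad.any():
        w = calendar[bad][0].date()
        raise IntegrityError(
            f"{condition}: events in week {w} but denominator is zero"
        )
    data = pd.DataFrame(
        {
            "week_start": calendar,
            "count": counts.to_numpy(),
            "denominator": denom.to_numpy(),
        }
    )
    return WeeklySeries(condition=condition, stratum=stratum, data=data)


def historical_average(series: WeeklySeries) -> pd.DataFrame:
    """Mean, median and IQR of pre-2020 proportions by week-of-year.

    Week-of-year is the ordinal index of the week within its calendar year
    on the Sunday grid, so "the same week" aligns across years even though
    calendar dates drift by weekday.
    """
    df = series.data
    pre = df[pd.DatetimeIndex(df["week_start"]).year < 2020]
    if pre.empty:
        raise ValidationError("no pre-2020 weeks available for historical average")
    woy = week_of_year(pre["week_start"])
    g = pre.assign(week_of_year=woy).groupby("week_of_year")["proportion"]
    out = g.agg(
        mean="mean",
        median="median",
        q1=lambda s: s.quantile(0.25),
        q3=lambda s: s.quantile(0.75),
        n_years="size",
    ).reset_index()
    return out


def suppress_small_cells(series: WeeklySeries, threshold: int = 5) -> WeeklySeries:
    """Mask weekly counts in ``[1, threshold)`` for publication.

    Masked cells are distinguishable from true zeros via the ``masked``
    flag and a missing count; zeros are not disclosive and stay visible.
    """
    if threshold < 1:
        raise ValidationError("suppression threshold must be >= 1")
    df = series.data.copy()
    mask = (df["count"] >= 1) & (df["count"] < threshold)
    df["masked"] = mask
    df["count"] = df["count"].astype("Int64").mask(mask)
    df["proportion"] = df["proportion"].mask(mask)
    return replace(series, data=df)
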