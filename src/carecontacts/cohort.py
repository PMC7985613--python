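"""Dynamic weekly denominator populations.

Eligibility is evaluated at each week's start instant: a patient counts in
a week's denominator iff at week_start they are old enough, have completed
the 1-year registration run-in, are alive and registered, and (where the
condition requires it) meet the chronic-condition criterion at that week.
A patient dying or deregistering mid-week still counts for that week.

Chronic criteria come in three modes:

* ``none`` — the general denominator (e.g. mental health outcomes);
* ``from_first_code`` — membership opens at the first diagnosis record and
  never closes (diabetes, COPD);
* ``asthma_current`` — membership requires an asthma code within the last
  2 years (age < 18) or 3 years (age >= 18) at week_start, so it can lapse
  and re-open with a later code.  Records in patients aged >= 40 at the
  record date are discarded when any COPD code follows within 2 years
  (the asthma/COPD reclassification rule); because this looks forward,
  eligibility is computed retrospectively over the full record.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codelists import Codelist
from .errors import ValidationError
from .weekgrid import week_grid

VALID_STRATIFIERS = ("age_band", "sex", "region", "ethnicity")
CHRONIC_MODES = ("none", "from_first_code", "asthma_current")


@dataclass
class CohortRule:
    """Denominator eligibility rule for one condition."""

    condition: str
    min_age_years: int = 11
    chronic_mode: str = "none"
    chronic_codelist: str | None = None
    requires_smoking_history: bool = False
    smoking_codelist: str = "smoking"
    copd_codelist: str = "copd"
    asthma_window_child_years: int = 2
    asthma_window_adult_years: int = 3
    asthma_adult_age: int = 18
    copd_reclass_age: int = 40
    copd_reclass_window_years: int = 2
    registration_run_in_years: int = 1

    def __post_init__(self):
        if self.min_age_years < 0:
            raise ValidationError("min_age_years must be >= 0")
        if self.chronic_mode not in CHRONIC_MODES:
            raise ValidationError(f"unknown chronic_mode {self.chronic_mode!r}")
        if self.chronic_mode != "none" and not self.chronic_codelist:
            raise ValidationError(
                f"{self.condition}: chronic_mode {self.chronic_mode!r} needs a codelist"
            )
        for w in (
            self.asthma_window_child_years,
            self.asthma_window_adult_years,
            self.copd_reclass_window_years,
            self.registration_run_in_years,
        ):
            if w <= 0:
                raise ValidationError("windows must be positive")


def _ages_at(weeks: pd.DatetimeIndex, birth: pd.Timestamp) -> np.ndarray:
    """Completed years at each week start (floor)."""
    before_birthday = (weeks.month < birth.month) | (
        (weeks.month == birth.month) & (weeks.day < birth.day)
    )
    return weeks.year.to_numpy() - birth.year - before_birthday.astype(int)


def _plus_years(ts: pd.Timestamp, years: int) -> pd.Timestamp:
    return ts + pd.DateOffset(years=years)


def _asthma_code_dates(
    events: pd.DataFrame,
    birth: pd.Timestamp,
    rule: CohortRule,
    codelists: dict[str, Codelist],
) -> list[pd.Timestamp]:
    """Asthma record dates surviving the >=40 COPD reclassification."""
    asthma = codelists[rule.chronic_codelist]
    copd = codelists.get(rule.copd_codelist)
    dates = sorted(pd.Timestamp(d) for d in events.loc[events["code"].isin(asthma.codes), "event_date"])
    if copd is None:
        return dates
    copd_dates = [
        pd.Timestamp(d)
        for d in events.loc[events["code"].isin(copd.codes), "event_date"]
    ]
    if not copd_dates:
        return dates
    kept = []
    for c in dates:
        age_at_code = (
            c.year - birth.year - ((c.month, c.day) < (birth.month, birth.day))
        )
        horizon = _plus_years(c, rule.copd_reclass_window_years)
        if age_at_code >= rule.copd_reclass_age and any(
            c < d <= horizon for d in copd_dates
        ):
            continue
        kept.append(c)
    return kept


def eligibility_mask(
    patient: pd.Series,
    events: pd.DataFrame,
    rule: CohortRule,
    calendar: pd.DatetimeIndex,
    codelists: dict[str, Codelist] | None = None,
) -> np.ndarray:
    """Boolean eligibility over ``calendar`` weeks for one patient."""
    ws = pd.DatetimeIndex(calendar)
    birth = pd.Timestamp(patient["birth_date"])
    mask = _ages_at(ws, birth) >= rule.min_age_years
    run_in_done = _plus_years(
        pd.Timestamp(patient["registration_start"]), rule.registration_run_in_years
    )
    mask &= ws >= run_in_done
    reg_end = patient.get("registration_end")
    if pd.notna(reg_end):
        mask &= ws < pd.Timestamp(reg_end)
    death = patient.get("death_date")
    if pd.notna(death):
        mask &= ws < pd.Timestamp(death)
    if not mask.any():
        return mask

    if rule.chronic_mode != "none" or rule.requires_smoking_history:
        if codelists is None:
            raise ValidationError(f"{rule.condition}: codelists required")
        if events is None:
            events = pd.DataFrame(columns=["event_date", "code"])

    if rule.chronic_mode == "from_first_code":
        cl = codelists[rule.chronic_codelist]
        dates = events.loc[events["code"].isin(cl.codes), "event_date"]
        if len(dates) == 0:
            return np.zeros(len(ws), dtype=bool)
        mask &= ws >= pd.Timestamp(min(dates))
    elif rule.chronic_mode == "asthma_current":
        codes = _asthma_code_dates(events, birth, rule, codelists)
        if not codes:
            return np.zeros(len(ws), dtype=bool)
        ages = _ages_at(ws, birth)
        child = ages < rule.asthma_adult_age
        current = np.zeros(len(ws), dtype=bool)
        for c in codes:
            after = ws >= c
            current |= (
                after & child & (ws < _plus_years(c, rule.asthma_window_child_years))
            )
            current |= (
                after & ~child & (ws < _plus_years(c, rule.asthma_window_adult_years))
            )
        mask &= current

    if rule.requires_smoking_history:
        cl = codelists[rule.smoking_codelist]
        dates = events.loc[events["code"].isin(cl.codes), "event_date"]
        if len(dates) == 0:
            return np.zeros(len(ws), dtype=bool)
        mask &= ws >= pd.Timestamp(min(dates))
    return mask


def eligible_weeks(
    patient: pd.Series,
    events: pd.DataFrame,
    rule: CohortRule,
    calendar: pd.DatetimeIndex | None = None,
    codelists: dict[str, Codelist] | None = None,
) -> pd.DatetimeIndex:
    """Week-start dates at which the patient belongs to the condition's
    denominator (possibly empty)."""
    if calendar is None:
        calendar = week_grid()
    mask = eligibility_mask(patient, events, rule, calendar, codelists)
    return pd.DatetimeIndex(calendar)[mask]


def age_band(age: int) -> str:
    """10-year band label (11-20 ... 91-100); ages above 100 are folded
    into the top band."""
    lo = ((int(age) - 1) // 10) * 10 + 1
    lo = min(lo, 91)
    return f"{lo}-{lo + 9}"


def build_denominators(
    patients: pd.DataFrame,
    events: pd.DataFrame,
    rule: CohortRule,
    calendar: pd.DatetimeIndex | None = None,
    strata: list[str] | None = None,
    codelists: dict[str, Codelist] | None = None,
) -> pd.DataFrame:
    """Weekly eligible-person counts, overall and per requested stratifier.

    Returns a long table (condition, stratifier, stratum, week_start,
    count) containing an ``overall/all`` series plus one series per stratum
    level of each stratifier; per-week stratum counts sum exactly to the
    overall count by construction.
    """
    if calendar is None:
        calendar = week_grid()
    calendar = pd.DatetimeIndex(calendar)
    strata = list(strata or [])
    unknown = [s for s in strata if s not in VALID_STRATIFIERS]
    if unknown:
        raise ValidationError(
            f"unknown stratifier(s) {unknown}; valid: {VALID_STRATIFIERS}"
        )
    m = len(calendar)
    overall = np.zeros(m, dtype=int)
    fixed_counts: dict[str, dict[str, np.ndarray]] = {
        s: {} for s in strata if s != "age_band"
    }
    band_counts: dict[str, np.ndarray] = {}

    if events is not None and len(events):
        by_patient = dict(tuple(events.groupby("patient_id", sort=False)))
    else:
        by_patient = {}
    empty = pd.DataFrame(columns=["patient_id", "event_date", "code"])

    for _, patient in patients.iterrows():
        ev = by_patient.get(patient["patient_id"], empty)
        mask = eligibility_mask(patient, ev, rule, calendar, codelists)
        if not mask.any():
            continue
        overall += mask
        for s in fixed_counts:
            level = str(patient[s])
            fixed_counts[s].setdefault(level, np.zeros(m, dtype=int))
            fixed_counts[s][level] += mask
        if "age_band" in strata:
            ages = _ages_at(calendar, pd.Timestamp(patient["birth_date"]))
            for a in np.unique(ages[mask]):
                b = age_band(a)
                band_counts.setdefault(b, np.zeros(m, dtype=int))
                band_counts[b] += mask & (ages == a)

    rows = [
        pd.DataFrame(
            {
                "condition": rule.condition,
                "stratifier": "overall",
                "stratum": "all",
                "week_start": calendar,
                "count": overall,
            }
        )
    ]
    for s, levels in fixed_counts.items():
        for level in sorted(levels):
            rows.append(
                pd.DataFrame(
                    {
                        "condition": rule.condition,
                        "stratifier": s,
                        "stratum": level,
                        "week_start": calendar,
                        "count": levels[level],
                    }
                )
            )
    for b in sorted(band_counts):
        rows.append(
            pd.DataFrame(
                {
                    "condition": rule.condition,
                    "stratifier": "age_band",
                    "stratum": b,
                    "week_start": calendar,
                    "count": band_counts[b],
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
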