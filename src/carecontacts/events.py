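"""Outcome event extraction from coded records.

Most outcomes are "any matching morbidity code", with multiple records
within a condition-specific window (7 days for mental health and diabetic
emergencies, 14 days for exacerbations and alcohol, 6 months or 1 year for
cardiovascular events) merged into a single episode dated at its first
record.  Exceptions: heart failure counts only a person's first-ever
diagnosis, and asthma/COPD exacerbations are composite outcomes requiring
a qualifying prescription (oral corticosteroid, or antibiotic for COPD)
close to the morbidity record.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .codelists import Codelist
from .errors import ValidationError

REQUIRES_PRESCRIPTION = ("none", "ocs", "ocs_or_antibiotic")


@dataclass
class OutcomeDefinition:
    """How one condition's outcome events are identified."""

    condition: str
    morbidity_codelist: str
    prescription_codelists: tuple[str, ...] = ()
    dedup_window_days: int | None = 7
    first_ever_mode: bool = False
    requires_prescription: str = "none"
    co_occurrence_window_days: int = 0
    #: a prescription only qualifies as "new" when none of the same class
    #: occurred in the preceding window (0 disables the check)
    new_rx_washout_days: int = 0

    def __post_init__(self):
        if self.requires_prescription not in REQUIRES_PRESCRIPTION:
            raise ValidationError(
                f"unknown requires_prescription {self.requires_prescription!r}"
            )
        if not self.first_ever_mode:
            if self.dedup_window_days is None or self.dedup_window_days <= 0:
                raise ValidationError(
                    f"{self.condition}: dedup_window_days must be positive"
                )
        if self.requires_prescription != "none" and not self.prescription_codelists:
            raise ValidationError(
                f"{self.condition}: prescription codelist(s) required"
            )


def match_codes(events: pd.DataFrame, codelist: Codelist) -> pd.DataFrame:
    """Rows of ``events`` whose code belongs to ``codelist``, order
    preserved."""
    if len(events) == 0:
        return events.copy()
    return events[events["code"].isin(codelist.codes)].copy()


def _gap(a, b) -> float:
    """Gap between two date-like or numeric values, in days."""
    d = b - a
    return d.days if hasattr(d, "days") else float(d)


def deduplicate(dates, window_days: int) -> list:
    """Collapse records within ``window_days`` of each other into episodes.

    The chain rule is greedy and transitive: a record starts a new episode
    iff its gap from the *immediately preceding record* (not the episode
    start) exceeds the window; a gap exactly equal to the window stays in
    the same episode.  Returns the first date of each episode.
    """
    dates = list(dates)
    out = []
    prev = None
    for d in dates:
        if prev is not None and _gap(prev, d) < 0:
            raise ValidationError("dates must be sorted ascending")
        if prev is None or _gap(prev, d) > window_days:
            out.append(d)
        prev = d
    return out


def first_ever(dates, study_start=None, study_end=None):
    """The first-ever record date, or ``None``.

    An event is emitted only when the first record falls inside the study
    calendar; an earlier out-of-window record disqualifies all later ones
    (the person's first-ever diagnosis predates the study, so nothing seen
    during it is incident).
    """
    dates = list(dates)
    if not dates:
        return None
    first = dates[0]
    for d in dates[1:]:
        if _gap(first, d) < 0:
            raise ValidationError("dates must be sorted ascending")
    if study_start is not None and _gap(study_start, first) < 0:
        return None
    if study_end is not None and _gap(first, study_end) < 0:
        return None
    return first


def _new_prescriptions(rx: pd.DataFrame, washout_days: int) -> pd.DataFrame:
    """Keep prescriptions with no same-class issue in the prior washout."""
    if washout_days <= 0 or len(rx) == 0:
        return rx
    keep_idx = []
    for _, grp in rx.groupby("rx_class", sort=False):
        grp = grp.sort_values("event_date", kind="stable")
        prev = None
        for idx, row in grp.iterrows():
            if prev is None or _gap(prev, row["event_date"]) > washout_days:
                keep_idx.append(idx)
            prev = row["event_date"]
    return rx.loc[sorted(keep_idx)]


def extract_exacerbations(
    morbidity: pd.DataFrame,
    prescriptions: pd.DataFrame,
    definition: OutcomeDefinition,
    codelists: dict[str, Codelist],
) -> pd.DataFrame:
    """Composite code+prescription outcome (asthma/COPD exacerbations).

    A morbidity record qualifies iff a qualifying (optionally "new")
    prescription exists within +/- ``co_occurrence_window_days``;
    qualifying records are then deduplicated with the condition's window.
    Returns (patient_id, condition, event_date) episode rows.
    """
    if definition.requires_prescription == "none":
        raise ValidationError(
            f"{definition.condition}: extract_exacerbations needs a prescription rule"
        )
    morb = match_codes(morbidity, codelists[definition.morbidity_codelist])
    rx_parts = []
    for name in definition.prescription_codelists:
        part = match_codes(prescriptions, codelists[name])
        part = part.assign(rx_class=name)
        rx_parts.append(part)
    rx = (
        pd.concat(rx_parts, ignore_index=True)
        if rx_parts
        else pd.DataFrame(columns=["patient_id", "event_date", "rx_class"])
    )
    rx = _new_prescriptions(rx, definition.new_rx_washout_days)

    out_rows = []
    rx_by_patient = dict(tuple(rx.groupby("patient_id", sort=False))) if len(rx) else {}
    for pid, grp in morb.groupby("patient_id", sort=False):
        prx = rx_by_patient.get(pid)
        if prx is None:
            continue
        rx_dates = list(prx["event_date"])
        qualified = sorted(
            d
            for d in grp["event_date"]
            if any(
                abs(_gap(d, r)) <= definition.co_occurrence_window_days
                for r in rx_dates
            )
        )
        for episode in deduplicate(qualified, definition.dedup_window_days):
            out_rows.append((pid, definition.condition, episode))
    return pd.DataFrame(
        out_rows, columns=["patient_id", "condition", "event_date"]
    )


def extract_events(
    clinical_events: pd.DataFrame,
    prescriptions: pd.DataFrame | None,
    definition: OutcomeDefinition,
    codelists: dict[str, Codelist],
    study_start=None,
    study_end=None,
) -> pd.DataFrame:
    """All outcome episodes for one condition across patients.

    Deduplication runs over each patient's full record before the result is
    restricted to the study calendar, so records preceding the study still
    chain with (or, for first-ever outcomes, disqualify) in-study ones.
    """
    if study_start is not None:
        study_start = pd.Timestamp(study_start)
    if study_end is not None:
        study_end = pd.Timestamp(study_end)
    if definition.requires_prescription != "none":
        if prescriptions is None:
            raise ValidationError(f"{definition.condition}: prescriptions required")
        out = extract_exacerbations(
            clinical_events, prescriptions, definition, codelists
        )
    else:
        morb = match_codes(clinical_events, codelists[definition.morbidity_codelist])
        rows = []
        for pid, grp in morb.groupby("patient_id", sort=False):
            dates = sorted(grp["event_date"])
            if definition.first_ever_mode:
                d = first_ever(dates, study_start=study_start, study_end=study_end)
                if d is not None:
                    rows.append((pid, definition.condition, d))
            else:
                for episode in deduplicate(dates, definition.dedup_window_days):
                    rows.append((pid, definition.condition, episode))
        out = pd.DataFrame(rows, columns=["patient_id", "condition", "event_date"])
    if len(out):
        if study_start is not None:
            out = out[out["event_date"] >= pd.Timestamp(study_start)]
        if study_end is not None:
            out = out[out["event_date"] <= pd.Timestamp(study_end)]
    return out.sort_values(["patient_id", "event_date"], kind="stable").reset_index(
        drop=True
    )
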