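"""Synthetic longitudinal primary-care EHR generator.

This module is the pipeline's only required data source.  It simulates a
UK-like registered population (demographics drawn from published general
denominator margins), registration churn, chronic-condition status coded as
dated diagnosis records, and weekly contact processes with a fully known
generating model:

    logit p_t = baseline + trend * t + season(month_t)
                + [t >= t0] * (step + slope * (t - t0)) + eps_t

where ``t`` counts study weeks, ``t0`` is the first with-restrictions week
and ``eps_t`` is optional AR(1) noise on the logit scale.  The linear
predictor and weekly probability are exposed as a truth oracle so that
statistical tests can compare estimates against known parameters.

Two modes are provided: individual-level tables (patients / clinical
events / prescriptions) for exercising the full cohort and extraction
pipeline, and a fast aggregated mode drawing weekly binomial counts
directly.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ValidationError
from .series import WeeklySeries
from .weekgrid import GRID_ANCHOR, STUDY_END, as_date, week_grid, week_index

# Demographic margins of the general (11+) denominator population at the
# start of 2017; counts as published for a ~9.9M-person UK primary-care
# population, normalised to probabilities at config construction.
_AGE_BAND_COUNTS = {
    "11-20": 1_233_387,
    "21-30": 1_455_550,
    "31-40": 1_559_933,
    "41-50": 1_577_507,
    "51-60": 1_520_720,
    "61-70": 1_165_390,
    "71-80": 833_570,
    "81-90": 426_769,
    "91-100": 91_077,
}
_SEX_COUNTS = {"female": 4_921_693, "male": 4_942_210}
_ETHNICITY_COUNTS = {
    "White": 4_814_510,
    "South Asian": 425_917,
    "Black": 261_552,
    "Other": 147_583,
    "Mixed": 94_174,
    "Missing": 4_120_167,
}
_REGION_COUNTS = {
    "North East": 343_510,
    "North West": 1_690_063,
    "Yorkshire and the Humber": 371_809,
    "East Midlands": 259_468,
    "West Midlands": 1_571_832,
    "East of England": 464_376,
    "South West": 1_185_045,
    "South Central": 1_242_192,
    "London": 1_842_724,
    "South East Coast": 827_239,
    "Northern Ireland": 47_713,
}

CHRONIC_CODES = {
    "diabetes": "DIABETES_DX",
    "asthma": "ASTHMA_DX",
    "copd": "COPD_DX",
    "smoking": "SMOKING",
}

# independent RNG streams per generation stage
_STREAM_POPULATION = 0
_STREAM_CHRONIC = 1
_STREAM_CONTACTS = 2
_STREAM_WEEKLY = 3


def _normalise(counts: dict[str, float]) -> dict[str, float]:
    total = float(sum(counts.values()))
    return {k: v / total for k, v in counts.items()}


def default_demographic_margins() -> dict[str, dict[str, float]]:
    """Categorical distributions for age band, sex, region and ethnicity."""
    return {
        "age_band": _normalise(_AGE_BAND_COUNTS),
        "sex": _normalise(_SEX_COUNTS),
        "region": _normalise(_REGION_COUNTS),
        "ethnicity": _normalise(_ETHNICITY_COUNTS),
    }


def default_chronic_prevalence() -> dict[str, float]:
    # UK-plausible adult prevalences: diagnosed diabetes ~5.6%, currently
    # treated asthma ~9%, diagnosed COPD ~2%, ever-smoker history ~25%.
    return {"diabetes": 0.056, "asthma": 0.09, "copd": 0.02, "smoking": 0.25}


def seasonal_month_effects(amplitude: float) -> tuple[float, ...]:
    """Sinusoidal month offsets on the logit scale with January fixed at 0."""
    return tuple(amplitude * math.sin(2.0 * math.pi * m / 12.0) for m in range(12))


@dataclass
class SimulationConfig:
    """Parameters of one simulated contact process and its population."""

    n_patients: int = 10_000
    calendar_start: dt.date = GRID_ANCHOR
    calendar_end: dt.date = STUDY_END
    restriction_week_start: dt.date = dt.date(2020, 3, 29)
    #: log-odds that a registered person has >= 1 contact in a week
    baseline_logit: float = math.log(0.0025 / 0.9975)
    trend_per_week: float = 0.0
    #: 12 log-odds offsets, January fixed at 0
    month_effects: tuple[float, ...] = (0.0,) * 12
    step_log_or: float = 0.0
    slope_log_or_per_week: float = 0.0
    ar_rho: float = 0.0
    ar_sigma: float = 0.0
    demographic_margins: dict[str, dict[str, float]] = field(
        default_factory=default_demographic_margins
    )
    chronic_prevalence: dict[str, float] = field(
        default_factory=default_chronic_prevalence
    )
    #: annual probability of deregistering
    registration_churn: float = 0.05
    condition: str = "contact"
    contact_codes: tuple[str, ...] = ("CONTACT_1",)
    seed: int = 0

    def __post_init__(self):
        self.calendar_start = as_date(self.calendar_start)
        self.calendar_end = as_date(self.calendar_end)
        self.restriction_week_start = as_date(self.restriction_week_start)
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")
        if not (
            self.calendar_start < self.restriction_week_start < self.calendar_end
        ):
            raise ValidationError(
                "require calendar_start < restriction_week_start < calendar_end"
            )
        if len(self.month_effects) != 12:
            raise ValidationError("month_effects must have 12 entries")
        if abs(self.month_effects[0]) > 1e-12:
            raise ValidationError("month_effects[January] must be 0 (reference)")
        if not (-1.0 < self.ar_rho < 1.0):
            raise ValidationError("ar_rho must lie in (-1, 1)")
        if self.ar_sigma < 0:
            raise ValidationError("ar_sigma must be nonnegative")
        for margin, dist in self.demographic_margins.items():
            if any(p < 0 or p > 1 for p in dist.values()):
                raise ValidationError(f"margin {margin!r}: probabilities outside [0,1]")
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValidationError(
                    f"margin {margin!r} does not sum to 1 (got {sum(dist.values())!r})"
                )
        for cond, p in self.chronic_prevalence.items():
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"chronic prevalence for {cond!r} outside [0,1]")
        if not (0.0 <= self.registration_churn <= 1.0):
            raise ValidationError("registration_churn must be in [0,1]")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=int(seed))


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def _sample_categorical(
    rng: np.random.Generator, dist: dict[str, float], n: int
) -> np.ndarray:
    cats = np.array(list(dist.keys()), dtype=object)
    probs = np.array(list(dist.values()), dtype=float)
    probs = probs / probs.sum()
    return cats[rng.choice(len(cats), size=n, p=probs)]


def generate_population(config: SimulationConfig) -> pd.DataFrame:
    """Simulate the registered population.

    Birth dates are simulated at year resolution and materialised as July 1
    of the birth year, mirroring the precision of de-identified EHR extracts;
    age computations elsewhere in the package use this convention.
    Registration spells always overlap the study calendar; deregistration
    and death are drawn from simple exponential hazards (annual
    ``registration_churn`` for deregistration, a Gompertz-like age gradient
    for death).
    """
    n = config.n_patients
    rng = _rng(config, _STREAM_POPULATION)
    margins = config.demographic_margins

    band = _sample_categorical(rng, margins["age_band"], n)
    lo = np.array([int(b.split("-")[0]) for b in band])
    hi = np.array([int(b.split("-")[1]) for b in band])
    age = rng.integers(lo, hi + 1)  # age at calendar_start
    start = config.calendar_start
    before_july = (start.month, start.day) < (7, 1)
    birth_year = start.year - age - (1 if before_july else 0)
    birth = pd.to_datetime({"year": birth_year, "month": 7, "day": 1})

    sex = _sample_categorical(rng, margins["sex"], n)
    region = _sample_categorical(rng, margins["region"], n)
    ethnicity = _sample_categorical(rng, margins["ethnicity"], n)

    # registration: a churn-sized share registers during the study, the rest
    # have been registered for up to a decade beforehand
    study_years = (config.calendar_end - config.calendar_start).days / 365.25
    p_new = min(0.9, config.registration_churn * study_years)
    is_new = rng.random(n) < p_new
    span_days = (config.calendar_end - config.calendar_start).days
    reg_offset = np.where(
        is_new,
        rng.integers(0, max(span_days - 30, 1), size=n),
        -rng.integers(1, int(10 * 365.25), size=n),
    )
    reg_start = pd.Timestamp(config.calendar_start) + pd.to_timedelta(
        reg_offset, unit="D"
    )
    reg_start = np.maximum(reg_start, birth)  # cannot register before birth

    # deregistration: exponential stay conditioned on still being
    # registered when the spell reaches the study calendar (memorylessness
    # keeps this a plain exponential beyond that point)
    min_days = np.maximum(
        np.asarray(
            (pd.Timestamp(config.calendar_start) - pd.DatetimeIndex(reg_start)).days
        ),
        0,
    )
    if config.registration_churn > 0:
        stay_days = min_days + rng.exponential(
            365.25 / config.registration_churn, size=n
        )
    else:
        stay_days = np.full(n, np.inf)
    reg_end = reg_start + pd.to_timedelta(
        np.ceil(stay_days).clip(max=50_000), unit="D"
    )
    reg_end = reg_end.where(reg_end <= pd.Timestamp(config.calendar_end), pd.NaT)

    death_hazard = 5e-5 * np.exp(0.085 * age)  # per year
    death_years = rng.exponential(1.0 / death_hazard)
    death = pd.Timestamp(config.calendar_start) + pd.to_timedelta(
        np.ceil(death_years * 365.25).clip(max=50_000), unit="D"
    )
    death = death.where(death <= pd.Timestamp(config.calendar_end), pd.NaT)

    return pd.DataFrame(
        {
            "patient_id": [f"P{i:07d}" for i in range(n)],
            "birth_date": birth,
            "sex": sex,
            "region": region,
            "ethnicity": ethnicity,
            "registration_start": pd.DatetimeIndex(reg_start),
            "registration_end": pd.DatetimeIndex(reg_end),
            "death_date": pd.DatetimeIndex(death),
        }
    )


def generate_chronic_codes(
    patients: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Dated chronic-condition diagnosis records (diabetes, asthma, COPD,
    smoking history).

    Status is materialised as a first diagnosis code either at registration
    (prevalent cases, 70%) or at a uniformly sampled onset during the study,
    so that "from the date of their first record" denominator-entry logic is
    exercised.  Asthma additionally receives roughly annual follow-up codes
    (80% per year) so currency windows open, lapse and re-open.
    """
    n = len(patients)
    rng = _rng(config, _STREAM_CHRONIC)
    end = pd.Timestamp(config.calendar_end)
    rows: list[pd.DataFrame] = []
    reg = patients["registration_start"]
    for cond, prev in sorted(config.chronic_prevalence.items()):
        code = CHRONIC_CODES.get(cond, f"{cond.upper()}_DX")
        has = rng.random(n) < prev
        prevalent = rng.random(n) < 0.7
        span = (end - reg).dt.days.clip(lower=1).to_numpy()
        onset_off = rng.integers(0, span)
        onset = reg.where(prevalent, reg + pd.to_timedelta(onset_off, unit="D"))
        sub = pd.DataFrame(
            {
                "patient_id": patients.loc[has, "patient_id"],
                "event_date": onset[has],
                "code": code,
                "source": "diagnosis",
            }
        )
        rows.append(sub)
        if cond == "asthma" and len(sub):
            for k in range(1, int(np.ceil((end - reg.min()).days / 365.25)) + 1):
                keep = rng.random(len(sub)) < 0.8
                follow = sub.loc[keep].copy()
                follow["event_date"] = follow["event_date"] + pd.Timedelta(
                    days=365 * k
                )
                follow = follow[follow["event_date"] <= end]
                if len(follow):
                    rows.append(follow)
    out = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["patient_id", "event_date", "code", "source"]
    )
    return out.sort_values(["patient_id", "event_date"], kind="stable").reset_index(
        drop=True
    )


def linear_predictor(
    config: SimulationConfig,
    week_starts,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Truth oracle: eta and p for each requested week.

    AR(1) noise (when ``ar_sigma > 0`` and an ``rng`` is supplied) is
    generated over the *contiguous* calendar-week range spanning the request
    and initialised at its stationary distribution, so requesting
    non-contiguous weeks (e.g. skipping the adjustment-to-restrictions gap)
    still yields a correlation structure indexed by true calendar time.
    """
    ws = pd.DatetimeIndex(week_starts)
    idx = np.array([week_index(w) for w in ws])
    t_origin = week_index(config.calendar_start)
    t0 = week_index(config.restriction_week_start)
    t = idx - t_origin
    post = idx >= t0
    month = ws.month.to_numpy()
    eta = (
        config.baseline_logit
        + config.trend_per_week * t
        + np.asarray(config.month_effects)[month - 1]
        + post * (config.step_log_or + config.slope_log_or_per_week * (idx - t0))
    )
    if config.ar_sigma > 0 and rng is not None:
        lo, hi = idx.min(), idx.max()
        m = hi - lo + 1
        eps = np.empty(m)
        eps[0] = rng.normal(
            0.0, config.ar_sigma / math.sqrt(1.0 - config.ar_rho**2)
        )
        shocks = rng.normal(0.0, config.ar_sigma, size=m - 1)
        for j in range(1, m):
            eps[j] = config.ar_rho * eps[j - 1] + shocks[j - 1]
        eta = eta + eps[idx - lo]
    return pd.DataFrame({"week_start": ws, "eta": eta, "p": expit(eta)})


def generate_contact_events(
    patients: pd.DataFrame, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Individual-level contact records.

    For every week a patient is registered (and alive) a Bernoulli draw with
    the oracle probability decides whether the patient has >= 1 contact; a
    drawn contact becomes a single clinical event with a code from the
    condition's codelist, dated uniformly within the week.  At most one
    synthetic contact per person-week is generated, matching the binomial
    "proportion of the population with contacts" outcome the downstream
    models fit.

    Returns ``(events, truth)`` where ``truth`` carries eta and p per week.
    """
    if len(patients) == 0:
        raise ValidationError("patients table is empty")
    rng = _rng(config, _STREAM_CONTACTS)
    ws = week_grid(config.calendar_start, config.calendar_end)
    truth = linear_predictor(config, ws, rng=rng)
    p = truth["p"].to_numpy()

    reg_start = patients["registration_start"].to_numpy()
    reg_end = patients["registration_end"].to_numpy()
    death = patients["death_date"].to_numpy()
    pids = patients["patient_id"].to_numpy()
    codes = np.asarray(config.contact_codes, dtype=object)

    chunks: list[pd.DataFrame] = []
    for j, w in enumerate(ws):
        w64 = np.datetime64(w)
        active = (reg_start <= w64) & (
            (pd.isna(reg_end)) | (reg_end > w64)
        ) & ((pd.isna(death)) | (death > w64))
        draws = rng.random(len(patients)) < p[j]
        hit = active & draws
        k = int(hit.sum())
        if k == 0:
            continue
        offsets = rng.integers(0, 7, size=k)
        dates = pd.Series(pd.Timestamp(w) + pd.to_timedelta(offsets, unit="D"))
        # keep the event inside the registration/life span when a spell ends
        # mid-week (rare edge; preserves the drawn count)
        ends = pd.DataFrame(
            {"e": reg_end[hit], "d": death[hit]}, index=dates.index
        ).min(axis=1)
        ub = ends - pd.Timedelta(days=1)
        clip = ub.notna() & (dates > ub)
        dates[clip] = ub[clip]
        chunks.append(
            pd.DataFrame(
                {
                    "patient_id": pids[hit],
                    "event_date": pd.DatetimeIndex(dates),
                    "code": codes[rng.integers(0, len(codes), size=k)],
                    "source": "diagnosis",
                }
            )
        )
    if chunks:
        events = pd.concat(chunks, ignore_index=True)
        events = events.sort_values(
            ["patient_id", "event_date"], kind="stable"
        ).reset_index(drop=True)
    else:
        events = pd.DataFrame(columns=["patient_id", "event_date", "code", "source"])
    return events, truth


def matched_prescriptions(
    events: pd.DataFrame,
    code: str,
    config: SimulationConfig,
    prob: float = 1.0,
    alternate_code: str | None = None,
) -> pd.DataFrame:
    """Same-day prescriptions accompanying contact events (for composite
    exacerbation outcomes).  With ``alternate_code`` set, prescriptions
    alternate randomly between the two codes (e.g. oral corticosteroid or
    antibiotic for COPD)."""
    rng = _rng(config, _STREAM_CONTACTS + 10)
    keep = rng.random(len(events)) < prob
    rx = events.loc[keep, ["patient_id", "event_date"]].copy()
    if alternate_code is None:
        rx["code"] = code
    else:
        rx["code"] = np.where(
            rng.random(len(rx)) < 0.5, code, alternate_code
        )
    rx["source"] = "prescription"
    return rx.reset_index(drop=True)


def generate_weekly_counts(
    config: SimulationConfig,
    n_weeks_pre: int,
    n_weeks_post: int,
    denominator: int,
) -> WeeklySeries:
    """Aggregated mode: weekly binomial counts drawn directly from the
    oracle probabilities, bypassing individual records.

    Pre weeks run consecutively from the calendar start; post weeks run
    consecutively from the restriction week, so the adjustment-to-
    restrictions gap is simply absent from the table (the default
    166-pre / 16-post request reproduces the 182 analysed study weeks).
    """
    if n_weeks_pre < 0 or n_weeks_post < 0:
        raise ValidationError("week counts must be nonnegative")
    if n_weeks_pre + n_weeks_post == 0:
        raise ValidationError("at least one week must be requested")
    if denominator <= 0:
        raise ValidationError("denominator must be positive")
    rng = _rng(config, _STREAM_WEEKLY)
    start = pd.Timestamp(config.calendar_start)
    pre = [start + pd.Timedelta(days=7 * i) for i in range(n_weeks_pre)]
    r0 = pd.Timestamp(config.restriction_week_start)
    post = [r0 + pd.Timedelta(days=7 * i) for i in range(n_weeks_post)]
    ws = pd.DatetimeIndex(sorted(set(pre) | set(post)), name="week_start")
    truth = linear_predictor(config, ws, rng=rng)
    counts = rng.binomial(denominator, truth["p"].to_numpy())
    data = pd.DataFrame(
        {
            "week_start": ws,
            "count": counts,
            "denominator": int(denominator),
            "proportion": counts / float(denominator),
        }
    )
    return WeeklySeries(
        condition=config.condition, stratum="all", data=data, truth=truth
    )


def write_simulation(
    outdir,
    patients: pd.DataFrame,
    clinical_events: pd.DataFrame,
    prescriptions: pd.DataFrame,
    truth: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write the simulated tables as ISO-8601-dated CSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in {
        "patients": patients,
        "clinical_events": clinical_events,
        "prescriptions": prescriptions,
    }.items():
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False, date_format="%Y-%m-%d")
        paths[name] = p
    if truth is not None:
        p = outdir / "weekly_truth.csv"
        truth.to_csv(p, index=False, date_format="%Y-%m-%d")
        paths["weekly_truth"] = p
    return paths
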