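"""Default condition registry.

One entry per study outcome: its denominator rule, outcome definition,
generator scenario (baseline weekly contact rate per million persons in
the condition's denominator, step odds ratio at the restrictions, weekly
recovery odds ratio) and presentation censoring thresholds.

Generator scenario values are anchored to the published study-scale
estimates: baselines are the modelled "without restrictions" weekly
contacts per million for the late-April snapshot week; step ORs are the
reported interrupted time-series step estimates (for COPD exacerbations,
where no step OR is printed, the ratio of the with/without expected weekly
contacts, ~0.54); recovery ORs follow the reported 1-2% weekly recovery
for mental health conditions and 3-5% for acute alcohol-related events and
unstable angina, with 2% for the remainder.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field

from .codelists import Codelist
from .cohort import CohortRule
from .events import OutcomeDefinition
from .synthetic import (
    CHRONIC_CODES,
    SimulationConfig,
    seasonal_month_effects,
)

OCS_CODES = ("RX_OCS_1", "RX_OCS_2")
ANTIBIOTIC_CODES = ("RX_ABX_1", "RX_ABX_2")


@dataclass(frozen=True)
class ConditionSpec:
    name: str
    label: str
    min_age_years: int = 11
    chronic_mode: str = "none"
    chronic_codelist: str | None = None
    requires_smoking_history: bool = False
    dedup_window_days: int | None = 7
    first_ever_mode: bool = False
    requires_prescription: str = "none"
    prescription_codelists: tuple[str, ...] = ()
    new_rx_washout_days: int = 0
    n_morbidity_codes: int = 3
    baseline_weekly_per_million: float = 100.0
    step_or: float = 1.0
    recovery_or: float = 1.02
    weekly_censor_threshold: int = 100
    cumulative_censor_threshold: int = 100
    pre_period_start: dt.date = dt.date(2017, 1, 1)

    @property
    def morbidity_codes(self) -> tuple[str, ...]:
        stem = self.name.upper()
        return tuple(f"{stem}_{i}" for i in range(1, self.n_morbidity_codes + 1))

    def cohort_rule(self) -> CohortRule:
        return CohortRule(
            condition=self.name,
            min_age_years=self.min_age_years,
            chronic_mode=self.chronic_mode,
            chronic_codelist=self.chronic_codelist,
            requires_smoking_history=self.requires_smoking_history,
        )

    def outcome_definition(self) -> OutcomeDefinition:
        return OutcomeDefinition(
            condition=self.name,
            morbidity_codelist=self.name,
            prescription_codelists=self.prescription_codelists,
            dedup_window_days=self.dedup_window_days,
            first_ever_mode=self.first_ever_mode,
            requires_prescription=self.requires_prescription,
            new_rx_washout_days=self.new_rx_washout_days,
        )

    def simulation_config(
        self,
        seed: int = 0,
        season_amplitude: float = 0.1,
        ar_sigma: float = 0.05,
        ar_rho: float = 0.3,
        trend_per_week: float = 0.0,
        **overrides,
    ) -> SimulationConfig:
        p = self.baseline_weekly_per_million / 1e6
        defaults = dict(
            baseline_logit=math.log(p / (1.0 - p)),
            step_log_or=math.log(self.step_or),
            slope_log_or_per_week=math.log(self.recovery_or),
            month_effects=seasonal_month_effects(season_amplitude),
            ar_sigma=ar_sigma,
            ar_rho=ar_rho,
            trend_per_week=trend_per_week,
            condition=self.name,
            contact_codes=self.morbidity_codes,
            seed=seed,
        )
        defaults.update(overrides)
        return SimulationConfig(**defaults)


_MH = dict(recovery_or=1.015)  # mental health: 1-2% weekly recovery

CONDITIONS: dict[str, ConditionSpec] = {
    s.name: s
    for s in [
        ConditionSpec(
            name="diabetic_emergency",
            label="Diabetic emergency",
            chronic_mode="from_first_code",
            chronic_codelist="diabetes",
            dedup_window_days=7,
            baseline_weekly_per_million=39,
            step_or=0.35,
            recovery_or=1.02,
        ),
        ConditionSpec(
            name="anxiety",
            label="Anxiety",
            baseline_weekly_per_million=1816,
            step_or=0.67,
            **_MH,
        ),
        ConditionSpec(
            name="depression",
            label="Depression",
            baseline_weekly_per_million=2451,
            step_or=0.53,
            **_MH,
        ),
        ConditionSpec(
            name="self_harm",
            label="Self-harm",
            baseline_weekly_per_million=217,
            step_or=0.56,
            pre_period_start=dt.date(2019, 1, 1),
            **_MH,
        ),
        ConditionSpec(
            name="severe_mental_illness",
            label="Severe mental illness",
            baseline_weekly_per_million=184,
            step_or=0.80,
            **_MH,
        ),
        ConditionSpec(
            name="eating_disorder",
            label="Eating disorder",
            baseline_weekly_per_million=44,
            step_or=0.62,
            **_MH,
        ),
        ConditionSpec(
            name="ocd",
            label="Obsessive-compulsive disorder",
            baseline_weekly_per_million=29,
            step_or=0.69,
            weekly_censor_threshold=10,
            **_MH,
        ),
        ConditionSpec(
            name="acute_alcohol",
            label="Acute alcohol-related event",
            min_age_years=18,
            dedup_window_days=14,
            baseline_weekly_per_million=13,
            step_or=0.98,
            recovery_or=1.04,
            weekly_censor_threshold=10,
        ),
        ConditionSpec(
            name="asthma_exacerbation",
            label="Asthma exacerbation",
            chronic_mode="asthma_current",
            chronic_codelist="asthma",
            dedup_window_days=14,
            requires_prescription="ocs",
            prescription_codelists=("ocs",),
            baseline_weekly_per_million=4636,
            step_or=0.88,
            # contacts kept falling relative to expectation: weekly ratio
            # derived from the published late-April and late-June
            # with/without expected-count ratios ((0.691/0.780)^(1/9))
            recovery_or=0.987,
        ),
        ConditionSpec(
            name="copd_exacerbation",
            label="COPD exacerbation",
            min_age_years=41,
            chronic_mode="from_first_code",
            chronic_codelist="copd",
            requires_smoking_history=True,
            dedup_window_days=14,
            requires_prescription="ocs_or_antibiotic",
            prescription_codelists=("ocs", "antibiotic"),
            new_rx_washout_days=28,
            baseline_weekly_per_million=7863,
            step_or=0.537,
            recovery_or=1.02,
        ),
        ConditionSpec(
            name="myocardial_infarction",
            label="Myocardial infarction",
            min_age_years=31,
            dedup_window_days=365,
            baseline_weekly_per_million=45,
            step_or=0.72,
            weekly_censor_threshold=10,
        ),
        ConditionSpec(
            name="unstable_angina",
            label="Unstable angina",
            min_age_years=31,
            dedup_window_days=183,
            baseline_weekly_per_million=5,
            step_or=0.72,
            recovery_or=1.04,
            weekly_censor_threshold=10,
            cumulative_censor_threshold=10,
        ),
        ConditionSpec(
            name="transient_ischaemic_attack",
            label="Transient ischaemic attack",
            min_age_years=31,
            dedup_window_days=183,
            baseline_weekly_per_million=37,
            step_or=0.63,
            weekly_censor_threshold=10,
        ),
        ConditionSpec(
            name="stroke",
            label="Stroke",
            min_age_years=31,
            dedup_window_days=365,
            baseline_weekly_per_million=88,
            step_or=0.59,
        ),
        ConditionSpec(
            name="heart_failure",
            label="Heart failure",
            min_age_years=31,
            dedup_window_days=None,
            first_ever_mode=True,
            baseline_weekly_per_million=279,
            step_or=0.62,
        ),
        ConditionSpec(
            name="venous_thromboembolism",
            label="Venous thromboembolism",
            min_age_years=31,
            dedup_window_days=365,
            baseline_weekly_per_million=67,
            step_or=0.94,
            weekly_censor_threshold=10,
        ),
    ]
}


def get_condition(name: str) -> ConditionSpec:
    try:
        return CONDITIONS[name]
    except KeyError:
        raise KeyError(
            f"unknown condition {name!r}; available: {sorted(CONDITIONS)}"
        ) from None


def all_condition_names() -> list[str]:
    return list(CONDITIONS)


def default_codelists() -> dict[str, Codelist]:
    """Synthetic-namespace codelists for every registry condition plus the
    chronic-condition and prescription lists."""
    out: dict[str, Codelist] = {}
    for spec in CONDITIONS.values():
        out[spec.name] = Codelist(
            name=spec.name, kind="morbidity", codes=frozenset(spec.morbidity_codes)
        )
    for cond, code in CHRONIC_CODES.items():
        out[cond] = Codelist(name=cond, kind="morbidity", codes=frozenset({code}))
    out["ocs"] = Codelist(name="ocs", kind="prescription", codes=frozenset(OCS_CODES))
    out["antibiotic"] = Codelist(
        name="antibiotic", kind="prescription", codes=frozenset(ANTIBIOTIC_CODES)
    )
    return out
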