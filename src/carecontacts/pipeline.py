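"""End-to-end orchestration: simulate -> cohorts -> events -> series ->
ITS -> counterfactuals -> reports, from a single run configuration.

Two execution modes exist.  ``aggregated`` draws weekly binomial counts
directly from each condition's generating scenario (fast; the default for
statistical work).  ``ehr`` simulates individual-level patient, clinical
event and prescription tables and runs the full cohort/extraction pipeline
on them.  Conditions are processed independently with per-condition
substreams of the run seed, so results are deterministic and independent
of processing order.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import build_denominators
from .counterfactual import (
    counterfactual_difference,
    counterfactual_table,
    fit_poisson,
    round_and_censor,
)
from .errors import PipelineError, ValidationError
from .events import extract_events
from .its import ITSDesign, default_sensitivity_grid, fit_its, recovery_or, step_or
from .scenarios import CONDITIONS, all_condition_names, default_codelists, get_condition
from .series import historical_average, suppress_small_cells, weekly_series
from .synthetic import (
    generate_chronic_codes,
    generate_contact_events,
    generate_population,
    generate_weekly_counts,
    matched_prescriptions,
    write_simulation,
)
from .weekgrid import week_grid, week_start

log = logging.getLogger(__name__)

DEFAULT_SNAPSHOTS = (dt.date(2020, 4, 26), dt.date(2020, 6, 28))


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    seed: int
    mode: str = "aggregated"
    conditions: list[str] = field(default_factory=all_condition_names)
    outdir: str | None = None
    # aggregated mode
    denominator: int = 1_000_000
    n_weeks_pre: int = 166
    n_weeks_post: int = 16
    # ehr mode
    n_patients: int = 20_000
    strata: list[str] = field(default_factory=list)
    #: multiplier applied to per-person weekly contact probabilities in ehr
    #: mode so a small simulated panel yields countable weekly events;
    #: step/recovery odds ratios are unaffected
    ehr_rate_multiplier: float = 50.0
    # generator noise/seasonality shared by both modes
    season_amplitude: float = 0.1
    ar_sigma: float = 0.05
    ar_rho: float = 0.3
    trend_per_week: float = 0.0
    # analysis
    its: dict = field(default_factory=dict)
    snapshot_weeks: tuple = DEFAULT_SNAPSHOTS
    sensitivity_grid: list[dict] | None = None
    make_plots: bool = False
    log_level: str = "INFO"

    def __post_init__(self):
        if self.seed is None:
            raise ValidationError("seed is mandatory in pipeline mode")
        if self.mode not in ("aggregated", "ehr"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        seen = set()
        for c in self.conditions:
            if c in seen:
                raise ValidationError(f"condition {c!r} listed twice")
            seen.add(c)
            get_condition(c)  # raises for unknown names


def load_run_config(path) -> RunConfig:
    """Read a YAML or JSON run configuration."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValidationError(f"run config {path}: expected a mapping")
    return RunConfig(**raw)


def _condition_seed(config: RunConfig, name: str) -> int:
    ss = np.random.SeedSequence(
        [int(config.seed), int(hashlib.sha256(name.encode()).hexdigest()[:8], 16)]
    )
    return int(ss.generate_state(1)[0] % (2**31))


def _design_for(spec, config: RunConfig) -> ITSDesign:
    overrides = dict(config.its)
    overrides.setdefault("pre_period_start", spec.pre_period_start)
    return ITSDesign(**overrides)


def _simulate_series(spec, config: RunConfig):
    sim = spec.simulation_config(
        seed=_condition_seed(config, spec.name),
        season_amplitude=config.season_amplitude,
        ar_sigma=config.ar_sigma,
        ar_rho=config.ar_rho,
        trend_per_week=config.trend_per_week,
    )
    return generate_weekly_counts(
        sim, config.n_weeks_pre, config.n_weeks_post, config.denominator
    )


def _its_row(spec, fit) -> dict:
    s = step_or(fit)
    rec = recovery_or(fit)
    return {
        "condition": spec.name,
        "label": spec.label,
        "scenario": fit.design.label,
        "step_or": s.estimate,
        "step_lo": s.lo,
        "step_hi": s.hi,
        "slope_or": rec.slope.estimate,
        "slope_lo": rec.slope.lo,
        "slope_hi": rec.slope.hi,
        "net_weekly_or": rec.net_weekly.estimate,
        "net_weekly_lo": rec.net_weekly.lo,
        "net_weekly_hi": rec.net_weekly.hi,
        "dispersion": fit.phi,
        "rho_hat": fit.rho_hat,
        "n_weeks": fit.n_weeks,
    }


def _table3_rows(spec, pfit, config: RunConfig) -> list[dict]:
    rows = []
    for snap in config.snapshot_weeks:
        start = week_start(snap)
        end = start + dt.timedelta(days=6)
        sub = counterfactual_difference(pfit, (start, end))
        if sub.empty:
            raise PipelineError("counterfactual", spec.name, f"snapshot {snap} empty")
        r = sub.iloc[0]
        rows.append(
            {
                "condition": spec.name,
                "label": spec.label,
                "week_start": start.isoformat(),
                "without_per_million": r["without_per_million"],
                "without_ci": f"{r['without_lo']:.0f}-{r['without_hi']:.0f}",
                "with_per_million": r["with_per_million"],
                "with_ci": f"{r['with_lo']:.0f}-{r['with_hi']:.0f}",
                "weekly_difference": round_and_censor(
                    r["difference_per_million"],
                    "weekly_diff",
                    spec.weekly_censor_threshold,
                ),
                "cumulative_difference": round_and_censor(
                    r["cumulative_difference"],
                    "cumulative",
                    spec.cumulative_censor_threshold,
                ),
            }
        )
    return rows


def _ehr_rate_logit(spec, config: RunConfig) -> float:
    import math

    p = spec.baseline_weekly_per_million / 1e6 * config.ehr_rate_multiplier
    p = min(p, 0.5)
    return math.log(p / (1.0 - p))


def _ehr_tables(config: RunConfig):
    """Simulate the shared individual-level tables for ehr mode."""
    specs = [get_condition(c) for c in config.conditions]
    base = specs[0].simulation_config(
        seed=int(config.seed) % (2**31),
        season_amplitude=config.season_amplitude,
        ar_sigma=config.ar_sigma,
        ar_rho=config.ar_rho,
        trend_per_week=config.trend_per_week,
        n_patients=config.n_patients,
    )
    patients = generate_population(base)
    chronic = generate_chronic_codes(patients, base)
    events_parts = [chronic]
    rx_parts = []
    truths = {}
    for spec in specs:
        sim = spec.simulation_config(
            seed=_condition_seed(config, spec.name),
            season_amplitude=config.season_amplitude,
            ar_sigma=config.ar_sigma,
            ar_rho=config.ar_rho,
            trend_per_week=config.trend_per_week,
            n_patients=config.n_patients,
            baseline_logit=_ehr_rate_logit(spec, config),
        )
        ev, truth = generate_contact_events(patients, sim)
        truths[spec.name] = truth
        events_parts.append(ev)
        if spec.requires_prescription == "ocs":
            rx_parts.append(matched_prescriptions(ev, "RX_OCS_1", sim))
        elif spec.requires_prescription == "ocs_or_antibiotic":
            rx_parts.append(
                matched_prescriptions(ev, "RX_OCS_1", sim, alternate_code="RX_ABX_1")
            )
    clinical_events = pd.concat(events_parts, ignore_index=True)
    prescriptions = (
        pd.concat(rx_parts, ignore_index=True)
        if rx_parts
        else pd.DataFrame(columns=["patient_id", "event_date", "code", "source"])
    )
    return patients, clinical_events, prescriptions, truths


def _eligible_filter(outcome_events, denominators, patients, events, spec, codelists):
    """Keep outcome episodes on eligible person-weeks only."""
    from .cohort import eligibility_mask

    if outcome_events.empty:
        return outcome_events
    calendar = week_grid()
    rule = spec.cohort_rule()
    by_patient = (
        dict(tuple(events.groupby("patient_id", sort=False))) if len(events) else {}
    )
    empty = pd.DataFrame(columns=["patient_id", "event_date", "code"])
    keep = []
    pat_index = patients.set_index("patient_id")
    cal_pos = {w: i for i, w in enumerate(calendar)}
    for pid, grp in outcome_events.groupby("patient_id", sort=False):
        if pid not in pat_index.index:
            continue
        mask = eligibility_mask(
            pat_index.loc[pid],
            by_patient.get(pid, empty),
            rule,
            calendar,
            codelists,
        )
        for idx, row in grp.iterrows():
            w = pd.Timestamp(week_start(row["event_date"]))
            pos = cal_pos.get(w)
            if pos is not None and mask[pos]:
                keep.append(idx)
    return outcome_events.loc[sorted(keep)]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns a dict of result tables and, when
    ``config.outdir`` is set, writes them as CSVs plus a manifest."""
    its_rows, t3_rows, series_rows, hist_rows, cf_rows, fitted_rows = (
        [],
        [],
        [],
        [],
        [],
        [],
    )
    denom_frames, event_frames = [], []
    codelists = default_codelists()

    ehr = None
    if config.mode == "ehr":
        ehr = _ehr_tables(config)

    for name in config.conditions:
        spec = get_condition(name)
        design = _design_for(spec, config)
        try:
            if config.mode == "aggregated":
                ws = _simulate_series(spec, config)
            else:
                patients, clinical_events, prescriptions, _ = ehr
                rule = spec.cohort_rule()
                denoms = build_denominators(
                    patients,
                    clinical_events,
                    rule,
                    week_grid(),
                    config.strata,
                    codelists,
                )
                denom_frames.append(denoms)
                outcome = extract_events(
                    clinical_events,
                    prescriptions,
                    spec.outcome_definition(),
                    codelists,
                    study_start=design.pre_period_start,
                    study_end=design.study_end,
                )
                outcome = _eligible_filter(
                    outcome, denoms, patients, clinical_events, spec, codelists
                )
                event_frames.append(outcome.assign(condition=spec.name))
                ws = weekly_series(
                    outcome, denoms, week_grid(), condition=spec.name
                )
        except PipelineError:
            raise
        except Exception as err:
            raise PipelineError("simulate/extract", name, str(err)) from err

        try:
            fit = fit_its(ws, design)
            its_rows.append(_its_row(spec, fit))
            fitted_rows.append(
                pd.DataFrame(
                    {
                        "condition": spec.name,
                        "week_start": fit.fitted.index,
                        "observed": fit.data["proportion"].to_numpy(),
                        "fitted": fit.fitted.to_numpy(),
                    }
                )
            )
        except Exception as err:
            raise PipelineError("its_fit", name, str(err)) from err

        try:
            pfit = fit_poisson(ws, design)
            cf = counterfactual_table(pfit).assign(condition=spec.name)
            cf_rows.append(cf)
            t3_rows.extend(_table3_rows(spec, pfit, config))
        except PipelineError:
            raise
        except Exception as err:
            raise PipelineError("counterfactual", name, str(err)) from err

        try:
            hist = historical_average(ws).assign(condition=spec.name)
            hist_rows.append(hist)
            pub = suppress_small_cells(ws)
            series_rows.append(
                pub.data.assign(condition=spec.name, stratum=pub.stratum)
            )
        except Exception as err:
            raise PipelineError("series", name, str(err)) from err

    results = {
        "its_results": pd.DataFrame(its_rows),
        "table3_like": pd.DataFrame(t3_rows),
        "series": pd.concat(series_rows, ignore_index=True),
        "historical": pd.concat(hist_rows, ignore_index=True),
        "counterfactual_weekly": pd.concat(cf_rows, ignore_index=True),
        "fitted_curves": pd.concat(fitted_rows, ignore_index=True),
    }
    if denom_frames:
        results["denominators"] = pd.concat(denom_frames, ignore_index=True)
    if event_frames:
        results["events"] = pd.concat(event_frames, ignore_index=True)
    if config.mode == "ehr":
        patients, clinical_events, prescriptions, _ = ehr
        results["patients"] = patients
        results["clinical_events"] = clinical_events
        results["prescriptions"] = prescriptions

    if config.outdir:
        _write_outputs(config, results)
    return results


def run_sensitivity(config: RunConfig) -> pd.DataFrame:
    """Refit each condition's series under every sensitivity scenario.

    The default grid is the seven period-definition scenarios; a custom
    grid is a list of ITSDesign keyword mappings (each needing a unique
    ``label``).  Data are simulated once per condition and shared across
    scenarios.
    """
    if config.sensitivity_grid is not None and len(config.sensitivity_grid) == 0:
        raise ValidationError("sensitivity grid is empty")
    if config.sensitivity_grid is None:
        grid = default_sensitivity_grid()
    else:
        grid = [ITSDesign(**cell) for cell in config.sensitivity_grid]
    labels = [d.label for d in grid]
    if len(set(labels)) != len(labels):
        raise ValidationError("sensitivity scenarios must have unique labels")

    rows = []
    for name in config.conditions:
        spec = get_condition(name)
        ws = _simulate_series(spec, config)
        for design in grid:
            design = replace(design, pre_period_start=spec.pre_period_start)
            fit = fit_its(ws, design)
            rows.append(_its_row(spec, fit))
    out = pd.DataFrame(rows)
    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        out.to_csv(outdir / "sensitivity_results.csv", index=False)
    return out


def _config_hash(config: RunConfig) -> str:
    canon = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()


def _write_outputs(config: RunConfig, results: dict) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {}
    for name, df in results.items():
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False, date_format="%Y-%m-%d")
        files[path.name] = {
            "sha256": hashlib.sha256(path.read_bytes()).hexdigest(),
            "rows": int(len(df)),
        }
    if config.make_plots:
        from .plotting import plot_run

        for p in plot_run(results, outdir):
            files[p.name] = {
                "sha256": hashlib.sha256(p.read_bytes()).hexdigest(),
                "rows": None,
            }
    manifest = {
        "package_version": __version__,
        "seed": int(config.seed),
        "config_hash": _config_hash(config),
        "files": files,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def verify_manifest(outdir) -> bool:
    """Re-hash every file listed in the manifest; True iff all match."""
    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    for name, meta in manifest["files"].items():
        path = outdir / name
        if not path.exists():
            return False
        if hashlib.sha256(path.read_bytes()).hexdigest() != meta["sha256"]:
            return False
    return True


def simulate_ehr(config: RunConfig) -> dict[str, Path]:
    """Simulate and write the individual-level tables (CLI ``simulate``)."""
    patients, clinical_events, prescriptions, truths = _ehr_tables(config)
    truth = pd.concat(
        [t.assign(condition=c) for c, t in truths.items()], ignore_index=True
    )
    if not config.outdir:
        raise ValidationError("simulate requires an output directory")
    return write_simulation(
        config.outdir, patients, clinical_events, prescriptions, truth
    )
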