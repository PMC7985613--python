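"""Interrupted time-series estimation for weekly contact proportions.

The model is a binomial GLM (logit link) of weekly contact counts over
dynamic denominators with:

* a linear week trend ``t`` (centred at the last pre-lockdown week),
* a with-restrictions indicator ``R`` whose coefficient gamma is the log
  step change at the start of the with-restrictions period relative to the
  end of the pre-lockdown trend,
* an ``R x (t - t0)`` interaction whose coefficient delta is the weekly
  recovery-slope change,
* calendar-month dummies (January reference) for seasonality,
* a first-order lagged-residual term for autocorrelation, and
* standard errors scaled by sqrt(phi) when the Pearson dispersion phi
  exceeds 1 (never deflated).

Weeks inside the adjustment-to-restrictions window (default March 8-28
2020) are excluded from fitting; the lag bridges the gap, i.e. the first
with-restrictions row lags the last pre-lockdown row.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import FitDiagnosticError, ValidationError
from .series import WeeklySeries
from .weekgrid import as_date, week_index

Z95 = 1.96  # Wald normal critical value for 95% CIs

RESIDUAL_TYPES = ("deviance", "pearson", "response")


@dataclass(frozen=True)
class ITSDesign:
    """Period definitions and model options for one ITS fit."""

    pre_period_start: dt.date = dt.date(2017, 1, 1)
    pre_period_end: dt.date = dt.date(2020, 3, 7)
    exclusion_start: dt.date | None = dt.date(2020, 3, 8)
    exclusion_end: dt.date | None = dt.date(2020, 3, 28)
    restriction_start: dt.date = dt.date(2020, 3, 29)
    study_end: dt.date = dt.date(2020, 7, 18)
    include_trend: bool = True
    include_recovery_slope: bool = True
    include_month_dummies: bool = True
    include_lagged_residuals: bool = True
    residual_type: str = "deviance"
    label: str = "main"

    def __post_init__(self):
        for f in (
            "pre_period_start",
            "pre_period_end",
            "exclusion_start",
            "exclusion_end",
            "restriction_start",
            "study_end",
        ):
            v = getattr(self, f)
            if v is not None:
                object.__setattr__(self, f, as_date(v))
        if not (self.pre_period_start < self.pre_period_end):
            raise ValidationError("pre_period_start must precede pre_period_end")
        if not (self.pre_period_end < self.restriction_start <= self.study_end):
            raise ValidationError(
                "require pre_period_end < restriction_start <= study_end"
            )
        if (self.exclusion_start is None) != (self.exclusion_end is None):
            raise ValidationError("exclusion_start/end must both be set or both None")
        if self.exclusion_start is not None:
            if not (
                self.pre_period_end
                < self.exclusion_start
                <= self.exclusion_end
                < self.restriction_start
            ):
                raise ValidationError(
                    "require pre_period_end < exclusion_start <= exclusion_end"
                    " < restriction_start"
                )
        if self.residual_type not in RESIDUAL_TYPES:
            raise ValidationError(f"unknown residual_type {self.residual_type!r}")


@dataclass
class OddsRatio:
    estimate: float
    lo: float
    hi: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.estimate, self.lo, self.hi)


@dataclass
class ITSFit:
    """Fitted ITS model: coefficients, overdispersion-scaled uncertainty
    and the design frame the fit used."""

    condition: str
    design: ITSDesign
    data: pd.DataFrame  # retained rows incl. model columns
    exog: pd.DataFrame
    params: pd.Series
    bse: pd.Series  # scaled by sqrt(max(phi, 1))
    cov: pd.DataFrame  # scaled likewise
    phi: float
    rho_hat: float | None
    fitted: pd.Series  # fitted proportions, indexed by week_start
    converged: bool
    n_weeks: int
    offset: np.ndarray | None = None
    family: str = "binomial"
    result: object = field(default=None, repr=False)


def _series_frame(series) -> tuple[str, pd.DataFrame]:
    if isinstance(series, WeeklySeries):
        return series.condition, series.data
    return "series", pd.DataFrame(series)


def build_design_matrix(series, design: ITSDesign) -> pd.DataFrame:
    """Model-ready rows: retained weeks with centred week index ``t``,
    restriction indicator ``R``, recovery interaction ``Rt`` and calendar
    month.

    Retained weeks are those with week_start in the pre-lockdown period
    [pre_period_start, pre_period_end] or the with-restrictions period
    [restriction_start, study_end]; everything between (the adjustment-to-
    restrictions window) is dropped.
    """
    condition, df = _series_frame(series)
    df = df.copy()
    ws = pd.DatetimeIndex(df["week_start"])
    pre = (ws >= pd.Timestamp(design.pre_period_start)) & (
        ws <= pd.Timestamp(design.pre_period_end)
    )
    post = (ws >= pd.Timestamp(design.restriction_start)) & (
        ws <= pd.Timestamp(design.study_end)
    )
    keep = np.asarray(pre | post)
    df = df[keep].sort_values("week_start", kind="stable").reset_index(drop=True)
    if not np.asarray(post).any():
        raise ValidationError(
            f"{condition}: no weeks in the with-restrictions period"
        )
    if df.empty or not (
        pd.DatetimeIndex(df["week_start"]) <= pd.Timestamp(design.pre_period_end)
    ).any():
        raise ValidationError(f"{condition}: no pre-lockdown weeks retained")
    idx = np.array([week_index(w) for w in df["week_start"]])
    t_center = week_index(design.pre_period_end)
    t0 = week_index(design.restriction_start)
    df["t"] = idx - t_center
    df["R"] = (
        pd.DatetimeIndex(df["week_start"]) >= pd.Timestamp(design.restriction_start)
    ).astype(int)
    df["Rt"] = df["R"] * (idx - t0)
    df["month"] = pd.DatetimeIndex(df["week_start"]).month
    if not (df["R"] == 1).any():
        raise ValidationError(
            f"{condition}: empty with-restrictions segment after filtering"
        )
    return df


def _exog(df: pd.DataFrame, design: ITSDesign) -> pd.DataFrame:
    cols = {"const": np.ones(len(df))}
    if design.include_trend:
        cols["t"] = df["t"].to_numpy(dtype=float)
    cols["R"] = df["R"].to_numpy(dtype=float)
    if design.include_recovery_slope:
        cols["Rt"] = df["Rt"].to_numpy(dtype=float)
    X = pd.DataFrame(cols, index=df.index)
    if design.include_month_dummies:
        months = sorted(df["month"].unique())
        for m in months:
            if m == 1:  # January is the reference month
                continue
            X[f"month_{m}"] = (df["month"] == m).astype(float)
    return X


def _fit_glm(endog, exog, family, offset=None):
    model = sm.GLM(endog, exog, family=family, offset=offset)
    return model.fit()


def _residuals(result, kind: str) -> np.ndarray:
    return {
        "deviance": result.resid_deviance,
        "pearson": result.resid_pearson,
        "response": result.resid_response,
    }[kind]


def two_stage_fit(endog, exog: pd.DataFrame, design: ITSDesign, family, offset=None):
    """Stage-1 GLM, then refit with a lag-1 residual column.

    The lag runs over retained rows in week order with the first row's lag
    set to 0.  A degenerate (near-zero-variance) residual vector skips the
    refit, leaving the stage-1 fit as final.  Returns
    ``(final_result, rho_hat, phi)`` with phi the Pearson dispersion of the
    final fit.
    """
    stage1 = _fit_glm(endog, exog, family, offset)
    final, rho_hat = stage1, None
    if design.include_lagged_residuals:
        resid = np.asarray(_residuals(stage1, design.residual_type))
        # a (near-)perfect stage-1 fit leaves no autocorrelation to model
        if np.ptp(resid) > 1e-6:
            lag = np.concatenate([[0.0], resid[:-1]])
            exog2 = exog.assign(lag_resid=lag)
            final = _fit_glm(endog, exog2, family, offset)
            rho_hat = float(final.params["lag_resid"])
    if final.df_resid > 0:
        phi = float(final.pearson_chi2 / final.df_resid)
    else:
        phi = 1.0
    return final, rho_hat, phi


def fit_its(series, design: ITSDesign | None = None) -> ITSFit:
    """Fit the interrupted time-series binomial GLM to a weekly series."""
    if design is None:
        design = ITSDesign()
    condition, _ = _series_frame(series)
    df = build_design_matrix(series, design)
    if (df["denominator"] <= 0).any():
        raise ValidationError(f"{condition}: nonpositive denominator in model rows")
    exog = _exog(df, design)
    endog = np.column_stack(
        [df["count"].to_numpy(float), (df["denominator"] - df["count"]).to_numpy(float)]
    )
    try:
        final, rho_hat, phi = two_stage_fit(
            endog, exog, design, sm.families.Binomial()
        )
    except Exception as err:  # perfect separation / LinAlgError etc.
        raise FitDiagnosticError(condition, f"binomial GLM failed: {err}") from err
    params = final.params
    if not (np.isfinite(params).all() and np.isfinite(final.bse).all()):
        raise FitDiagnosticError(condition, "non-finite estimates (separation?)")
    structural = [n for n in final.bse.index if n != "lag_resid"]
    if (final.bse[structural] > 100).any():
        raise FitDiagnosticError(
            condition,
            "standard errors degenerate (quasi-separation; too few events?)",
        )
    converged = bool(getattr(final, "converged", True))
    if not converged:
        raise FitDiagnosticError(condition, "IRLS did not converge")
    scale = max(phi, 1.0)
    fitted = pd.Series(
        np.asarray(final.fittedvalues), index=pd.DatetimeIndex(df["week_start"])
    )
    return ITSFit(
        condition=condition,
        design=design,
        data=df,
        exog=pd.DataFrame(
            final.model.exog, columns=final.model.exog_names, index=df.index
        ),
        params=params,
        bse=final.bse * math.sqrt(scale),
        cov=final.cov_params() * scale,
        phi=phi,
        rho_hat=rho_hat,
        fitted=fitted,
        converged=converged,
        n_weeks=len(df),
        result=final,
    )


def _wald_or(est: float, se: float) -> OddsRatio:
    return OddsRatio(
        estimate=math.exp(est),
        lo=math.exp(est - Z95 * se),
        hi=math.exp(est + Z95 * se),
    )


def step_or(fit: ITSFit) -> OddsRatio:
    """Odds ratio for the immediate step at the start of the
    with-restrictions period, with overdispersion-scaled 95% CI."""
    return _wald_or(float(fit.params["R"]), float(fit.bse["R"]))


@dataclass
class RecoveryEstimate:
    """Weekly recovery during the with-restrictions period.

    ``slope`` is exp(delta), the change in weekly trend; ``net_weekly`` is
    exp(beta1 + delta), the net weekly odds ratio of contact under
    restrictions (the headline recovery measure reported by this package).
    """

    slope: OddsRatio
    net_weekly: OddsRatio


def recovery_or(fit: ITSFit) -> RecoveryEstimate:
    p, cov = fit.params, fit.cov
    delta = float(p["Rt"]) if "Rt" in p else 0.0
    se_d = float(fit.bse["Rt"]) if "Rt" in p else 0.0
    beta1 = float(p["t"]) if "t" in p else 0.0
    net = beta1 + delta
    var = 0.0
    if "t" in p:
        var += float(cov.loc["t", "t"])
    if "Rt" in p:
        var += float(cov.loc["Rt", "Rt"])
    if "t" in p and "Rt" in p:
        var += 2.0 * float(cov.loc["t", "Rt"])
    return RecoveryEstimate(
        slope=_wald_or(delta, se_d),
        net_weekly=_wald_or(net, math.sqrt(max(var, 0.0))),
    )


def default_sensitivity_grid() -> list[ITSDesign]:
    """The seven period-definition scenarios of the sensitivity analysis:
    the main design plus two longer exclusions with the March 7 pre-period
    end, and four exclusions (0/3/5/7 weeks) with the March 21 end."""
    base = ITSDesign()
    grid = [
        base,
        replace(
            base,
            exclusion_end=dt.date(2020, 4, 11),
            restriction_start=dt.date(2020, 4, 12),
            label="mar7_excl5",
        ),
        replace(
            base,
            exclusion_end=dt.date(2020, 4, 25),
            restriction_start=dt.date(2020, 4, 26),
            label="mar7_excl7",
        ),
        replace(
            base,
            pre_period_end=dt.date(2020, 3, 21),
            exclusion_start=None,
            exclusion_end=None,
            restriction_start=dt.date(2020, 3, 22),
            label="mar21_excl0",
        ),
        replace(
            base,
            pre_period_end=dt.date(2020, 3, 21),
            exclusion_start=dt.date(2020, 3, 22),
            exclusion_end=dt.date(2020, 4, 11),
            restriction_start=dt.date(2020, 4, 12),
            label="mar21_excl3",
        ),
        replace(
            base,
            pre_period_end=dt.date(2020, 3, 21),
            exclusion_start=dt.date(2020, 3, 22),
            exclusion_end=dt.date(2020, 4, 25),
            restriction_start=dt.date(2020, 4, 26),
            label="mar21_excl5",
        ),
        replace(
            base,
            pre_period_end=dt.date(2020, 3, 21),
            exclusion_start=dt.date(2020, 3, 22),
            exclusion_end=dt.date(2020, 5, 9),
            restriction_start=dt.date(2020, 5, 10),
            label="mar21_excl7",
        ),
    ]
    return grid
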