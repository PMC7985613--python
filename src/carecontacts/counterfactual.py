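"""Absolute contact deficits from a Poisson counterfactual.

The weekly series is refitted as a log-link Poisson count model with a
log-denominator offset and the same covariates as the ITS (trend, step,
recovery interaction, month dummies, lagged residuals, overdispersion
scaling).  The "no restrictions" counterfactual sets the whole restriction
effect — step, recovery interaction and the lagged-residual path — to
zero; predictions are reported as expected contacts per million persons
using each week's denominator, together with weekly differences and the
running cumulative deficit since the start of the with-restrictions
period.

Presentation follows the reporting conventions for such tables: 3
significant figures, deficits below a per-condition threshold censored as
"<10"/"<100", and negative deficits (excess contacts) as ">-10"/">-100".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import FitDiagnosticError, ValidationError
from .its import ITSDesign, Z95, _exog, _series_frame, build_design_matrix, two_stage_fit

PER = 1_000_000  # reporting scale: contacts per million persons


@dataclass
class PoissonFit:
    """Fitted counterfactual count model (see :func:`fit_poisson`)."""

    condition: str
    design: ITSDesign
    data: pd.DataFrame
    exog: pd.DataFrame
    params: pd.Series
    bse: pd.Series
    cov: pd.DataFrame
    phi: float
    rho_hat: float | None
    offset: np.ndarray
    converged: bool
    result: object = field(default=None, repr=False)


def fit_poisson(series, design: ITSDesign | None = None) -> PoissonFit:
    """Fit the Poisson count model with log-denominator offset."""
    if design is None:
        design = ITSDesign()
    condition, _ = _series_frame(series)
    df = build_design_matrix(series, design)
    if (df["denominator"] <= 0).any():
        raise ValidationError(f"{condition}: nonpositive denominator in model rows")
    exog = _exog(df, design)
    offset = np.log(df["denominator"].to_numpy(float))
    endog = df["count"].to_numpy(float)
    try:
        final, rho_hat, phi = two_stage_fit(
            endog, exog, design, sm.families.Poisson(), offset=offset
        )
    except Exception as err:
        raise FitDiagnosticError(condition, f"Poisson GLM failed: {err}") from err
    if not np.isfinite(final.params).all():
        raise FitDiagnosticError(condition, "non-finite estimates")
    scale = max(phi, 1.0)
    return PoissonFit(
        condition=condition,
        design=design,
        data=df,
        exog=pd.DataFrame(
            final.model.exog, columns=final.model.exog_names, index=df.index
        ),
        params=final.params,
        bse=final.bse * math.sqrt(scale),
        cov=final.cov_params() * scale,
        phi=phi,
        rho_hat=rho_hat,
        offset=offset,
        converged=bool(getattr(final, "converged", True)),
        result=final,
    )


def _per_million(exog: pd.DataFrame, fit: PoissonFit):
    """Expected contacts per million and a Wald interval on that scale.

    The offset cancels: expected count/denominator = exp(x'beta), so the
    per-million rate is 1e6 * exp(x'beta) regardless of denominator size.
    """
    X = exog[fit.params.index].to_numpy(float)
    lp = X @ fit.params.to_numpy()
    se = np.sqrt(np.einsum("ij,jk,ik->i", X, fit.cov.to_numpy(), X))
    est = PER * np.exp(lp)
    return est, PER * np.exp(lp - Z95 * se), PER * np.exp(lp + Z95 * se)


def counterfactual_table(fit: PoissonFit) -> pd.DataFrame:
    """Per-week counterfactual comparison over the with-restrictions period.

    Columns: expected contacts per million with restrictions (model as
    fitted) and without (step, recovery interaction and lag path zeroed),
    each with 95% CI, their difference (positive = deficit) and the
    cumulative difference since the start of the with-restrictions period.
    """
    df = fit.data
    post = df["R"] == 1
    exog_with = fit.exog[post]
    exog_without = exog_with.copy()
    for col in ("R", "Rt", "lag_resid"):
        if col in exog_without.columns:
            exog_without[col] = 0.0
    w_est, w_lo, w_hi = _per_million(exog_with, fit)
    o_est, o_lo, o_hi = _per_million(exog_without, fit)
    diff = o_est - w_est
    out = pd.DataFrame(
        {
            "week_start": df.loc[post, "week_start"].to_numpy(),
            "without_per_million": o_est,
            "without_lo": o_lo,
            "without_hi": o_hi,
            "with_per_million": w_est,
            "with_lo": w_lo,
            "with_hi": w_hi,
            "difference_per_million": diff,
            "cumulative_difference": np.cumsum(diff),
        }
    )
    return out.reset_index(drop=True)


def counterfactual_difference(fit: PoissonFit, window) -> pd.DataFrame:
    """Counterfactual rows for the weeks in ``window`` (start, end dates).

    The window must lie within the with-restrictions period; the
    cumulative column still accumulates from the start of that period.
    """
    start, end = (pd.Timestamp(w) for w in window)
    if start < pd.Timestamp(fit.design.restriction_start):
        raise ValidationError("window begins before the with-restrictions period")
    if end > pd.Timestamp(fit.design.study_end):
        raise ValidationError("window extends past the end of the study")
    table = counterfactual_table(fit)
    ws = pd.DatetimeIndex(table["week_start"])
    return table[(ws >= start) & (ws <= end)].reset_index(drop=True)


def _round_sig(value: float, sig: int = 3) -> float:
    if value == 0:
        return 0.0
    digits = sig - int(math.floor(math.log10(abs(value)))) - 1
    return round(value, digits)


def _format_number(value: float) -> str:
    v = _round_sig(value, 3)
    if float(v).is_integer():
        s = f"{int(abs(v)):,}"
        # thin-space thousands grouping only for 5+ digit numbers
        s = s.replace(",", " ") if abs(v) >= 10_000 else s.replace(",", "")
    else:
        s = f"{abs(v):g}"
    return ("-" if v < 0 else "") + s


def round_and_censor(
    value: float, kind: str = "weekly_diff", threshold: int | None = None
) -> str:
    """Presentation string for a contact-deficit estimate.

    Values whose magnitude falls below the censoring threshold are rendered
    as ``"<T"`` (deficits) or ``">-T"`` (excesses); everything else is
    rounded to 3 significant figures.  The default threshold is 100 for
    both weekly and cumulative differences; rare conditions use 10 via the
    per-condition configuration.
    """
    if kind not in ("weekly_diff", "cumulative"):
        raise ValidationError(f"unknown kind {kind!r}")
    thr = 100 if threshold is None else int(threshold)
    if abs(value) < thr:
        return f"<{thr}" if value >= 0 else f">-{thr}"
    return _format_number(value)
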