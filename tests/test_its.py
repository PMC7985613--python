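import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit, logit

from carecontacts import (
    ITSDesign,
    SimulationConfig,
    ValidationError,
    WeeklySeries,
    build_design_matrix,
    fit_its,
    generate_weekly_counts,
    recovery_or,
    seasonal_month_effects,
    step_or,
)
from carecontacts.its import ITSFit, OddsRatio
from carecontacts.weekgrid import week_grid

GRID = week_grid()


def make_series(pre_p=0.02, post_p=0.01, denom=1000, condition="toy"):
    rows = []
    for w in GRID:
        if w <= pd.Timestamp("2020-03-07"):
            p = pre_p
        elif w >= pd.Timestamp("2020-03-29"):
            p = post_p
        else:
            p = pre_p  # adjustment weeks; dropped by the design anyway
        rows.append((w, int(round(p * denom)), denom))
    return WeeklySeries(
        condition, "all", pd.DataFrame(rows, columns=["week_start", "count", "denominator"])
    )


NO_EXTRAS = ITSDesign(
    include_trend=False,
    include_recovery_slope=False,
    include_month_dummies=False,
    include_lagged_residuals=False,
)


class TestDesignMatrix:
    def test_default_design_drops_exactly_the_three_march_weeks(self):
        ws = make_series()
        df = build_design_matrix(ws, ITSDesign())
        dropped = set(GRID) - set(pd.DatetimeIndex(df["week_start"]))
        assert dropped == {
            pd.Timestamp("2020-03-08"),
            pd.Timestamp("2020-03-15"),
            pd.Timestamp("2020-03-22"),
        }
        assert len(df) == 182

    def test_restriction_indicator_and_interaction(self):
        df = build_design_matrix(make_series(), ITSDesign())
        ws = pd.DatetimeIndex(df["week_start"])
        pre = ws <= pd.Timestamp("2020-03-07")
        post = ws >= pd.Timestamp("2020-03-29")
        assert (df.loc[pre, "R"] == 0).all()
        assert (df.loc[post, "R"] == 1).all()
        assert (df.loc[pre, "Rt"] == 0).all()
        assert list(df.loc[post, "Rt"]) == list(range(16))
        # time index centred at the last pre-lockdown week
        assert df.loc[ws == pd.Timestamp("2020-03-01"), "t"].iloc[0] == 0
        assert df.loc[ws == pd.Timestamp("2020-03-29"), "t"].iloc[0] == 4

    def test_shortened_pre_period_for_self_harm_style_design(self):
        design = ITSDesign(pre_period_start=dt.date(2019, 1, 1))
        df = build_design_matrix(make_series(), design)
        assert df["week_start"].min() == pd.Timestamp("2019-01-06")

    def test_empty_restriction_segment_rejected(self):
        short = make_series()
        short.data = short.data[
            short.data["week_start"] < pd.Timestamp("2020-03-01")
        ].reset_index(drop=True)
        with pytest.raises(ValidationError):
            build_design_matrix(short, ITSDesign())

    def test_period_ordering_validated(self):
        with pytest.raises(ValidationError):
            ITSDesign(
                pre_period_end=dt.date(2020, 4, 1),
                restriction_start=dt.date(2020, 3, 29),
            )


class TestFit:
    def test_constant_series_has_null_step(self):
        ws = make_series(pre_p=0.02, post_p=0.02)
        fit = fit_its(ws, ITSDesign())
        assert step_or(fit).estimate == pytest.approx(1.0, abs=1e-6)

    def test_two_level_series_recovers_closed_form_odds_ratio(self):
        fit = fit_its(make_series(0.02, 0.01, 1000), NO_EXTRAS)
        expected = (0.01 / 0.99) / (0.02 / 0.98)
        assert step_or(fit).estimate == pytest.approx(expected, abs=1e-4)

    def test_fit_with_trend_matches_brute_force_likelihood_search(self):
        # noiseless data with a real trend and step; oracle = direct
        # numerical maximisation of the binomial log-likelihood
        design = ITSDesign(
            include_month_dummies=False, include_lagged_residuals=False
        )
        cfg = SimulationConfig(
            baseline_logit=-4.0,
            trend_per_week=0.002,
            step_log_or=math.log(0.6),
            seed=0,
        )
        denom = 1_000_000
        from carecontacts.synthetic import linear_predictor

        truth = linear_predictor(cfg, GRID)
        counts = np.round(truth["p"].to_numpy() * denom).astype(int)
        ws = WeeklySeries(
            "toy",
            "all",
            pd.DataFrame(
                {"week_start": GRID, "count": counts, "denominator": denom}
            ),
        )
        fit = fit_its(ws, design)
        df = build_design_matrix(ws, design)
        X = np.column_stack(
            [np.ones(len(df)), df["t"], df["R"], df["Rt"]]
        )
        y = df["count"].to_numpy()
        n = df["denominator"].to_numpy()

        def nll(beta):
            eta = X @ beta
            return -(y * eta - n * np.logaddexp(0.0, eta)).sum()

        start = np.zeros(4)
        start[0] = logit(y.sum() / n.sum())
        opt = minimize(nll, start, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 20000})
        assert fit.params["R"] == pytest.approx(opt.x[2], abs=1e-4)
        assert fit.params["t"] == pytest.approx(opt.x[1], abs=1e-5)

    def test_scaling_counts_and_denominators_preserves_step_or(self):
        ws = generate_weekly_counts(
            SimulationConfig(
                baseline_logit=-5.0, step_log_or=math.log(0.5), seed=4
            ),
            100,
            16,
            100_000,
        )
        base = step_or(fit_its(ws, NO_EXTRAS)).estimate
        scaled = step_or(fit_its(ws.scaled(10), NO_EXTRAS)).estimate
        assert scaled == pytest.approx(base, rel=1e-10)
        # with the full model the lag column rescales too; the OR moves
        # only negligibly
        full = step_or(fit_its(ws)).estimate
        full10 = step_or(fit_its(ws.scaled(10))).estimate
        assert full10 == pytest.approx(full, rel=1e-2)

    def test_dispersion_scaling_never_deflates_standard_errors(self):
        ws = make_series(0.02, 0.01)  # noiseless: phi << 1
        fit = fit_its(ws, NO_EXTRAS)
        assert fit.phi < 1
        unscaled = np.asarray(fit.result.bse)
        assert np.allclose(np.asarray(fit.bse), unscaled)  # not deflated


class TestOddsRatios:
    def _fit_with(self, params, ses):
        names = list(params)
        cov = pd.DataFrame(
            np.diag(np.asarray(ses, dtype=float) ** 2), index=names, columns=names
        )
        return ITSFit(
            condition="toy",
            design=ITSDesign(),
            data=pd.DataFrame(),
            exog=pd.DataFrame(),
            params=pd.Series(params),
            bse=pd.Series(dict(zip(names, ses))),
            cov=cov,
            phi=1.0,
            rho_hat=None,
            fitted=pd.Series(dtype=float),
            converged=True,
            n_weeks=0,
        )

    def test_null_step_gives_unit_or(self):
        fit = self._fit_with({"R": 0.0}, [0.1])
        assert step_or(fit).estimate == pytest.approx(1.0)

    def test_wald_interval_matches_hand_computation(self):
        fit = self._fit_with({"R": math.log(0.5)}, [0.1])
        s = step_or(fit)
        assert s.estimate == pytest.approx(0.5)
        assert s.lo == pytest.approx(0.5 * math.exp(-0.196), abs=1e-4)
        assert s.hi == pytest.approx(0.5 * math.exp(0.196), abs=1e-4)
        assert s.lo < s.estimate < s.hi and s.lo > 0

    def test_recovery_single_term_case(self):
        fit = self._fit_with(
            {"t": 0.0, "R": 0.0, "Rt": math.log(1.02)}, [0.0, 0.0, 0.01]
        )
        rec = recovery_or(fit)
        assert rec.slope.estimate == pytest.approx(1.02)
        assert rec.net_weekly.estimate == pytest.approx(1.02)

    def test_recovery_null_case(self):
        fit = self._fit_with({"t": 0.0, "R": 0.0, "Rt": 0.0}, [0.0, 0.0, 0.0])
        rec = recovery_or(fit)
        assert rec.slope.estimate == pytest.approx(1.0)
        assert rec.net_weekly.estimate == pytest.approx(1.0)

    def test_net_weekly_recovery_recovered_from_simulations(self):
        ests = []
        for s in range(20):
            cfg = SimulationConfig(
                baseline_logit=float(logit(0.002)),
                slope_log_or_per_week=math.log(1.03),
                ar_sigma=0.05,
                ar_rho=0.3,
                month_effects=seasonal_month_effects(0.1),
                seed=3000 + s,
            )
            ws = generate_weekly_counts(cfg, 166, 16, 1_000_000)
            ests.append(recovery_or(fit_its(ws)).net_weekly.estimate)
        ests = np.array(ests)
        se = ests.std(ddof=1) / math.sqrt(len(ests))
        assert abs(ests.mean() - 1.03) < max(2 * se, 1e-3)


class TestLagTerm:
    @staticmethod
    def _ac1(resid):
        r = np.asarray(resid) - np.mean(resid)
        return float(np.sum(r[1:] * r[:-1]) / np.sum(r * r))

    def test_lag_term_reduces_residual_autocorrelation(self):
        reduced = []
        nolag = ITSDesign(include_lagged_residuals=False)
        for s in range(100):
            cfg = SimulationConfig(
                baseline_logit=float(logit(0.0025)),
                ar_sigma=0.1,
                ar_rho=0.5,
                month_effects=seasonal_month_effects(0.1),
                seed=90_000 + s,
            )
            ws = generate_weekly_counts(cfg, 166, 16, 1_000_000)
            a1 = abs(self._ac1(fit_its(ws, nolag).result.resid_deviance))
            a2 = abs(self._ac1(fit_its(ws).result.resid_deviance))
            reduced.append(a2 < a1)
        assert np.median(reduced) == 1  # reduced for the majority of seeds

    def test_step_estimate_unbiased_at_scale(self):
        # absolute bias of the step log-OR < 0.01 over 200 simulations at
        # denominator 1e6 with a common-condition baseline
        ests = []
        for s in range(200):
            cfg = SimulationConfig(
                baseline_logit=float(logit(0.0025)),
                step_log_or=math.log(0.53),
                ar_sigma=0.05,
                ar_rho=0.3,
                month_effects=seasonal_month_effects(0.1),
                seed=70_000 + s,
            )
            ws = generate_weekly_counts(cfg, 166, 16, 1_000_000)
            ests.append(float(fit_its(ws).params["R"]))
        assert abs(np.mean(ests) - math.log(0.53)) < 0.01
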