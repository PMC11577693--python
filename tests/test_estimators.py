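"""Unit tests for the MLR, Tobit and median-regression fitters.

Independent oracles: direct two-group formulas, finite differences,
a grid-search likelihood maximiser, statsmodels OLS, and R
survival::survreg for the censored-normal fit.
"""

import subprocess

import numpy as np
import pytest
import statsmodels.api as sm

from conftest import build_trial
from prosim import (
    ScenarioSpec,
    fit_median,
    fit_method,
    fit_mlr,
    fit_tobit,
    generate_trial,
    grid_from_label,
    tobit_loglik,
    tobit_score,
)

RE4 = grid_from_label("RE4")
MH26 = grid_from_label("MH26")


def sample_trial(effect_x=11.0, n=60, grid=MH26, seed=3, rep=0):
    spec = ScenarioSpec(
        mu=50.0, sigma=22.0, effect_x=effect_x, n=n, grid=grid, seed=seed,
        scenario_id="t",
    )
    return generate_trial(spec, rep)


def interior_trial(n=60, seed=5):
    """A trial with no scores at the 0/100 bounds (uncensored)."""
    rng = np.random.default_rng(seed)
    y0 = rng.choice([33.3, 66.6], size=n // 2)
    y1 = rng.choice([33.3, 66.6], size=n // 2, p=[0.2, 0.8])
    return build_trial(y0, y1)


class TestMLR:
    def test_estimate_equals_group_mean_difference(self):
        tr = sample_trial()
        fit = fit_mlr(tr)
        y0 = tr.observed[tr.arm == 0]
        y1 = tr.observed[tr.arm == 1]
        assert fit.estimate == pytest.approx(y1.mean() - y0.mean(), abs=1e-12)

    def test_matches_statsmodels_ols(self):
        tr = sample_trial(seed=11)
        fit = fit_mlr(tr, alpha=0.05)
        X = sm.add_constant(tr.arm.astype(float))
        ols = sm.OLS(tr.observed, X).fit()
        assert fit.estimate == pytest.approx(ols.params[1], rel=1e-10)
        assert fit.se == pytest.approx(ols.bse[1], rel=1e-10)
        assert fit.p_value == pytest.approx(ols.pvalues[1], rel=1e-8)
        lo, hi = ols.conf_int(alpha=0.05)[1]
        assert fit.ci_low == pytest.approx(lo, rel=1e-10)
        assert fit.ci_upp == pytest.approx(hi, rel=1e-10)

    def test_identical_arms_give_zero_effect_p_one(self):
        y = [0.0, 33.3, 66.6, 100.0, 33.3]
        fit = fit_mlr(build_trial(y, y))
        assert fit.estimate == 0.0
        assert fit.p_value == pytest.approx(1.0)

    def test_zero_within_arm_variance_flagged_missing(self):
        fit = fit_mlr(build_trial([0.0, 0.0], [100.0, 100.0]))
        assert not fit.converged
        assert fit.estimate is None and fit.se is None

    def test_ci_brackets_estimate(self):
        fit = fit_mlr(sample_trial(seed=9))
        assert fit.ci_low <= fit.estimate <= fit.ci_upp


class TestTobitLoglik:
    def test_equals_normal_loglik_without_censoring(self):
        tr = interior_trial()
        y = tr.observed
        y0, y1 = y[tr.arm == 0], y[tr.arm == 1]
        b0, b1 = y0.mean(), y1.mean() - y0.mean()
        resid = y - np.where(tr.arm == 1, b0 + b1, b0)
        sigma2 = (resid ** 2).mean()
        ll = tobit_loglik(b0, b1, 0.5 * np.log(sigma2), tr)
        expected = (
            -0.5 * y.size * np.log(2 * np.pi * sigma2)
            - 0.5 * (resid ** 2).sum() / sigma2
        )
        assert ll == pytest.approx(expected, rel=1e-12)

    def test_boundary_observation_at_linear_predictor_gives_log_half(self):
        # every observation left-censored at 0 with eta=0: each contributes
        # log Phi(0) = log 0.5 by symmetry
        tr = build_trial([0.0], [0.0])
        ll = tobit_loglik(0.0, 0.0, np.log(22.0), tr)
        assert ll == pytest.approx(2 * np.log(0.5), rel=1e-12)

    def test_nonfinite_parameters_yield_nonfinite_loglik(self):
        tr = sample_trial()
        assert tobit_loglik(np.nan, 0.0, 0.0, tr) == -np.inf
        assert tobit_loglik(0.0, np.inf, 0.0, tr) == -np.inf

    @pytest.mark.parametrize("point", [
        (45.0, 10.0, np.log(20.0)),
        (60.0, -5.0, np.log(35.0)),
        (50.0, 22.0, np.log(10.0)),
    ])
    def test_score_matches_finite_differences(self, point):
        tr = sample_trial(effect_x=22.0, grid=RE4, seed=7)
        analytic = tobit_score(*point, tr)
        h = 1e-6
        fd = np.empty(3)
        for i in range(3):
            p_hi = list(point)
            p_lo = list(point)
            p_hi[i] += h
            p_lo[i] -= h
            fd[i] = (tobit_loglik(*p_hi, tr) - tobit_loglik(*p_lo, tr)) / (2 * h)
        np.testing.assert_allclose(analytic, fd, rtol=1e-5)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError, match="lower"):
            tobit_loglik(0, 0, 0, sample_trial(), lower=100, upper=0)


class TestFitTobit:
    def test_equals_mlr_on_uncensored_trial(self):
        tr = interior_trial(n=80)
        tob = fit_tobit(tr)
        mlr = fit_mlr(tr)
        assert tob.converged
        assert tob.estimate == pytest.approx(mlr.estimate, abs=1e-6)
        # sigma-hat uses the n divisor where OLS uses n-2
        y = tr.observed
        resid = y - np.where(tr.arm == 1, y[tr.arm == 1].mean(),
                             y[tr.arm == 0].mean())
        assert tob.aux["sigma"] == pytest.approx(
            np.sqrt((resid ** 2).mean()), rel=1e-5
        )

    def test_matches_r_survreg_oracle(self, tmp_path):
        tr = sample_trial(effect_x=22.0, n=60, grid=RE4, seed=3)
        fit = fit_tobit(tr)
        csv = tmp_path / "trial.csv"
        tr.to_frame().to_csv(csv, index=False)
        rcode = f"""
        d <- read.csv("{csv}")
        lo <- ifelse(d$observed <= 0, NA, ifelse(d$observed >= 100, 100, d$observed))
        hi <- ifelse(d$observed <= 0, 0, ifelse(d$observed >= 100, NA, d$observed))
        suppressMessages(library(survival))
        f <- survreg(Surv(lo, hi, type="interval2") ~ arm, data=d, dist="gaussian")
        cat(sprintf("%.10f %.10f %.10f", coef(f)[2], sqrt(vcov(f)[2,2]), f$scale))
        """
        out = subprocess.run(
            ["Rscript", "-e", rcode], capture_output=True, text=True, check=True
        )
        r_coef, r_se, r_scale = map(float, out.stdout.split())
        assert fit.estimate == pytest.approx(r_coef, abs=1e-5)
        assert fit.se == pytest.approx(r_se, abs=1e-4)
        assert fit.aux["sigma"] == pytest.approx(r_scale, abs=1e-4)

    def test_optimum_beats_surrounding_grid(self):
        # independent grid-search maximiser around the fitted optimum
        tr = sample_trial(effect_x=22.0, n=40, grid=RE4, seed=13)
        fit = fit_tobit(tr)
        b0, b1 = fit.aux["beta0"], fit.estimate
        logs = np.log(fit.aux["sigma"])
        best = -np.inf
        for db0 in np.linspace(-3, 3, 7):
            for db1 in np.linspace(-3, 3, 7):
                for dls in np.linspace(-0.2, 0.2, 5):
                    best = max(
                        best,
                        tobit_loglik(b0 + db0, b1 + db1, logs + dls, tr),
                    )
        assert fit.aux["loglik"] >= best - 1e-9

    def test_random_restarts_reach_same_optimum(self):
        # concavity in the working parameterisation: restarts agree
        tr = sample_trial(effect_x=17.6, n=60, grid=RE4, seed=21)
        fit = fit_tobit(tr)
        from prosim.estimators import _tobit_nll_grad, _trial_groups
        from scipy.optimize import minimize

        groups = _trial_groups(tr, 0.0, 100.0)
        rng = np.random.default_rng(0)
        for _ in range(5):
            x0 = np.array([rng.uniform(20, 80), rng.uniform(-30, 30),
                           np.log(rng.uniform(5, 60))])
            res = minimize(_tobit_nll_grad, x0, args=(groups, 0.0, 100.0),
                           jac=True, method="BFGS",
                           options={"gtol": 1e-8, "maxiter": 500})
            assert res.x[1] == pytest.approx(fit.estimate, abs=1e-5)

    def test_ceiling_pushes_estimate_above_mlr(self):
        # heavy right-censoring in the treatment arm: the latent-scale
        # Tobit effect exceeds the attenuated observed mean difference
        tr = sample_trial(effect_x=22.0, n=400, grid=RE4, seed=2)
        assert np.mean(tr.observed[tr.arm == 1] == 100.0) > 0.2
        tob = fit_tobit(tr)
        mlr = fit_mlr(tr)
        assert tob.converged
        assert tob.estimate > mlr.estimate

    def test_all_censored_flagged_missing(self):
        fit = fit_tobit(build_trial([0.0, 0.0, 100.0], [100.0, 100.0, 0.0]))
        assert not fit.converged

    def test_shift_equivariance_with_bounds(self):
        tr = sample_trial(effect_x=22.0, n=100, grid=RE4, seed=4)
        shifted = build_trial(
            tr.observed[tr.arm == 0] + 7.0, tr.observed[tr.arm == 1] + 7.0
        )
        a = fit_tobit(tr)
        b = fit_tobit(shifted, lower=7.0, upper=107.0)
        assert b.estimate == pytest.approx(a.estimate, abs=1e-5)
        assert b.se == pytest.approx(a.se, rel=1e-4)


class TestFitMedian:
    def test_equals_group_median_difference_odd_arms(self):
        # odd arm sizes make the within-arm median unique
        rng = np.random.default_rng(8)
        for _ in range(5):
            y0 = clamp26(rng.normal(50, 22, 25))
            y1 = clamp26(rng.normal(61, 22, 25))
            fit = fit_median(build_trial(y0, y1))
            assert fit.converged
            assert fit.estimate == pytest.approx(
                np.median(y1) - np.median(y0), abs=1e-4
            )

    def test_identical_arms_give_zero(self):
        y = [0.0, 33.3, 33.3, 66.6, 100.0]
        fit = fit_median(build_trial(y, y))
        assert fit.converged
        assert fit.estimate == pytest.approx(0.0, abs=1e-6)

    def test_degenerate_constant_outcome_flagged_missing(self):
        fit = fit_median(build_trial([33.3] * 5, [33.3] * 5))
        assert not fit.converged

    def test_ci_and_p_are_consistent(self):
        tr = sample_trial(effect_x=22.0, n=50, grid=MH26, seed=12)
        fit = fit_median(tr)
        assert fit.converged
        assert fit.ci_low <= fit.estimate <= fit.ci_upp
        assert 0.0 <= fit.p_value <= 1.0


def clamp26(x):
    from prosim import clamp_and_discretise

    return clamp_and_discretise(x, MH26)


class TestCommonContracts:
    @pytest.mark.parametrize("method", ["mlr", "tobit", "median"])
    def test_swapping_arms_negates_estimate(self, method):
        tr = sample_trial(effect_x=17.6, n=50, grid=MH26, seed=6)
        swapped = build_trial(
            tr.observed[tr.arm == 1], tr.observed[tr.arm == 0]
        )
        a = fit_method(method, tr)
        b = fit_method(method, swapped)
        assert a.converged and b.converged
        assert b.estimate == pytest.approx(-a.estimate, abs=1e-6)
        assert b.p_value == pytest.approx(a.p_value, abs=1e-6)
        assert b.se == pytest.approx(a.se, rel=1e-5)

    @pytest.mark.parametrize("method", ["mlr", "median"])
    def test_shift_equivariance_interior(self, method):
        # adding a constant that keeps scores off the bounds leaves the
        # effect estimate and its SE unchanged
        tr = interior_trial(n=50, seed=14)
        shifted = build_trial(
            tr.observed[tr.arm == 0] + 5.0, tr.observed[tr.arm == 1] + 5.0
        )
        a = fit_method(method, tr)
        b = fit_method(method, shifted)
        assert b.estimate == pytest.approx(a.estimate, abs=1e-6)
        assert b.se == pytest.approx(a.se, rel=1e-6)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown method"):
            fit_method("clad", sample_trial())

    def test_empty_arm_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            fit_mlr(build_trial([], [1.0, 2.0]))
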