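"""Linear-mixed-model engine: REML fitting, conditional prediction,
knot means, growth indicators and their invariants."""

import numpy as np
import pandas as pd
import pytest

from growthcv import reml
from growthcv.basis import BasisDescriptor, DegenerateDesignError
from growthcv.data import Cohort, ModelSpec
from growthcv.models import (Brokenstick, FitFailure, FittedLMM,
                             GrowthCurveModel, LairdWareLinear,
                             LairdWareQuadratic, PenalizedSpline)
from growthcv.simulate import make_synthetic_reference, simulate_cohort, SimConfig

from conftest import make_cohort


def dense_conditional_oracle(pop_obs, pop_tgt, Zo, Zt, G, sigma2, y_obs):
    """Independent oracle: build the joint Gaussian of (trajectory at
    targets, observations) explicitly and condition by brute force."""
    n_o = len(y_obs)
    cov_tt = Zt @ G @ Zt.T
    cov_to = Zt @ G @ Zo.T
    cov_oo = Zo @ G @ Zo.T + sigma2 * np.eye(n_o)
    return pop_tgt + cov_to @ np.linalg.solve(cov_oo, y_obs - pop_obs)


def _fit_from_params(model, basis, beta, G, sigma2, scale="z"):
    spec = ModelSpec(model, scale=scale)
    return FittedLMM(spec=spec, basis=basis, beta=np.asarray(beta, float),
                     G=np.asarray(G, float), sigma2=float(sigma2),
                     loglik=0.0, trace=[0.0], converged=True, n_iter=1,
                     n_subjects=10, n_obs=40)


def _random_psd(rng, q, scale=0.3):
    A = rng.normal(0, scale, (q, q))
    return A @ A.T + 1e-3 * np.eye(q)


def _basis_for(model, rng):
    if model == "lwlinear":
        return BasisDescriptor("lwlinear", 0.0, 730.0)
    if model == "lwquad":
        return BasisDescriptor("lwquad", 0.0, 730.0)
    if model == "brokenstick":
        return BasisDescriptor("brokenstick", 0.0, 730.0,
                               knots=(200.0, 400.0, 580.0))
    return BasisDescriptor("penalized_spline", 0.0, 730.0,
                           knots=(150.0, 365.0, 580.0),
                           subject_knots=(244.0, 487.0))


@pytest.mark.parametrize("model", ["lwlinear", "lwquad", "brokenstick",
                                   "penalized_spline"])
def test_predict_subject_matches_dense_gaussian_oracle(model):
    """Conditional prediction agrees with brute-force joint-Gaussian
    conditioning on many small random instances."""
    rng = np.random.default_rng(20240915)
    for rep in range(15):
        basis = _basis_for(model, rng)
        q = basis.n_random
        beta = rng.normal(0, 1, basis.n_fixed)
        G = _random_psd(rng, q)
        sigma2 = float(rng.uniform(0.01, 0.3))
        u = rng.normal(0, 0.1, len(basis.knots)) if model == "penalized_spline" \
            else None
        fit = _fit_from_params(model, basis, beta, G, sigma2)
        if u is not None:
            fit.u_blup = u
            fit.sigma_u2 = 0.01
        n_obs = int(rng.integers(1, 5))
        obs_t = np.sort(rng.uniform(0, 730, n_obs))
        tgt = np.sort(rng.uniform(0, 730, 3))
        y = fit.population_curve(obs_t) + rng.normal(0, 0.5, n_obs)
        expected = dense_conditional_oracle(
            fit.population_curve(obs_t), fit.population_curve(tgt),
            basis.random_design(obs_t), basis.random_design(tgt),
            G, sigma2, y)
        got = fit.predict_subject(obs_t, y, tgt)
        assert np.allclose(got, expected, atol=1e-8)


def test_empty_observations_give_population_curve():
    basis = BasisDescriptor("brokenstick", 0.0, 730.0, knots=(365.0,))
    fit = _fit_from_params("brokenstick", basis, [0.0, -1.5, -1.0],
                           0.2 * np.eye(3), 0.05)
    tgt = np.linspace(0, 730, 7)
    assert np.allclose(fit.predict_subject([], [], tgt),
                       fit.population_curve(tgt))


def test_zero_g_ignores_observations():
    basis = BasisDescriptor("lwlinear", 0.0, 730.0)
    fit = _fit_from_params("lwlinear", basis, [1.0, -2.0],
                           np.zeros((2, 2)), 0.04)
    pred = fit.predict_subject([100.0, 300.0], [5.0, -5.0], [500.0])
    assert pred[0] == pytest.approx(fit.population_curve([500.0])[0])


def test_random_intercept_closed_form_and_shrinkage():
    """One observation, intercept-only covariance: prediction follows the
    scalar conditional-Gaussian formula, and shrinks monotonically toward
    the population curve as sigma2 grows."""
    basis = BasisDescriptor("lwlinear", 0.0, 730.0)
    beta0, beta1 = -0.4, 0.0
    sg2 = 0.36
    y1 = 1.3
    prev_gap = np.inf
    for s2 in (0.01, 0.05, 0.2, 0.8, 3.0):
        fit = _fit_from_params("lwlinear", basis, [beta0, beta1],
                               np.diag([sg2, 0.0]), s2)
        pred = fit.predict_subject([200.0], [y1], [600.0])[0]
        expected = beta0 + sg2 / (sg2 + s2) * (y1 - beta0)
        assert pred == pytest.approx(expected, abs=1e-10)
        gap = abs(pred - beta0)
        assert gap < prev_gap
        prev_gap = gap


class TestFitLMM:
    def test_noiseless_global_line_recovered(self):
        rng = np.random.default_rng(1)
        t = rng.uniform(0, 1, (20, 8))
        y = (2.0 - 3.0 * t).ravel()
        X = np.column_stack([np.ones(160), t.ravel()])
        groups = np.repeat(np.arange(20), 8)
        res = reml.fit_lmm(X, X, y, groups)
        assert np.allclose(res.beta, [2.0, -3.0], atol=1e-6)
        assert res.sigma2 <= 1e-8

    def test_single_subject_rejected(self):
        X = np.column_stack([np.ones(5), np.arange(5.0)])
        with pytest.raises(DegenerateDesignError):
            reml.fit_lmm(X, X, np.arange(5.0), np.zeros(5, int))

    def test_singular_design_rejected(self):
        X = np.column_stack([np.ones(10), np.ones(10)])
        with pytest.raises(DegenerateDesignError):
            reml.fit_lmm(X, X, np.arange(10.0), np.repeat([0, 1], 5))

    def test_reml_trace_monotone_nondecreasing(self, faltering_cohort):
        cohort, _, _ = faltering_cohort
        model = Brokenstick(cohort, scale="z", n_internal_knots=3)
        fit = model.fit()
        assert isinstance(fit, FittedLMM)
        tr = np.asarray(fit.trace)
        assert np.all(np.diff(tr) >= -1e-8 * (1 + np.abs(tr[:-1])))

    def test_agrees_with_statsmodels_mixedlm(self):
        """Dual-route check: our REML EM against the independent
        statsmodels MixedLM implementation on a random-slope dataset."""
        import statsmodels.api as sm
        rng = np.random.default_rng(7)
        N, n_i = 60, 6
        t = rng.uniform(0, 1, (N, n_i))
        b = rng.multivariate_normal([0, 0], [[0.25, 0.05], [0.05, 0.16]], N)
        y = (1.0 + b[:, 0:1]) + (-0.5 + b[:, 1:2]) * t \
            + rng.normal(0, 0.3, (N, n_i))
        X = np.column_stack([np.ones(N * n_i), t.ravel()])
        groups = np.repeat(np.arange(N), n_i)
        ours = reml.fit_lmm(X, X, y.ravel(), groups)
        md = sm.regression.mixed_linear_model.MixedLM(
            y.ravel(), X, groups, exog_re=X)
        sm_fit = md.fit(reml=True)
        assert np.allclose(ours.beta, sm_fit.fe_params, atol=2e-3)
        assert ours.sigma2 == pytest.approx(sm_fit.scale, rel=2e-2)
        assert np.allclose(ours.G, np.asarray(sm_fit.cov_re), atol=2e-2)
        # same restricted likelihood (statsmodels omits no constants)
        assert ours.loglik == pytest.approx(sm_fit.llf, abs=1e-2)

    def test_nonconvergence_is_failure_result(self, faltering_cohort):
        cohort, _, _ = faltering_cohort
        model = Brokenstick(cohort, scale="z", n_internal_knots=4)
        out = model.fit(max_iter=3)
        assert isinstance(out, FitFailure)
        assert not out.ok
        assert "budget" in out.reason


@pytest.fixture(scope="module")
def bs_fit(faltering_cohort):
    cohort, _, _ = faltering_cohort
    fit = Brokenstick(cohort, scale="z", n_internal_knots=3).fit()
    assert isinstance(fit, FittedLMM)
    return fit, cohort


class TestBrokenstickGeometry:
    def test_piecewise_linear_second_differences(self, bs_fit):
        fit, cohort = bs_fit
        sub = cohort.subject(cohort.subject_ids[0])
        lo = fit.basis.age_lo
        k1 = fit.basis.knots[0]
        t = np.linspace(lo + 1.0, k1 - 1.0, 40)  # strictly inside one segment
        pred = fit.predict_subject(sub["age_days"].to_numpy(),
                                   sub["value_z"].to_numpy(), t)
        assert np.abs(np.diff(pred, n=2)).max() < 1e-9

    def test_knot_means_connect_trajectory(self, bs_fit):
        fit, cohort = bs_fit
        sub = cohort.subject(cohort.subject_ids[3])
        obs_t = sub["age_days"].to_numpy()
        obs_v = sub["value_z"].to_numpy()
        psi = fit.knot_means(obs_t, obs_v)
        ages = fit.basis.knot_ages
        assert np.allclose(fit.predict_subject(obs_t, obs_v, ages), psi,
                           atol=1e-8)
        mid = (ages[1] + ages[2]) / 2
        assert fit.predict_subject(obs_t, obs_v, [mid])[0] == \
            pytest.approx((psi[1] + psi[2]) / 2, abs=1e-8)

    def test_empty_obs_knot_means_equal_beta(self, bs_fit):
        fit, _ = bs_fit
        assert np.allclose(fit.knot_means([], []), fit.beta)

    def test_knot_means_require_brokenstick(self, faltering_cohort):
        cohort, _, _ = faltering_cohort
        fit = LairdWareLinear(cohort, scale="z").fit()
        with pytest.raises(Exception, match="brokenstick"):
            fit.knot_means([], [])


class TestGrowthIndicators:
    def test_linear_trajectory_derivative(self):
        basis = BasisDescriptor("lwlinear", 0.0, 730.0)
        # z(t) = 0.002 * t  ->  internal slope 0.002 * 730
        fit = _fit_from_params("lwlinear", basis, [0.0, 0.002 * 730.0],
                               np.zeros((2, 2)), 0.01)
        ind = fit.growth_indicators([], [], (0.0, 365.0))
        assert ind["mean_derivative"] == pytest.approx(0.002, rel=1e-10)

    def test_slope_sign_flip_averages_to_zero(self):
        basis = BasisDescriptor("brokenstick", 0.0, 400.0, knots=(200.0,))
        # segment slopes +0.01/day then -0.01/day
        fit = _fit_from_params("brokenstick", basis, [0.0, 2.0, 0.0],
                               np.zeros((3, 3)), 0.01)
        ind = fit.growth_indicators([], [], (0.0, 400.0))
        assert ind["mean_derivative"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_trajectory(self):
        basis = BasisDescriptor("lwlinear", 0.0, 730.0)
        fit = _fit_from_params("lwlinear", basis, [-0.7, 0.0],
                               np.zeros((2, 2)), 0.01)
        ind = fit.growth_indicators([], [], (100.0, 500.0))
        assert ind["mean_derivative"] == pytest.approx(0.0, abs=1e-12)
        assert ind["mean_level"] == pytest.approx(-0.7, rel=1e-9)

    def test_degenerate_window_rejected(self):
        basis = BasisDescriptor("lwlinear", 0.0, 730.0)
        fit = _fit_from_params("lwlinear", basis, [0.0, 1.0],
                               np.eye(2), 0.01)
        with pytest.raises(Exception, match="window"):
            fit.growth_indicators([], [], (400.0, 400.0))


def test_penalized_spline_invariant_to_population_knot_count(faltering_cohort):
    """Predictions stabilise once the population basis is rich enough: the
    ridge penalty, not the knot count, controls the fit.  Exact invariance
    is not attainable — each basis re-estimates its own smoothing ratio by
    REML — so the tolerance is a small fraction of the trajectory scale
    (the same level at which published comparisons report the MSE
    unchanged across population knot counts)."""
    cohort, _, _ = faltering_cohort
    preds = []
    tgt = np.linspace(20.0, 700.0, 25)
    sub = cohort.subject(cohort.subject_ids[0])
    for n_pop in (10, 14):
        fit = PenalizedSpline(cohort, scale="z", n_internal_knots=n_pop,
                              subject_knots=3).fit()
        assert isinstance(fit, FittedLMM)
        preds.append(fit.predict_subject(sub["age_days"].to_numpy(),
                                         sub["value_z"].to_numpy(), tgt))
    assert np.allclose(preds[0], preds[1], atol=0.05)


def test_serialisation_round_trip(faltering_cohort):
    cohort, _, _ = faltering_cohort
    fit = Brokenstick(cohort, scale="z", n_internal_knots=3).fit()
    back = FittedLMM.from_json(fit.to_json())
    t = np.linspace(*cohort.age_range, 9)
    sub = cohort.subject(cohort.subject_ids[1])
    a, v = sub["age_days"].to_numpy(), sub["value_z"].to_numpy()
    assert np.allclose(back.predict_subject(a, v, t),
                       fit.predict_subject(a, v, t), atol=1e-12)
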