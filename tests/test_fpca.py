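"""Sparse FPCA: stagewise estimators, PACE prediction and recovery of a
known eigenstructure."""

import numpy as np
import pandas as pd
import pytest

from growthcv.data import Cohort, GrowthDataError, ModelSpec
from growthcv.fpca import (FittedFPCA, SparseFPCA, eigendecompose,
                           estimate_mean, pace_predict, raw_covariance,
                           smooth_covariance)
from growthcv.models import FitFailure
from growthcv.simulate import (SimConfig, eigen_shape,
                               make_synthetic_reference, simulate_cohort)

from conftest import make_cohort


def _frame(rows):
    return pd.DataFrame(rows, columns=["subject_id", "age_days"])


class TestEstimateMean:
    def test_constant_data_reproduced(self):
        rng = np.random.default_rng(0)
        ages = rng.uniform(0, 700, 200)
        grid = np.linspace(0, 700, 51)
        mean = estimate_mean(ages, np.full(200, 3.25), grid)
        assert np.allclose(mean, 3.25, atol=1e-8)

    def test_sine_curve_recovered(self):
        rng = np.random.default_rng(1)
        ages = rng.uniform(0, 700, 5000)
        y = np.sin(ages / 100.0) + rng.normal(0, 0.01, 5000)
        grid = np.linspace(0, 700, 51)
        mean = estimate_mean(ages, y, grid)
        interior = (grid > 35) & (grid < 665)
        assert np.abs(mean[interior] - np.sin(grid[interior] / 100.0)).max() < 0.05

    def test_too_few_points_rejected(self):
        with pytest.raises(GrowthDataError):
            estimate_mean(np.arange(5.0), np.arange(5.0),
                          np.linspace(0, 5, 11))


class TestRawCovariance:
    def test_single_pair_product(self):
        frame = pd.DataFrame({
            "subject_id": ["a", "a"], "age_days": [100.0, 300.0]})
        s, t, prod, td, pd_ = raw_covariance(frame, np.array([2.0, 3.0]))
        assert sorted(prod.tolist()) == [6.0, 6.0]   # entry and its mirror
        assert set(zip(s, t)) == {(100.0, 300.0), (300.0, 100.0)}
        assert np.allclose(sorted(pd_), [4.0, 9.0])

    def test_all_singletons_rejected(self):
        frame = pd.DataFrame({
            "subject_id": ["a", "b", "c"], "age_days": [1.0, 2.0, 3.0]})
        with pytest.raises(GrowthDataError, match="2"):
            raw_covariance(frame, np.zeros(3))


class TestSmoothCovariance:
    def test_constant_surface(self):
        rng = np.random.default_rng(2)
        grid = np.linspace(0, 100, 21)
        s = rng.uniform(0, 100, 3000)
        t = rng.uniform(0, 100, 3000)
        C = smooth_covariance(s, t, np.ones(3000), grid)
        assert np.allclose(C, 1.0, atol=1e-6)

    def test_symmetric_by_construction(self):
        rng = np.random.default_rng(3)
        grid = np.linspace(0, 100, 21)
        s = rng.uniform(0, 100, 2000)
        t = rng.uniform(0, 100, 2000)
        prod = np.exp(-np.abs(s - t) / 40) + rng.normal(0, 0.3, 2000)
        C = smooth_covariance(s, t, prod, grid)
        assert np.abs(C - C.T).max() == 0.0

    def test_exponential_covariance_recovered(self):
        """Two-stage estimate recovers C(s,t)=exp(-|s-t|/200) from sparse
        noisy subjects.

        Raw within-subject products carry noise SD ~ sqrt(1 + C^2) ~= 1.4
        per entry, so with ~14k pairs the surface estimate keeps pointwise
        SD near 0.1; the tolerances below (count-weighted interior RMSE,
        off-diagonal interior sup) were frozen from three replicate runs
        of this generator.
        """
        rng = np.random.default_rng(4)
        grid = np.linspace(0, 600, 31)
        rows, resids = [], []
        for i in range(2000):
            m = rng.integers(2, 5)
            ages = np.sort(rng.uniform(0, 600, m))
            Csub = np.exp(-np.abs(ages[:, None] - ages[None, :]) / 200.0)
            x = rng.multivariate_normal(np.zeros(m), Csub, method="svd")
            rows.extend([(f"s{i}", a) for a in ages])
            resids.extend(x.tolist())
        frame = pd.DataFrame(rows, columns=["subject_id", "age_days"])
        s, t, prod, _, _ = raw_covariance(frame, np.array(resids))
        C = smooth_covariance(s, t, prod, grid)
        truth = np.exp(-np.abs(grid[:, None] - grid[None, :]) / 200.0)
        interior = np.zeros_like(C, bool)
        interior[3:-3, 3:-3] = True
        offdiag = np.abs(grid[:, None] - grid[None, :]) > 60.0
        err = C - truth
        assert np.sqrt(np.mean(err[interior] ** 2)) < 0.15
        assert np.abs(err[interior & offdiag]).max() < 0.45


class TestEigendecompose:
    def test_diag_matrix_eigenvalues_unit_weights(self):
        grid = np.array([0.0, 1.0])
        C = np.diag([2.0, 1.0])
        phi, lam, w, pve = eigendecompose(C, grid, pve_threshold=1.0,
                                          weights=np.ones(2))
        assert np.allclose(lam, [2.0, 1.0])

    def test_pve_truncation_rule(self):
        grid = np.array([0.0, 1.0])
        # eigenvalues 3 and 1 -> first component explains exactly 0.75
        C = np.diag([3.0, 1.0])
        phi, lam, _, pve = eigendecompose(C, grid, pve_threshold=0.75)
        assert len(lam) == 1
        assert pve == pytest.approx(0.75)

    def test_negative_definite_rejected(self):
        grid = np.linspace(0, 1, 5)
        with pytest.raises(GrowthDataError, match="degenerate"):
            eigendecompose(-np.eye(5), grid)

    def test_orthonormal_under_quadrature(self):
        rng = np.random.default_rng(5)
        grid = np.linspace(0, 700, 31)
        A = rng.normal(0, 1, (31, 31))
        C = A @ A.T
        phi, lam, w, _ = eigendecompose(C, grid, pve_threshold=0.999)
        gram = phi.T @ (w[:, None] * phi)
        assert np.allclose(gram, np.eye(phi.shape[1]), atol=1e-8)

    def test_truncated_reconstruction_psd(self):
        rng = np.random.default_rng(6)
        grid = np.linspace(0, 700, 21)
        A = rng.normal(0, 1, (21, 21))
        phi, lam, w, _ = eigendecompose(A @ A.T, grid, pve_threshold=0.9)
        recon = (phi * lam) @ phi.T
        ev = np.linalg.eigvalsh(0.5 * (recon + recon.T))
        assert ev.min() > -1e-9


def _toy_fpca(lam=(0.5,), sigma2=0.04, grid_n=41):
    grid = np.linspace(0.0, 730.0, grid_n)
    shapes = ["linear", "quadratic", "cubic"][: len(lam)]
    phi = np.column_stack([eigen_shape(s, 0.0, 730.0)(grid) for s in shapes])
    mean = -0.5 - 0.001 * grid
    return FittedFPCA(spec=ModelSpec("face"), grid=grid, mean=mean,
                      phi=phi, lam=np.asarray(lam, float), sigma2=sigma2,
                      pve=0.95, n_subjects=100, n_obs=400)


class TestPacePredict:
    def test_empty_obs_gives_mean_curve(self):
        fit = _toy_fpca()
        tgt = np.linspace(0, 730, 7)
        assert np.allclose(fit.predict_subject([], [], tgt),
                           fit.population_curve(tgt))

    def test_single_component_closed_form(self):
        fit = _toy_fpca(lam=(0.5,), sigma2=0.04)
        t_obs, t_tgt = 200.0, 600.0
        y = 0.8
        p1 = float(fit._phi_at([t_obs])[0, 0])
        pt = float(fit._phi_at([t_tgt])[0, 0])
        resid = y - fit.population_curve([t_obs])[0]
        xi = 0.5 * p1 / (0.5 * p1**2 + 0.04) * resid
        expected = fit.population_curve([t_tgt])[0] + pt * xi
        got = pace_predict(fit, [t_obs], [y], [t_tgt])[0]
        assert got == pytest.approx(expected, abs=1e-12)

    def test_matches_dense_gaussian_oracle(self):
        """PACE agrees with brute-force conditioning of the joint Gaussian
        over (targets, observations) on many small instances."""
        rng = np.random.default_rng(11)
        fit = _toy_fpca(lam=(0.8, 0.2, 0.05), sigma2=0.03, grid_n=20)
        for _ in range(20):
            n_obs = int(rng.integers(1, 5))
            t_obs = np.sort(rng.uniform(0, 730, n_obs))
            t_tgt = np.sort(rng.uniform(0, 730, 3))
            y = fit.population_curve(t_obs) + rng.normal(0, 0.6, n_obs)
            Po = fit._phi_at(t_obs)
            Pt = fit._phi_at(t_tgt)
            cov_oo = (Po * fit.lam) @ Po.T + fit.sigma2 * np.eye(n_obs)
            cov_to = (Pt * fit.lam) @ Po.T
            expected = fit.population_curve(t_tgt) + cov_to @ np.linalg.solve(
                cov_oo, y - fit.population_curve(t_obs))
            got = fit.predict_subject(t_obs, y, t_tgt)
            assert np.allclose(got, expected, atol=1e-8)

    def test_shrinks_to_mean_as_noise_grows(self):
        prev = np.inf
        for s2 in (0.01, 0.1, 1.0, 10.0):
            fit = _toy_fpca(lam=(0.5,), sigma2=s2)
            gap = abs(fit.predict_subject([200.0], [1.5], [600.0])[0]
                      - fit.population_curve([600.0])[0])
            assert gap < prev
            prev = gap

    def test_target_outside_grid_rejected(self):
        fit = _toy_fpca()
        with pytest.raises(GrowthDataError, match="outside"):
            fit.predict_subject([100.0], [0.0], [800.0])


def test_eigenstructure_recovery_two_components(reference):
    """Eigenvalues within 20% and sign-aligned eigenfunction inner products
    >= 0.95 on data generated from two known orthonormal components."""
    cfg = SimConfig(n_subjects=1000, obs_min=3, obs_max=6, obs_median=4,
                    age_lo=0.0, age_hi=730.0,
                    mean_curve=__import__("growthcv").simulate.MeanCurve(
                        "linear", (-0.3, -0.001), 0.0, 730.0),
                    intercept_sd=0.0, slope_sd=0.0,
                    eigenfunctions=(("linear", 1.0), ("quadratic", 0.25)),
                    noise_sd=0.1, seed=99)
    cohort, truth = simulate_cohort(cfg, reference)
    fit = SparseFPCA(cohort, scale="z").fit()
    assert isinstance(fit, FittedFPCA)
    assert fit.n_components >= 2
    assert fit.lam[0] == pytest.approx(1.0, rel=0.2)
    assert fit.lam[1] == pytest.approx(0.25, rel=0.2)
    # quadrature-weighted alignment with the generating shapes
    grid = fit.grid
    w = fit.quadrature_weights
    for k, name in enumerate(["linear", "quadratic"]):
        true_phi = eigen_shape(name, 0.0, 730.0)(grid)
        true_phi /= np.sqrt(np.sum(w * true_phi**2))
        inner = abs(np.sum(w * true_phi * fit.phi[:, k]))
        assert inner >= 0.95


def test_noise_floor_clipping_rule():
    """When the smoothed diagonal falls below diag(C), the noise estimate
    clips to the positive floor instead of going negative."""
    from growthcv.fpca import estimate_noise
    rng = np.random.default_rng(8)
    grid = np.linspace(0.0, 600.0, 31)
    C = np.outer(np.ones(31), np.ones(31)) * 0.5 + np.diag(np.full(31, 0.5))
    t_diag = rng.uniform(0, 600, 400)
    prod_diag = np.full(400, 0.2)        # well below diag(C) = 1.0
    floor = 1e-8
    assert estimate_noise(t_diag, prod_diag, C, grid, floor) == floor


def test_noise_variance_recovered_from_noisy_data(reference):
    """The stagewise noise estimate is unbiased but noisy (it inherits the
    covariance-surface fit error along the diagonal), so recovery is
    checked on the average over replicate cohorts."""
    from growthcv.simulate import MeanCurve
    vals = []
    for seed in (5, 6, 7):
        cfg = SimConfig(n_subjects=800, obs_min=3, obs_max=6, obs_median=4,
                        age_lo=0.0, age_hi=730.0, intercept_sd=0.6,
                        mean_curve=MeanCurve("linear", (-0.3, -0.001),
                                             0.0, 730.0),
                        slope_sd=0.0005, noise_sd=0.3, seed=seed)
        cohort, _ = simulate_cohort(cfg, reference)
        fit = SparseFPCA(cohort, scale="z").fit()
        assert isinstance(fit, FittedFPCA)
        assert fit.sigma2 >= 0.0
        vals.append(fit.sigma2)
    assert np.mean(vals) == pytest.approx(0.09, rel=0.5)


def test_degenerate_input_returns_failure_not_exception():
    c = make_cohort([("a", "male", 100.0, "height", 60.0),
                     ("b", "male", 200.0, "height", 60.0),
                     ("c", "male", 300.0, "height", 60.0)])
    c = c.with_z(np.zeros(3))
    out = SparseFPCA(c, scale="z").fit()
    assert isinstance(out, FitFailure)
    assert not out.ok


def test_fpca_serialisation_round_trip():
    fit = _toy_fpca(lam=(0.5, 0.2))
    back = FittedFPCA.from_json(fit.to_json())
    t = np.linspace(0, 730, 9)
    assert np.allclose(back.predict_subject([300.0], [0.4], t),
                       fit.predict_subject([300.0], [0.4], t), atol=1e-12)
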