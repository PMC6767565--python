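"""Sparse functional principal component analysis of growth curves.

The model is ``Y_ij = f(t_ij) + h_i(t_ij) + e_ij`` where f is a smooth
population curve and h_i a mean-zero stochastic process with covariance
surface C(s, t), observed at a handful of irregular ages per child.  The
fit proceeds in the classic sparse-FPCA stages:

1. estimate f by a penalized-spline smoother of the pooled (age, value)
   scatter, with the smoothing parameter chosen by generalized
   cross-validation (GCV);
2. form raw covariance products r_ij * r_il of within-child residual pairs
   (the same-age j = l products are set aside — they are inflated by the
   measurement-error variance — and used later for the noise estimate);
3. smooth the off-diagonal products with a bivariate weighted
   local-linear smoother (Gaussian kernel, bandwidth by GCV) to get C on
   a work grid, symmetrising it and clipping to the Cauchy-Schwarz
   envelope of the smoothed diagonal;
4. eigendecompose C under the grid quadrature weights, truncate negative
   eigenvalues, and keep the smallest number of components reaching the
   requested proportion of variance explained (PVE);
5. estimate the noise variance sigma^2 from the smoothed diagonal minus
   the diagonal of C, floored at a small positive value.

Prediction for a child with observations y at ages t is the conditional
expectation (PACE) score estimate

    xi_hat = Lambda Phi_o' (Phi_o Lambda Phi_o' + sigma^2 I)^-1 (y - f_o)

followed by ``f(target) + Phi_target xi_hat``, with eigenfunction rows
interpolated linearly off the work grid.

This is a generic sparse-FPCA estimator; it targets the same estimand as
the fast-covariance-estimation (FACE) algorithm without its specialised
linear algebra.  Local-linear smoothing is used for the covariance stage
because its boundary behaviour stays linear — penalized-spline surfaces
can oscillate violently in the data-poor corners of irregular designs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy.interpolate import BSpline

from .data import Cohort, GrowthDataError, ModelSpec
from .models import FitFailure


# ---------------------------------------------------------------------------
# penalized-spline building blocks


def _bspline_design(x, lo, hi, n_basis, degree=3):
    """Cubic B-spline design on [lo, hi] with ``n_basis`` columns."""
    n_inner = max(n_basis - degree - 1, 0)
    inner = np.linspace(lo, hi, n_inner + 2)[1:-1]
    t = np.concatenate([[lo] * (degree + 1), inner, [hi] * (degree + 1)])
    x = np.clip(np.asarray(x, float), lo, hi)
    return BSpline.design_matrix(x, t, degree).toarray(), t


def _diff_penalty(n_basis, order=2):
    D = np.diff(np.eye(n_basis), n=order, axis=0)
    return D.T @ D


def _gcv_ridge(B, y, P, weights=None, lambdas=None):
    """Weighted penalized LS with GCV selection of the penalty weight.

    Returns (coefficients, lambda, gcv score).
    """
    if lambdas is None:
        lambdas = np.logspace(-6, 8, 29)
    w = np.ones(len(y)) if weights is None else np.asarray(weights, float)
    BtWB = (B * w[:, None]).T @ B
    BtWy = (B * w[:, None]).T @ y
    n_eff = w.sum()
    best = None
    scale = np.trace(BtWB) / max(np.trace(P), 1e-300)
    # anchor basis coefficients whose support carries (almost) no data,
    # e.g. empty corner cells of a tensor surface: the difference penalty
    # alone leaves them nearly free and GCV cannot see them
    d = np.diag(BtWB)
    unsupported = d < 1e-8 * d.max()
    ridge = np.diag(np.where(unsupported, 1e-3 * d.max(), 0.0))
    for lam in lambdas:
        A = BtWB + lam * scale * P + ridge
        try:
            coef = np.linalg.solve(A, BtWy)
            Ainv = np.linalg.inv(A)
        except np.linalg.LinAlgError:
            continue
        edf = float(np.trace(Ainv @ BtWB))
        fitted = B @ coef
        rss = float(w @ (y - fitted) ** 2)
        denom = max(n_eff - edf, 1e-8) ** 2
        gcv = n_eff * rss / denom
        if best is None or gcv < best[2]:
            best = (coef, lam, gcv)
    if best is None:
        raise GrowthDataError("penalized smoother: all ridge systems singular")
    return best


# ---------------------------------------------------------------------------
# stage estimators (functional surface)


def estimate_mean(ages, values, grid, n_basis=10):
    """Penalized-spline mean curve evaluated on the work grid."""
    ages = np.asarray(ages, float)
    values = np.asarray(values, float)
    if len(ages) < 20:
        raise GrowthDataError("need at least 20 pooled observations for the mean")
    lo, hi = float(grid[0]), float(grid[-1])
    n_basis = int(min(n_basis, max(4, len(np.unique(ages)))))
    B, knots = _bspline_design(ages, lo, hi, n_basis)
    P = _diff_penalty(B.shape[1])
    coef, lam, _ = _gcv_ridge(B, values, P)
    Bg, _ = _bspline_design(grid, lo, hi, n_basis)
    return Bg @ coef


def raw_covariance(cohort_frame, residuals):
    """Within-child residual cross-products.

    Returns ``(s, t, prod)`` arrays for all ordered pairs j != l (each
    unordered pair appears with its mirror) and ``(t_diag, prod_diag)``
    for the j = l products, which estimate C(t,t) + sigma^2.
    """
    s_list, t_list, p_list = [], [], []
    td_list, pd_list = [], []
    n_multi = 0
    start = 0
    sizes = cohort_frame.groupby("subject_id", sort=False).size()
    ages_all = cohort_frame["age_days"].to_numpy(float)
    r_all = np.asarray(residuals, float)
    for size in sizes.to_numpy():
        a = ages_all[start:start + size]
        r = r_all[start:start + size]
        start += size
        td_list.append(a)
        pd_list.append(r * r)
        if size < 2:
            continue
        n_multi += 1
        S, T = np.meshgrid(a, a, indexing="ij")
        PR = np.outer(r, r)
        off = ~np.eye(size, dtype=bool)
        s_list.append(S[off])
        t_list.append(T[off])
        p_list.append(PR[off])
    if n_multi == 0:
        raise GrowthDataError(
            "no subject has 2+ observations; covariance not estimable")
    return (np.concatenate(s_list), np.concatenate(t_list),
            np.concatenate(p_list),
            np.concatenate(td_list), np.concatenate(pd_list))


def _bin_to_grid(s, t, prod, grid):
    """Average-preserving binning of raw products to nearest grid nodes."""
    edges = np.concatenate([[-np.inf], (grid[1:] + grid[:-1]) / 2, [np.inf]])
    i = np.searchsorted(edges, s, side="right") - 1
    j = np.searchsorted(edges, t, side="right") - 1
    m = len(grid)
    flat = i * m + j
    cnt = np.bincount(flat, minlength=m * m).astype(float)
    tot = np.bincount(flat, weights=prod, minlength=m * m)
    keep = cnt > 0
    mean = np.zeros(m * m)
    mean[keep] = tot[keep] / cnt[keep]
    return mean, cnt


def _loclin_2d(vals, cnt, grid, h):
    """Weighted local-linear surface fit on grid-binned data.

    Returns (surface on grid x grid, edf, weighted rss).  Exploits that
    data cells and evaluation nodes share the grid: with a Gaussian kernel
    the local moment sums factorise into a handful of (m x m) matrix
    products.
    """
    m = len(grid)
    K = np.exp(-0.5 * ((grid[:, None] - grid[None, :]) / h) ** 2)
    D = grid[None, :] - grid[:, None]          # D[i, a] = grid_a - node_i
    K0, K1, K2 = K, K * D, K * D * D
    V = (vals * cnt).reshape(m, m)
    W = cnt.reshape(m, m)

    def mom(A, P, Q):
        return P @ A @ Q.T

    # normal-equation blocks of the [1, ds, dt] regression at every node
    S00 = mom(W, K0, K0)
    S10 = mom(W, K1, K0)
    S01 = mom(W, K0, K1)
    S20 = mom(W, K2, K0)
    S02 = mom(W, K0, K2)
    S11 = mom(W, K1, K1)
    T0 = mom(V, K0, K0)
    T1 = mom(V, K1, K0)
    T2 = mom(V, K0, K1)
    A = np.empty((m, m, 3, 3))
    A[..., 0, 0] = S00
    A[..., 0, 1] = A[..., 1, 0] = S10
    A[..., 0, 2] = A[..., 2, 0] = S01
    A[..., 1, 1] = S20
    A[..., 2, 2] = S02
    A[..., 1, 2] = A[..., 2, 1] = S11
    b = np.stack([T0, T1, T2], axis=-1)
    # ridge against degenerate neighbourhoods (far corners with no data)
    A = A + 1e-8 * np.maximum(S00, 1e-12)[..., None, None] * np.eye(3)
    sol = np.linalg.solve(A, b[..., None])[..., 0]
    fit = sol[..., 0]
    Ainv00 = np.linalg.inv(A)[..., 0, 0]
    # smoother self-influence at each data cell: S_ii = w_i * K(0)^2 * e1'
    # (X'WX)^-1 e1 evaluated at that cell's own node
    edf = float(np.sum(W * Ainv00))
    rss = float(np.sum(W * (vals.reshape(m, m) - fit) ** 2))
    return fit, edf, rss


def smooth_covariance(s, t, prod, grid, bandwidth=None, diag_bound=None):
    """Local-linear covariance surface on grid x grid.

    Raw products are binned to grid cells (average-preserving, with cell
    counts as weights) and smoothed by a bivariate weighted local-linear
    fit with a Gaussian kernel; the bandwidth is chosen by GCV over a
    geometric grid unless given.  Local-linear fitting keeps boundary
    behaviour linear, which is why it is the standard choice for sparse
    functional covariance estimation — spline surfaces can oscillate
    wildly in the data-poor corners of irregular designs.  The output is
    symmetrised as (A + A') / 2.

    ``diag_bound`` (a positive vector on the grid, normally the smoothed
    diagonal C(t,t) + sigma^2) additionally activates the Cauchy-Schwarz
    envelope |C(s,t)| <= sqrt(bound(s) * bound(t)), which every valid
    covariance surface satisfies.
    """
    s = np.asarray(s, float)
    if len(s) < 10:
        raise GrowthDataError("need at least 10 raw covariance entries")
    grid = np.asarray(grid, float)
    rng_w = grid[-1] - grid[0]
    vals, cnt = _bin_to_grid(s, t, np.asarray(prod, float), grid)
    if (cnt > 0).sum() < 10:
        raise GrowthDataError("degenerate raw-entry support")
    if bandwidth is not None:
        C, _, _ = _loclin_2d(vals, cnt, grid, bandwidth)
    else:
        n_eff = cnt.sum()
        best = None
        for h in rng_w * np.array([0.05, 0.08, 0.12, 0.18, 0.27, 0.4]):
            fit, edf, rss = _loclin_2d(vals, cnt, grid, h)
            gcv = n_eff * rss / max(n_eff - edf, 1e-8) ** 2
            if best is None or gcv < best[0]:
                best = (gcv, fit)
        C = best[1]
    C = 0.5 * (C + C.T)
    if diag_bound is not None:
        b = np.sqrt(np.outer(np.clip(diag_bound, 0.0, None),
                             np.clip(diag_bound, 0.0, None)))
        C = np.clip(C, -b, b)
    return C


def eigendecompose(C, grid, pve_threshold=0.95, weights=None):
    """Quadrature-weighted eigendecomposition of the covariance surface.

    The default quadrature is trapezoidal on the grid, normalised to total
    weight one, so eigenfunctions satisfy ``phi' W phi = I`` and
    eigenvalues are on the variance scale of the measurements; pass
    ``weights`` for a different quadrature.  Negative eigenvalues are
    truncated to zero and the smallest R with cumulative PVE >=
    ``pve_threshold`` is retained.
    """
    grid = np.asarray(grid, float)
    m = len(grid)
    if weights is not None:
        w = np.asarray(weights, float)
    else:
        w = np.empty(m)
        w[0] = (grid[1] - grid[0]) / 2
        w[-1] = (grid[-1] - grid[-2]) / 2
        w[1:-1] = (grid[2:] - grid[:-2]) / 2
        w = w / w.sum()
    sw = np.sqrt(w)
    K = sw[:, None] * C * sw[None, :]
    ev, U = np.linalg.eigh(0.5 * (K + K.T))
    ev = ev[::-1]
    U = U[:, ::-1]
    ev = np.clip(ev, 0.0, None)
    total = ev.sum()
    if total <= 0:
        raise GrowthDataError("degenerate covariance: no positive eigenvalues")
    cum = np.cumsum(ev) / total
    R = int(np.searchsorted(cum, pve_threshold - 1e-12) + 1)
    phi = U[:, :R] / sw[:, None]
    return phi, ev[:R], w, float(cum[R - 1])


def _loclin_1d(x, yv, grid, h):
    K = np.exp(-0.5 * ((grid[:, None] - x[None, :]) / h) ** 2)
    d = x[None, :] - grid[:, None]
    s0, s1, s2 = K.sum(1), (K * d).sum(1), (K * d * d).sum(1)
    t0, t1 = K @ yv, (K * d) @ yv
    det = s0 * s2 - s1 * s1 + 1e-12 * np.maximum(s0, 1e-12) ** 2
    fit = (s2 * t0 - s1 * t1) / det
    # self-influence of each observation at its nearest evaluation
    edf = float(np.sum(np.interp(x, grid, s2 / det)))
    resid = yv - np.interp(x, grid, fit)
    return fit, edf, float(np.sum(resid ** 2))


def smooth_diagonal(t_diag, prod_diag, grid):
    """Local-linear smooth of the same-age residual products; estimates
    C(t, t) + sigma^2 on the grid.  Bandwidth by GCV."""
    x = np.asarray(t_diag, float)
    yv = np.asarray(prod_diag, float)
    grid = np.asarray(grid, float)
    rng_w = grid[-1] - grid[0]
    n = len(x)
    best = None
    for h in rng_w * np.array([0.05, 0.08, 0.12, 0.18, 0.27, 0.4]):
        fit, edf, rss = _loclin_1d(x, yv, grid, h)
        gcv = n * rss / max(n - edf, 1e-8) ** 2
        if best is None or gcv < best[0]:
            best = (gcv, fit)
    return best[1]


def estimate_noise(t_diag, prod_diag, C, grid, floor):
    """Noise variance from smoothed diagonal products minus diag(C).

    Averaged over the central half of the age range only: near the range
    ends both curves are boundary-attenuated at different rates, which
    would otherwise leak systematic error into sigma^2.
    """
    vbar = smooth_diagonal(t_diag, prod_diag, grid)
    return _noise_from_diagonal(vbar, C, grid, floor)


def _noise_from_diagonal(vbar, C, grid, floor):
    lo, hi = grid[0], grid[-1]
    central = (grid >= lo + 0.25 * (hi - lo)) & (grid <= hi - 0.25 * (hi - lo))
    return float(max(np.mean((vbar - np.diag(C))[central]), floor))


# ---------------------------------------------------------------------------
# Model / Results


@dataclass
class FittedFPCA:
    """Sparse-FPCA results: mean curve, eigenstructure and noise variance.

    ``grid`` is the work grid in days; ``mean`` the population curve on
    the grid; ``phi`` an (m, R) matrix of eigenfunctions orthonormal under
    the grid quadrature; ``lam`` the non-increasing eigenvalues.
    """

    spec: ModelSpec
    grid: np.ndarray
    mean: np.ndarray
    phi: np.ndarray
    lam: np.ndarray
    sigma2: float
    pve: float
    n_subjects: int
    n_obs: int
    ok: bool = True

    @property
    def n_components(self) -> int:
        return len(self.lam)

    @property
    def quadrature_weights(self) -> np.ndarray:
        """Trapezoid weights on the work grid, normalised to total 1 —
        the measure under which the eigenfunctions are orthonormal."""
        g = self.grid
        w = np.empty(len(g))
        w[0] = (g[1] - g[0]) / 2
        w[-1] = (g[-1] - g[-2]) / 2
        w[1:-1] = (g[2:] - g[:-2]) / 2
        return w / w.sum()

    def _interp(self, curve, times):
        times = np.asarray(times, float)
        lo, hi = self.grid[0], self.grid[-1]
        if (times < lo - 1e-8).any() or (times > hi + 1e-8).any():
            raise GrowthDataError(
                f"target ages outside the work grid [{lo}, {hi}]")
        return np.interp(np.clip(times, lo, hi), self.grid, curve)

    def population_curve(self, times) -> np.ndarray:
        return self._interp(self.mean, np.atleast_1d(times))

    def _phi_at(self, times) -> np.ndarray:
        times = np.atleast_1d(np.asarray(times, float))
        return np.column_stack([self._interp(self.phi[:, k], times)
                                for k in range(self.n_components)])

    def scores(self, obs_times, obs_values) -> np.ndarray:
        """PACE conditional-expectation score estimates for one child."""
        obs_times = np.atleast_1d(np.asarray(obs_times, float)) \
            if obs_times is not None else np.empty(0)
        if obs_times.size == 0:
            return np.zeros(self.n_components)
        y = np.atleast_1d(np.asarray(obs_values, float))
        Phi = self._phi_at(obs_times)
        resid = y - self.population_curve(obs_times)
        So = (Phi * self.lam) @ Phi.T + self.sigma2 * np.eye(len(y))
        return self.lam * (Phi.T @ np.linalg.solve(So, resid))

    def predict_subject(self, obs_times, obs_values, targets) -> np.ndarray:
        """Conditional-mean trajectory at target ages given the child's
        observed measurements (the PACE predictor)."""
        targets = np.atleast_1d(np.asarray(targets, float))
        xi = self.scores(obs_times, obs_values)
        return self.population_curve(targets) + self._phi_at(targets) @ xi

    def summary(self) -> str:
        return "\n".join([
            f"sparse FPCA on the {self.spec.scale} scale",
            f"  subjects: {self.n_subjects}   observations: {self.n_obs}",
            f"  work grid: {len(self.grid)} ages over "
            f"[{self.grid[0]:.0f}, {self.grid[-1]:.0f}] days",
            f"  components: {self.n_components}  (PVE {self.pve:.3f})",
            f"  eigenvalues: {np.array2string(self.lam, precision=4)}",
            f"  noise variance sigma^2: {self.sigma2:.6g}",
        ])

    def to_json(self) -> str:
        return json.dumps({
            "kind": "fpca",
            "spec": asdict(self.spec),
            "grid": self.grid.tolist(),
            "mean": self.mean.tolist(),
            "phi": self.phi.tolist(),
            "lam": self.lam.tolist(),
            "sigma2": self.sigma2,
            "pve": self.pve,
            "n_subjects": self.n_subjects,
            "n_obs": self.n_obs,
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "FittedFPCA":
        d = json.loads(text)
        if d.get("kind") != "fpca":
            raise GrowthDataError("not a serialised FPCA fit")
        return cls(spec=ModelSpec(**d["spec"]),
                   grid=np.asarray(d["grid"]), mean=np.asarray(d["mean"]),
                   phi=np.asarray(d["phi"]), lam=np.asarray(d["lam"]),
                   sigma2=d["sigma2"], pve=d["pve"],
                   n_subjects=d["n_subjects"], n_obs=d["n_obs"])


class SparseFPCA:
    """Sparse functional PCA growth model bound to a cohort.

    Parameters
    ----------
    cohort : the growth data.
    scale : fit on "raw" values or "z" scores.
    n_internal_knots : marginal basis size control for the mean and
        covariance smoothers ("auto" -> 10 basis functions).
    pve_threshold : proportion of variance explained for truncation
        (default 0.95).
    grid_size : number of work-grid ages (default 51).
    """

    model_name = "face"

    def __init__(self, cohort: Cohort, scale: str = "z",
                 age_range: tuple[float, float] | None = None,
                 n_internal_knots="auto", knot_placement="even_age",
                 pve_threshold: float | None = None, grid_size: int = 51):
        self.cohort = cohort
        self.spec = ModelSpec(model="face", scale=scale,
                              n_internal_knots=n_internal_knots,
                              knot_placement=knot_placement,
                              pve_threshold=pve_threshold)
        lo, hi = age_range if age_range is not None else cohort.age_range
        if not hi > lo:
            raise GrowthDataError("degenerate age range")
        self.age_range_ = (float(lo), float(hi))
        self.grid = np.linspace(lo, hi, grid_size)
        self.n_basis = 10 if n_internal_knots == "auto" else int(n_internal_knots)
        self.pve_threshold = 0.95 if pve_threshold is None else float(pve_threshold)

    def fit(self) -> FittedFPCA | FitFailure:
        frame = self.cohort.frame.copy()
        # keep rows grouped by subject for the pairing stage
        frame["__y"] = self.cohort.values(self.spec.scale)
        frame = frame.sort_values(["subject_id", "age_days"],
                                  kind="stable").reset_index(drop=True)
        ages = frame["age_days"].to_numpy(float)
        y = frame["__y"].to_numpy(float)
        try:
            mean = estimate_mean(ages, y, self.grid, n_basis=self.n_basis)
            resid = y - np.interp(ages, self.grid, mean)
            s, t, prod, t_diag, prod_diag = raw_covariance(frame, resid)
            vbar = smooth_diagonal(t_diag, prod_diag, self.grid)
            # an explicit knot count fixes the covariance bandwidth to the
            # matching inter-knot spacing; "auto" leaves it to GCV
            bw = None if self.spec.n_internal_knots == "auto" else \
                (self.grid[-1] - self.grid[0]) / (self.n_basis + 1)
            C = smooth_covariance(s, t, prod, self.grid, bandwidth=bw,
                                  diag_bound=vbar)
            phi, lam, w, pve = eigendecompose(C, self.grid,
                                              self.pve_threshold)
            floor = 1e-8 * max(float(np.var(resid)), 1e-30)
            sigma2 = _noise_from_diagonal(vbar, C, self.grid, floor)
        except (GrowthDataError, np.linalg.LinAlgError) as e:
            return FitFailure("face", self.spec.scale, str(e))
        return FittedFPCA(spec=self.spec, grid=self.grid, mean=mean,
                          phi=phi, lam=lam, sigma2=sigma2, pve=pve,
                          n_subjects=self.cohort.n_subjects,
                          n_obs=self.cohort.n_records)


def pace_predict(fit: FittedFPCA, obs_times, obs_values, targets):
    """Functional alias for :meth:`FittedFPCA.predict_subject`."""
    return fit.predict_subject(obs_times, obs_values, targets)
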