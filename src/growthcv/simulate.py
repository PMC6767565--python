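"""Synthetic growth cohorts and growth references with known ground truth.

Real multi-country child anthropometry collections are confidential, so
every test and example in this package runs on simulated cohorts that
emulate their structure: 150-30,000 children, 1-77 irregularly spaced
measurements each over ages 0-2,000 days, subject-specific smooth
deviations around a population mean curve, and measurement noise.

Simulation happens on the Z scale — mean curve plus a correlated random
intercept/slope, optional eigenfunction deviations, and Gaussian noise —
and raw values are derived through the inverse LMS transform of a
synthetic sex-dimorphic reference.  Fitting on the Z scale is then exactly
model-true for the linear generator, while fitting on the raw scale is
misspecified by the age-varying reference, which is precisely the
raw-versus-Z contrast the cross-validation harness studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import Cohort, GrowthDataError
from .zscore import LMSReference, z_to_raw

# Published per-study summaries (children, observations, obs-per-child
# min/max/median, age min/max/median in days) used to parameterise the
# simulator so synthetic cohorts match the documented study structures.
TABLE1 = {
    "bfzn": (7637, 18983, 1, 4, 2, 168, 927, 541),
    "bngd": (197, 2352, 1, 15, 14, 95, 1903, 804),
    "cmc": (373, 12478, 23, 37, 34, 1, 1111, 558),
    "cmin": (3125, 35506, 1, 37, 9, 1, 1846, 446),
    "cntt": (197, 4405, 10, 41, 21, 1, 702, 116),
    "cort": (20510, 158892, 1, 19, 6, 1, 6954, 718),
    "ee": (380, 8436, 2, 26, 23, 1, 1175, 343),
    "fels": (1544, 28823, 1, 77, 16, 1, 6954, 2746),
    "gbsc": (315, 2548, 1, 13, 10, 119, 493, 269),
    "gems": (22545, 43158, 1, 2, 2, 5, 1908, 1942),
    "grip": (203, 1427, 1, 17, 7, 1, 521, 136),
    "jvt3": (27363, 122139, 1, 6, 5, 1, 960, 92),
    "knba": (2954, 41587, 1, 69, 13, 0, 900, 309),
    "mled": (2144, 46499, 1, 25, 25, 1, 732, 336),
    "phua": (153, 1839, 1, 16, 13, 1, 679, 185),
    "ppd": (412, 2279, 1, 8, 7, 193, 1282, 628),
    "prbt": (16898, 174233, 1, 14, 11, 1, 3287, 275),
    "pzn": (302, 1140, 2, 4, 4, 153, 457, 265),
    "rspk": (278, 3177, 1, 33, 13, 1, 525, 211),
    "smcc": (2027, 15637, 1, 10, 8, 18, 1095, 280),
    "zvit": (14086, 64867, 1, 10, 5, 1, 1132, 115),
}


@dataclass(frozen=True)
class MeanCurve:
    """Serialisable population mean curve on the Z scale.

    kinds:
      * ``constant`` — params (c,)
      * ``linear``   — params (intercept, slope per day)
      * ``faltering``— params (z0, z_dip, t_dip, z_end): piecewise-linear
        decline from z0 at the range start to z_dip at age t_dip, then
        partial recovery to z_end at the range end — the canonical growth
        faltering-and-recovery pattern.
      * ``smooth_faltering`` — params (z0, z_dip, t_dip): the same dip-and-
        partial-recovery shape as a smooth curve,
        ``z0 + (z_dip - z0) * s * exp(1 - s)`` with ``s = t / t_dip``; its
        curvature is spread over the whole range, so no small evenly
        spaced knot grid represents it exactly.
    """

    kind: str = "faltering"
    params: tuple[float, ...] = (0.0, -1.5, 365.0, -1.0)
    age_lo: float = 0.0
    age_hi: float = 730.0

    def __call__(self, t):
        t = np.asarray(t, float)
        if self.kind == "constant":
            return np.full_like(t, self.params[0])
        if self.kind == "linear":
            b0, b1 = self.params
            return b0 + b1 * t
        if self.kind == "faltering":
            z0, zdip, tdip, zend = self.params
            tdip = min(max(tdip, self.age_lo + 1e-9), self.age_hi - 1e-9)
            return np.interp(t, [self.age_lo, tdip, self.age_hi],
                             [z0, zdip, zend])
        if self.kind == "smooth_faltering":
            z0, zdip, tdip = self.params
            s = (t - self.age_lo) / (tdip - self.age_lo)
            return z0 + (zdip - z0) * s * np.exp(1.0 - s)
        raise GrowthDataError(f"unknown mean-curve kind {self.kind!r}")


# deviation shapes, unit-norm and mean-zero under the uniform measure on
# the age range (matching the FPCA quadrature normalised to total weight
# one); the shifted-Legendre shapes (linear/quadratic/cubic) are mutually
# orthonormal, while sine/cosine are orthogonal to each other but not to
# the polynomials
_EIGEN_SHAPES = {
    "linear": lambda u: np.sqrt(3.0) * (2.0 * u - 1.0),
    "quadratic": lambda u: np.sqrt(5.0) * (6.0 * u * u - 6.0 * u + 1.0),
    "cubic": lambda u: np.sqrt(7.0) * (20 * u**3 - 30 * u**2 + 12 * u - 1.0),
    "sine": lambda u: np.sqrt(2.0) * np.sin(2.0 * np.pi * u),
    "cosine": lambda u: np.sqrt(2.0) * np.cos(2.0 * np.pi * u),
}


def eigen_shape(name: str, age_lo: float, age_hi: float):
    """Return the named eigenfunction as a callable of age in days."""
    f = _EIGEN_SHAPES[name]
    return lambda t: f((np.asarray(t, float) - age_lo) / (age_hi - age_lo))


@dataclass(frozen=True)
class SimConfig:
    """Generator settings for one synthetic cohort.

    Observation counts per child follow a clipped rounded log-normal with
    the requested median; ages start near the range floor and advance by
    log-normal gaps, giving the irregular right-skewed schedules of real
    studies.  All standard deviations are on the Z scale; ``slope_sd`` is
    per day.
    """

    n_subjects: int = 200
    obs_min: int = 1
    obs_max: int = 20
    obs_median: int = 8
    age_lo: float = 0.0
    age_hi: float = 730.0
    mean_curve: MeanCurve = field(default_factory=MeanCurve)
    intercept_sd: float = 0.7
    slope_sd: float = 0.0008
    intercept_slope_corr: float = -0.2
    eigenfunctions: tuple[tuple[str, float], ...] = ()
    noise_sd: float = 0.25
    sex_ratio: float = 0.5
    measure_kind: str = "height"
    seed: int = 0

    def __post_init__(self):
        if not (self.obs_min <= self.obs_median <= self.obs_max) or self.obs_min < 1:
            raise GrowthDataError("need 1 <= obs_min <= obs_median <= obs_max")
        if not self.age_hi > self.age_lo:
            raise GrowthDataError("invalid age range")
        for sd in (self.intercept_sd, self.slope_sd, self.noise_sd):
            if sd < 0:
                raise GrowthDataError("standard deviations must be >= 0")
        for _, lam in self.eigenfunctions:
            if lam < 0:
                raise GrowthDataError("eigenvalues must be >= 0")


@dataclass
class GroundTruth:
    """Per-subject generating parameters and the true trajectory."""

    config: SimConfig
    sex: dict[str, str]
    intercept: dict[str, float]
    slope: dict[str, float]
    scores: dict[str, np.ndarray]

    def trajectory(self, subject_id: str, times) -> np.ndarray:
        """True (noiseless) Z trajectory of one subject."""
        cfg = self.config
        t = np.asarray(times, float)
        z = cfg.mean_curve(t) + self.intercept[subject_id] \
            + self.slope[subject_id] * (t - cfg.age_lo)
        for (name, _), xi in zip(cfg.eigenfunctions, self.scores[subject_id]):
            z = z + xi * eigen_shape(name, cfg.age_lo, cfg.age_hi)(t)
        return z


def make_synthetic_reference(age_range=(0.0, 2000.0), measure_kind="height",
                             n_grid=201) -> LMSReference:
    """A smooth sex-dimorphic LMS reference with plausible shapes.

    Synthetic: the curves have the qualitative form of height/weight
    references (M strictly increasing for height, S within [0.03, 0.15],
    L smoothly varying) but do not reproduce any published table.
    """
    lo, hi = float(age_range[0]), float(age_range[1])
    if not hi > lo:
        raise GrowthDataError("degenerate reference age range")
    # pad one day each side so cohort boundary ages stay strictly inside
    a = np.linspace(lo - 1.0, hi + 1.0, n_grid)
    span = hi - lo + 2.0
    u = (a - a[0]) / span
    tables = {}
    for sex, bump in (("male", 1.0), ("female", 0.0)):
        if measure_kind == "height":
            M = 50.0 + 78.0 * (1.0 - np.exp(-(a - a[0] + 30.0) / 450.0)) \
                + 0.004 * (a - a[0]) + bump * (1.0 + 0.4 * u)
            S = 0.035 + 0.012 * u + 0.002 * bump
            L = 1.0 + 0.3 * np.exp(-(a - a[0]) / 800.0) - 0.1 * bump * u
        elif measure_kind == "weight":
            M = 3.3 + 11.5 * (1.0 - np.exp(-(a - a[0] + 15.0) / 400.0)) \
                + 0.002 * (a - a[0]) + bump * (0.3 + 0.2 * u)
            S = 0.11 + 0.03 * u + 0.004 * bump
            L = 0.1 - 0.4 * u - 0.05 * bump
        else:
            raise GrowthDataError(f"unknown measure kind {measure_kind!r}")
        tables[sex] = pd.DataFrame({"age_days": a, "L": L, "M": M, "S": S})
    return LMSReference(tables)


def _observation_counts(rng, cfg: SimConfig, n: int) -> np.ndarray:
    if cfg.obs_min == cfg.obs_max:
        return np.full(n, cfg.obs_min)
    sigma = max((np.log(cfg.obs_max) - np.log(max(cfg.obs_median, 1))) / 2.0, 0.1)
    raw = rng.lognormal(np.log(max(cfg.obs_median, 1)), sigma, size=n)
    return np.clip(np.round(raw), cfg.obs_min, cfg.obs_max).astype(int)


def _observation_ages(rng, cfg: SimConfig, n_obs: int) -> np.ndarray:
    span = cfg.age_hi - cfg.age_lo
    start = cfg.age_lo + rng.uniform(0.0, 0.1 * span)
    target_gap = max(span * 0.9 / max(n_obs, 1), 1e-6)
    gaps = rng.lognormal(np.log(target_gap), 0.5, size=max(n_obs - 1, 0))
    ages = start + np.concatenate([[0.0], np.cumsum(gaps)])
    inside = ages[ages <= cfg.age_hi]
    short = n_obs - len(inside)
    if short > 0:  # schedule overshot the range: top up uniformly
        extra = rng.uniform(cfg.age_lo, cfg.age_hi, size=short)
        inside = np.concatenate([inside, extra])
    return np.sort(inside[:n_obs], kind="stable")


def simulate_cohort(cfg: SimConfig,
                    ref: LMSReference) -> tuple[Cohort, GroundTruth]:
    """Draw a synthetic cohort and its generating ground truth.

    The observed Z value is the subject's true trajectory plus N(0,
    noise_sd^2) noise; the raw value is its inverse-LMS transform at the
    record's age and sex.  Fully deterministic given ``cfg.seed``.
    """
    for sex in ("male", "female"):
        rlo, rhi = ref.age_range(sex)
        if rlo > cfg.age_lo or rhi < cfg.age_hi:
            raise GrowthDataError(
                "reference grid does not cover the simulation age range")
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_subjects
    width = len(str(max(n - 1, 1)))
    ids = [f"S{i:0{width}d}" for i in range(n)]
    sexes = np.where(rng.random(n) < cfg.sex_ratio, "male", "female")
    counts = _observation_counts(rng, cfg, n)
    cov = np.array([
        [cfg.intercept_sd**2,
         cfg.intercept_slope_corr * cfg.intercept_sd * cfg.slope_sd],
        [cfg.intercept_slope_corr * cfg.intercept_sd * cfg.slope_sd,
         cfg.slope_sd**2]])
    b = rng.multivariate_normal([0.0, 0.0], cov, size=n, method="svd") \
        if cov.any() else np.zeros((n, 2))
    lam = np.array([l for _, l in cfg.eigenfunctions])
    xi = rng.standard_normal((n, len(lam))) * np.sqrt(lam)[None, :] \
        if len(lam) else np.zeros((n, 0))

    truth = GroundTruth(cfg, {}, {}, {}, {})
    rows = []
    for i, sid in enumerate(ids):
        truth.sex[sid] = str(sexes[i])
        truth.intercept[sid] = float(b[i, 0])
        truth.slope[sid] = float(b[i, 1])
        truth.scores[sid] = xi[i].copy()
        ages = _observation_ages(rng, cfg, counts[i])
        z_true = truth.trajectory(sid, ages)
        z_obs = z_true + rng.normal(0.0, cfg.noise_sd, size=len(ages))
        L, M, S = ref.lookup(str(sexes[i]), ages)
        raw = z_to_raw(z_obs, L, M, S)
        for a, zo, yo in zip(ages, z_obs, raw):
            rows.append((sid, str(sexes[i]), float(a), cfg.measure_kind,
                         float(yo), float(zo)))
    frame = pd.DataFrame(rows, columns=["subject_id", "sex", "age_days",
                                        "measure_kind", "value_raw",
                                        "value_z"])
    return Cohort(frame), truth


def simulate_from_lmm(model: str, ref: LMSReference, *, n_subjects=40,
                      obs_range=(4, 8), age_range=(0.0, 730.0),
                      beta=None, G=None, sigma2=0.0, knots=None,
                      subject_knots=None, sigma_u2=0.04, stratify=False,
                      seed=0) -> tuple[Cohort, dict]:
    """Draw a cohort exactly from one of the mixed-model families.

    Trajectories are built on the Z scale from the model's own design —
    fixed curve plus subject random effects drawn from G plus N(0, sigma2)
    noise — so the named model is exactly true for the data.  Raw values
    come from the inverse LMS transform.  Returns the cohort and the
    generating parameters (including the model basis).

    Defaults give a gentle faltering-like fixed curve and a full-rank G
    scaled to realistic Z-score variation.
    """
    from .basis import BasisDescriptor  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    # draw every child's sex and observation schedule first, then anchor
    # the basis to the observed range: a model re-built from the cohort
    # with the same knot counts is then exactly the generating model
    schedules = []
    for i in range(n_subjects):
        sex = "male" if rng.random() < 0.5 else "female"
        m = int(rng.integers(obs_range[0], obs_range[1] + 1))
        if stratify:
            # spread observations over equal sub-intervals so every child's
            # schedule covers the whole range (keeps the subject random
            # effects identifiable from any m-1 of the m observations)
            edges = np.linspace(age_range[0], age_range[1], m + 1)
            ages = np.sort(rng.uniform(edges[:-1], edges[1:]))
        else:
            ages = np.sort(rng.uniform(age_range[0], age_range[1], m))
        schedules.append((f"M{i:04d}", sex, ages))
    lo = min(s[2][0] for s in schedules)
    hi = max(s[2][-1] for s in schedules)
    if model in ("lwlinear", "lwquad"):
        basis = BasisDescriptor(model, lo, hi)
    elif model == "brokenstick":
        kn = tuple(knots) if knots is not None \
            else tuple(np.linspace(lo, hi, 5)[1:-1])
        basis = BasisDescriptor(model, lo, hi, knots=kn)
    elif model == "penalized_spline":
        kn = tuple(knots) if knots is not None \
            else tuple(np.linspace(lo, hi, 6)[1:-1])
        sub = tuple(subject_knots) if subject_knots is not None \
            else tuple(np.linspace(lo, hi, 4)[1:-1])
        basis = BasisDescriptor(model, lo, hi, knots=kn, subject_knots=sub)
    else:
        raise GrowthDataError(f"no LMM generator for model {model!r}")

    q = basis.n_random
    if beta is None:
        beta = {"lwlinear": np.array([-0.3, -0.8]),
                "lwquad": np.array([-0.2, -2.0, 1.6]),
                "brokenstick": np.linspace(0.0, -1.2, basis.n_fixed),
                "penalized_spline": np.array([-0.2, -0.9])}[model]
    beta = np.asarray(beta, float)
    if G is None:
        if model == "penalized_spline":
            G = np.diag([0.25, 0.09] + [0.02] * (q - 2))
        else:
            A = rng.normal(0.0, 1.0, (q, q))
            G = 0.25 * (A @ A.T / q + 0.5 * np.eye(q))
    G = np.asarray(G, float)
    u = rng.normal(0.0, np.sqrt(sigma_u2), len(basis.knots)) \
        if model == "penalized_spline" else None

    rows = []
    Lc = np.linalg.cholesky(G + 1e-12 * np.eye(q))
    for sid, sex, ages in schedules:
        m = len(ages)
        X = basis.fixed_design(ages)
        Zb = basis.random_design(ages)
        b = Lc @ rng.standard_normal(q)
        z = X @ beta + Zb @ b
        if u is not None:
            z = z + basis.penalized_design(ages) @ u
        z = z + rng.normal(0.0, np.sqrt(sigma2), m)
        L, M, S = ref.lookup(sex, ages)
        raw = z_to_raw(z, L, M, S)
        rows.extend((sid, sex, float(a), "height", float(y), float(zz))
                    for a, y, zz in zip(ages, raw, z))
    frame = pd.DataFrame(rows, columns=["subject_id", "sex", "age_days",
                                        "measure_kind", "value_raw",
                                        "value_z"])
    truth = {"model": model, "basis": basis, "beta": beta, "G": G,
             "sigma2": float(sigma2), "u": u, "sigma_u2": sigma_u2}
    return Cohort(frame), truth


def table1_presets(name: str, n_subjects: int | None = None,
                   seed: int = 0) -> SimConfig:
    """SimConfig matching a documented study row's structure.

    ``n_subjects`` optionally downscales the cohort while keeping the
    observation schedule; other fields can be adjusted with
    :func:`dataclasses.replace`.
    """
    if name not in TABLE1:
        raise GrowthDataError(
            f"unknown preset {name!r}; choose from {sorted(TABLE1)}")
    (n_children, _n_obs, omin, omax, omed,
     age_min, age_max, _age_med) = TABLE1[name]
    curve = MeanCurve("faltering", (0.0, -1.5, 365.0, -1.0),
                      age_lo=float(age_min), age_hi=float(age_max))
    return SimConfig(
        n_subjects=int(n_subjects if n_subjects is not None else n_children),
        obs_min=omin, obs_max=omax, obs_median=omed,
        age_lo=float(age_min), age_hi=float(age_max),
        mean_curve=curve, seed=seed)


def faltering_preset(n_subjects=150, seed=0, **overrides) -> SimConfig:
    """A faltering cohort with a mid-range changepoint: Z declines from 0
    to -1.5 over the first eight months, then partially recovers to -1.0
    by age two.

    The changepoint (day 245) sits between the nodes of a 3-internal-knot
    grid on [0, 730] but next to a 5-knot node, so a 3-knot piecewise-
    linear fit genuinely underfits the kink while a 5-knot fit captures
    it — this preset is the test bed of the knot-sensitivity harness.
    Children also carry a small smooth sine-shaped deviation on top of
    their random intercept and slope."""
    cfg = SimConfig(n_subjects=n_subjects, obs_min=4, obs_max=12,
                    obs_median=8, age_lo=0.0, age_hi=730.0,
                    mean_curve=MeanCurve("faltering",
                                         (0.0, -1.5, 245.0, -1.0),
                                         age_lo=0.0, age_hi=730.0),
                    eigenfunctions=(("sine", 0.04),),
                    noise_sd=0.2,
                    seed=seed)
    return replace(cfg, **overrides) if overrides else cfg
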