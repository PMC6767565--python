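"""Growth-curve mixed models with a statsmodels-style Model/Results surface.

Each model is constructed from a :class:`~growthcv.data.Cohort` and a fit
scale ("raw" or "z"); ``fit()`` returns a :class:`FittedLMM` results object
carrying the fixed effects, the subject random-effect covariance G, the
residual variance, the restricted log-likelihood trace and convergence
diagnostics.  Conditional (empirical-Bayes) prediction for a partially
observed child hangs off the results object.

The four specialisations:

* :class:`LairdWareLinear`    — random intercept and slope.
* :class:`LairdWareQuadratic` — adds fixed and random quadratic terms.
* :class:`Brokenstick`        — degree-1 B-spline (piecewise linear) basis
  with one correlated random effect per knot; the child's conditional knot
  means, connected by line segments, are the trajectory.
* :class:`PenalizedSpline`    — population truncated-line spline with a
  ridge (mixed-model) penalty plus a subject-level penalized spline.

A failed fit is returned as a :class:`FitFailure` value, not raised, so a
cross-validation run can record it and move on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import reml
from .basis import BasisDescriptor, RangeError, make_basis
from .data import Cohort, ConfigurationError, GrowthDataError, ModelSpec


@dataclass
class FitFailure:
    """A structured fit failure (the bookkeeping behind blank table cells)."""

    model: str
    scale: str
    reason: str
    diagnostics: dict = field(default_factory=dict)
    ok: bool = False

    def __bool__(self):
        return False


@dataclass
class FittedLMM:
    """Results of one linear-mixed-model growth fit.

    ``beta`` are the fixed effects on the basis columns; ``G`` is the
    subject random-effect covariance (PSD); ``sigma2`` the residual
    variance; for the penalized spline, ``u_blup``/``sigma_u2`` carry the
    population spline coefficients and their variance component (they are
    part of the population curve, not the subject deviation).
    """

    spec: ModelSpec
    basis: BasisDescriptor
    beta: np.ndarray
    G: np.ndarray
    sigma2: float
    loglik: float
    trace: list[float]
    converged: bool
    n_iter: int
    n_subjects: int
    n_obs: int
    u_blup: np.ndarray | None = None
    sigma_u2: float | None = None
    ok: bool = True

    # -- population curve ------------------------------------------------

    def population_curve(self, times) -> np.ndarray:
        """Fitted population mean trajectory at the given ages (days)."""
        times = np.atleast_1d(np.asarray(times, float))
        mu = self.basis.fixed_design(times) @ self.beta
        if self.u_blup is not None:
            mu = mu + self.basis.penalized_design(times) @ self.u_blup
        return mu

    # -- conditional prediction ------------------------------------------

    def _subject_gain(self, obs_times, obs_values):
        """Posterior mean of the subject random effects given observations."""
        obs_times = np.atleast_1d(np.asarray(obs_times, float))
        obs_values = np.atleast_1d(np.asarray(obs_values, float))
        Zo = self.basis.random_design(obs_times)
        resid = obs_values - self.population_curve(obs_times)
        So = Zo @ self.G @ Zo.T + self.sigma2 * np.eye(len(obs_times))
        # guard against exactly singular conditioning on noiseless fits
        jitter = 1e-12 * (np.trace(So) / max(len(obs_times), 1) + 1.0)
        try:
            k = np.linalg.solve(So + jitter * np.eye(len(So)), resid)
        except np.linalg.LinAlgError:
            k = np.linalg.pinv(So) @ resid
        return self.G @ Zo.T @ k

    def predict_subject(self, obs_times, obs_values, targets) -> np.ndarray:
        """Empirical-Bayes conditional mean trajectory at target ages.

        ``E[Y(target) | obs]`` under the fitted Gaussian model: the
        population curve plus the cross-covariance times the whitened
        observed residuals.  With no observations this is the population
        curve itself.
        """
        targets = np.atleast_1d(np.asarray(targets, float))
        mu_t = self.population_curve(targets)
        obs_times = np.atleast_1d(np.asarray(obs_times, float)) \
            if obs_times is not None else np.empty(0)
        if obs_times.size == 0:
            return mu_t
        b = self._subject_gain(obs_times, obs_values)
        Zt = self.basis.random_design(targets)
        return mu_t + Zt @ b

    def knot_means(self, obs_times, obs_values) -> np.ndarray:
        """Brokenstick conditional knot means psi_m = beta_m + E[gamma_im | obs].

        Connecting consecutive psi values by straight segments reproduces
        the child's predicted piecewise-linear trajectory.
        """
        if self.spec.model != "brokenstick":
            raise ConfigurationError("knot_means is defined for brokenstick fits")
        obs_times = np.atleast_1d(np.asarray(obs_times, float)) \
            if obs_times is not None else np.empty(0)
        if obs_times.size == 0:
            return self.beta.copy()
        return self.beta + self._subject_gain(obs_times, obs_values)

    def growth_indicators(self, obs_times, obs_values,
                          window: tuple[float, float]) -> dict:
        """Mean derivative and mean level of the child's predicted
        trajectory over an age window (days).

        The mean derivative over [a, b] is (traj(b) - traj(a)) / (b - a)
        (exact for any trajectory, and in particular for the piecewise
        linear ones); the mean level is the trapezoidal average.
        """
        lo, hi = float(window[0]), float(window[1])
        if not hi > lo:
            raise GrowthDataError("window must satisfy age_lo < age_hi")
        ends = self.predict_subject(obs_times, obs_values, [lo, hi])
        grid = np.linspace(lo, hi, 201)
        traj = self.predict_subject(obs_times, obs_values, grid)
        return {
            "mean_derivative": float((ends[1] - ends[0]) / (hi - lo)),
            "mean_level": float(np.trapezoid(traj, grid) / (hi - lo)),
        }

    # -- reporting / serialisation ---------------------------------------

    def summary(self) -> str:
        lines = [
            f"{self.spec.model} mixed model on the {self.spec.scale} scale",
            f"  subjects: {self.n_subjects}   observations: {self.n_obs}",
            f"  REML log-likelihood: {self.loglik:.4f}"
            f"   ({'converged' if self.converged else 'NOT converged'}"
            f" in {self.n_iter} iterations)",
            f"  residual variance sigma^2: {self.sigma2:.6g}",
            f"  fixed effects: {np.array2string(self.beta, precision=4)}",
            f"  random-effect SDs: "
            f"{np.array2string(np.sqrt(np.diag(self.G)), precision=4)}",
        ]
        if self.sigma_u2 is not None:
            lines.append(f"  population-spline variance: {self.sigma_u2:.6g}")
        if self.spec.model == "brokenstick":
            lines.append(f"  knots (days): "
                         f"{np.array2string(self.basis.knot_ages, precision=1)}")
        return "\n".join(lines)

    def to_json(self) -> str:
        d = {
            "kind": "lmm",
            "spec": asdict(self.spec),
            "basis": {
                "model": self.basis.model,
                "age_lo": self.basis.age_lo, "age_hi": self.basis.age_hi,
                "knots": list(self.basis.knots),
                "subject_knots": list(self.basis.subject_knots),
            },
            "beta": self.beta.tolist(),
            "G": self.G.tolist(),
            "sigma2": self.sigma2,
            "loglik": self.loglik,
            "trace": [float(v) for v in self.trace],
            "converged": self.converged,
            "n_iter": self.n_iter,
            "n_subjects": self.n_subjects,
            "n_obs": self.n_obs,
            "u_blup": None if self.u_blup is None else self.u_blup.tolist(),
            "sigma_u2": self.sigma_u2,
        }
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "FittedLMM":
        d = json.loads(text)
        if d.get("kind") != "lmm":
            raise GrowthDataError("not a serialised LMM fit")
        spec = ModelSpec(**d["spec"])
        b = d["basis"]
        basis = BasisDescriptor(b["model"], b["age_lo"], b["age_hi"],
                                knots=tuple(b["knots"]),
                                subject_knots=tuple(b["subject_knots"]))
        return cls(spec=spec, basis=basis,
                   beta=np.asarray(d["beta"]), G=np.asarray(d["G"]),
                   sigma2=d["sigma2"], loglik=d["loglik"], trace=d["trace"],
                   converged=d["converged"], n_iter=d["n_iter"],
                   n_subjects=d["n_subjects"], n_obs=d["n_obs"],
                   u_blup=None if d["u_blup"] is None else np.asarray(d["u_blup"]),
                   sigma_u2=d["sigma_u2"])


class GrowthCurveModel:
    """Base class: a growth model bound to a cohort and a fit scale."""

    model_name: str = ""

    def __init__(self, cohort: Cohort, scale: str = "z",
                 age_range: tuple[float, float] | None = None, **options):
        self.cohort = cohort
        self.spec = ModelSpec(model=self.model_name, scale=scale, **options)
        self.basis = make_basis(cohort, self.spec, age_range=age_range)

    @staticmethod
    def from_spec(cohort: Cohort, spec: ModelSpec,
                  age_range: tuple[float, float] | None = None):
        """Instantiate the model class matching a :class:`ModelSpec`."""
        from .fpca import SparseFPCA
        classes = {
            "lwlinear": LairdWareLinear,
            "lwquad": LairdWareQuadratic,
            "brokenstick": Brokenstick,
            "penalized_spline": PenalizedSpline,
            "face": SparseFPCA,
        }
        cls = classes[spec.model]
        opts = {}
        if spec.model in ("brokenstick", "penalized_spline", "face"):
            opts["n_internal_knots"] = spec.n_internal_knots
            opts["knot_placement"] = spec.knot_placement
        if spec.model == "penalized_spline":
            opts["subject_knots"] = spec.subject_knots
        if spec.model == "face":
            opts["pve_threshold"] = spec.pve_threshold
        return cls(cohort, scale=spec.scale, age_range=age_range, **opts)

    def _design(self):
        frame = self.cohort.frame
        times = frame["age_days"].to_numpy(float)
        X = self.basis.fixed_design(times)
        Z = self.basis.random_design(times)
        y = self.cohort.values(self.spec.scale)
        groups = frame["subject_id"].to_numpy()
        return X, Z, y, groups, times

    def fit(self, **fit_kwargs) -> FittedLMM | FitFailure:
        X, Z, y, groups, times = self._design()
        try:
            res = reml.fit_lmm(X, Z, y, groups, **fit_kwargs)
        except (GrowthDataError, np.linalg.LinAlgError) as e:
            return FitFailure(self.spec.model, self.spec.scale, str(e))
        if not res.converged:
            return FitFailure(self.spec.model, self.spec.scale, res.message,
                              diagnostics={"n_iter": res.n_iter,
                                           "loglik": res.loglik})
        return FittedLMM(
            spec=self.spec, basis=self.basis, beta=res.beta, G=res.G,
            sigma2=res.sigma2, loglik=res.loglik, trace=res.trace,
            converged=res.converged, n_iter=res.n_iter,
            n_subjects=self.cohort.n_subjects, n_obs=self.cohort.n_records)


class LairdWareLinear(GrowthCurveModel):
    """Random-intercept-and-slope linear growth model."""

    model_name = "lwlinear"


class LairdWareQuadratic(GrowthCurveModel):
    """Quadratic extension with a random curvature term per child."""

    model_name = "lwquad"


class Brokenstick(GrowthCurveModel):
    """Piecewise-linear (degree-1 B-spline) growth model.

    One correlated random effect per knot; the fixed and random designs
    share the B-spline columns, and a child's trajectory is the line
    interpolant of their conditional knot means.
    """

    model_name = "brokenstick"


class PenalizedSpline(GrowthCurveModel):
    """Penalized-spline mixed model (population + subject smooths)."""

    model_name = "penalized_spline"

    def fit(self, **fit_kwargs) -> FittedLMM | FitFailure:
        frame = self.cohort.frame
        times = frame["age_days"].to_numpy(float)
        X = self.basis.fixed_design(times)
        T = self.basis.penalized_design(times)
        Z = self.basis.random_design(times)
        y = self.cohort.values(self.spec.scale)
        groups = frame["subject_id"].to_numpy()
        try:
            res = reml.fit_shared_spline(X, T, Z, y, groups, **fit_kwargs)
        except (GrowthDataError, np.linalg.LinAlgError) as e:
            return FitFailure(self.spec.model, self.spec.scale, str(e))
        if not res.converged:
            return FitFailure(self.spec.model, self.spec.scale, res.message,
                              diagnostics={"n_iter": res.n_iter,
                                           "loglik": res.loglik})
        return FittedLMM(
            spec=self.spec, basis=self.basis, beta=res.beta, G=res.G,
            sigma2=res.sigma2, loglik=res.loglik, trace=res.trace,
            converged=res.converged, n_iter=res.n_iter,
            n_subjects=self.cohort.n_subjects, n_obs=self.cohort.n_records,
            u_blup=res.u_blup, sigma_u2=res.sigma_u2)


def fit_lmm_from_spec(cohort: Cohort, spec: ModelSpec,
                      age_range=None, **fit_kwargs):
    """Convenience: build the model for a spec and fit it."""
    model = GrowthCurveModel.from_spec(cohort, spec, age_range=age_range)
    return model.fit(**fit_kwargs)
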