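"""Time bases for the mixed-model growth curves.

All bases work on age rescaled to u = (t - lo) / (hi - lo) in [0, 1] for
numerical conditioning; knots are stored in days and reported in days.

* ``lwlinear``          fixed/random columns [1, u]
* ``lwquad``            fixed/random columns [1, u, u^2]
* ``brokenstick``       degree-1 B-spline basis on the knot vector; the
                        fixed and subject random designs share the same
                        columns, one per knot (boundary knots included)
* ``penalized_spline``  fixed [1, u] plus truncated lines (u - k)_+ at the
                        population knots (penalized, i.e. random with an
                        iid variance); subject random design [1, u] plus
                        truncated lines at the subject knots
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

from .data import Cohort, ConfigurationError, GrowthDataError, ModelSpec


class DegenerateDesignError(GrowthDataError):
    pass


class RangeError(GrowthDataError):
    """Requested times fall outside the basis age range."""


@dataclass(frozen=True)
class BasisDescriptor:
    """Defines the fixed and subject random design columns of one model.

    ``knots`` are internal knots in days; ``age_lo``/``age_hi`` are the
    boundary (and rescaling) endpoints in days.  ``subject_knots`` is only
    used by the penalized-spline model.
    """

    model: str
    age_lo: float
    age_hi: float
    knots: tuple[float, ...] = ()
    subject_knots: tuple[float, ...] = ()
    degree: int = 1

    def __post_init__(self):
        if not self.age_hi > self.age_lo:
            raise DegenerateDesignError("age range must have positive width")
        k = np.asarray(self.knots, float)
        if k.size and (np.any(np.diff(k) <= 0) or k[0] <= self.age_lo
                       or k[-1] >= self.age_hi):
            raise DegenerateDesignError(
                "internal knots must be strictly increasing and strictly "
                "inside the age range")

    # -- helpers ---------------------------------------------------------

    def rescale(self, times) -> np.ndarray:
        return (np.asarray(times, float) - self.age_lo) / (self.age_hi - self.age_lo)

    def _check_range(self, times, tol=1e-8):
        t = np.asarray(times, float)
        if t.size and ((t < self.age_lo - tol).any() or (t > self.age_hi + tol).any()):
            raise RangeError(
                f"times outside basis range [{self.age_lo}, {self.age_hi}]")

    @property
    def _uknots(self) -> np.ndarray:
        return self.rescale(np.asarray(self.knots, float))

    @property
    def _usubject_knots(self) -> np.ndarray:
        return self.rescale(np.asarray(self.subject_knots, float))

    def _bspline_basis(self, u: np.ndarray) -> np.ndarray:
        # degree-1 B-splines on [0,1] with the internal knots: K+2 columns,
        # rows sum to one (partition of unity)
        tk = np.concatenate([[0.0, 0.0], self._uknots, [1.0, 1.0]])
        u = np.clip(u, 0.0, 1.0)
        return BSpline.design_matrix(u, tk, 1).toarray()

    # -- design matrices -------------------------------------------------

    def fixed_design(self, times) -> np.ndarray:
        self._check_range(times)
        u = self.rescale(times)
        if self.model in ("lwlinear", "penalized_spline"):
            return np.column_stack([np.ones_like(u), u])
        if self.model == "lwquad":
            return np.column_stack([np.ones_like(u), u, u * u])
        if self.model == "brokenstick":
            return self._bspline_basis(u)
        raise ConfigurationError(f"no fixed design for model {self.model!r}")

    def penalized_design(self, times) -> np.ndarray:
        """Population truncated-line columns (penalized_spline only)."""
        self._check_range(times)
        u = self.rescale(times)
        return np.maximum(u[:, None] - self._uknots[None, :], 0.0)

    def random_design(self, times) -> np.ndarray:
        self._check_range(times)
        u = self.rescale(times)
        if self.model in ("lwlinear", "lwquad", "brokenstick"):
            return self.fixed_design(times)
        if self.model == "penalized_spline":
            trunc = np.maximum(u[:, None] - self._usubject_knots[None, :], 0.0)
            return np.column_stack([np.ones_like(u), u, trunc])
        raise ConfigurationError(f"no random design for model {self.model!r}")

    @property
    def n_fixed(self) -> int:
        return {"lwlinear": 2, "lwquad": 3, "penalized_spline": 2,
                "brokenstick": len(self.knots) + 2}[self.model]

    @property
    def n_random(self) -> int:
        if self.model == "penalized_spline":
            return 2 + len(self.subject_knots)
        return self.n_fixed

    @property
    def knot_ages(self) -> np.ndarray:
        """All knots in days including the boundary endpoints."""
        return np.concatenate([[self.age_lo], self.knots, [self.age_hi]])


def build_design(spec: ModelSpec, basis: BasisDescriptor, times):
    """Return ``(fixed, random)`` design matrices at the given ages.

    For the penalized-spline model the population truncated-line columns are
    appended after the [1, t] fixed columns; they are fitted as penalized
    (random) coefficients but belong to the population curve.
    """
    if spec.model != basis.model:
        raise ConfigurationError("spec and basis disagree on the model")
    X = basis.fixed_design(times)
    if spec.model == "penalized_spline":
        X = np.column_stack([X, basis.penalized_design(times)])
    return X, basis.random_design(times)


def default_knots(cohort: Cohort, spec: ModelSpec,
                  age_range: tuple[float, float] | None = None) -> np.ndarray:
    """Deterministic internal-knot rule.

    The number of internal knots is the rounded mean number of observations
    per child, clamped to [2, 10] — never more knots than the average number
    of growth observations per child.  Placement is either equally spaced
    over the age range (``even_age``) or at age quantiles
    (``even_quantile``); boundary knots sit at the range endpoints and are
    not counted as internal.  ``age_range`` overrides the observed range —
    during cross-validation the full-study range is used so every fold's
    model shares one knot vector.
    """
    ages = cohort.frame["age_days"].to_numpy(float)
    if len(np.unique(ages)) < 2:
        raise DegenerateDesignError("need at least 2 distinct ages to place knots")
    if spec.n_internal_knots == "auto":
        mean_obs = cohort.n_records / cohort.n_subjects
        n_internal = int(np.clip(round(mean_obs), 2, 10))
    else:
        n_internal = int(spec.n_internal_knots)
    lo, hi = age_range if age_range is not None \
        else (float(ages.min()), float(ages.max()))
    if spec.knot_placement == "even_age":
        knots = np.linspace(lo, hi, n_internal + 2)[1:-1]
    else:
        q = np.linspace(0, 1, n_internal + 2)[1:-1]
        knots = np.quantile(ages, q)
        # quantile knots can coincide on gappy data; nudge to strict order
        knots = np.maximum.accumulate(knots)
        for i in range(1, len(knots)):
            if knots[i] <= knots[i - 1]:
                knots[i] = knots[i - 1] + 1e-9 * (hi - lo)
        knots = np.clip(knots, lo + 1e-9 * (hi - lo), hi - 1e-9 * (hi - lo))
    return np.asarray(knots, float)


def make_basis(cohort: Cohort, spec: ModelSpec,
               age_range: tuple[float, float] | None = None) -> BasisDescriptor:
    """Build the :class:`BasisDescriptor` for a spec on a cohort.

    ``age_range`` overrides the boundary endpoints (e.g. the full-study
    range during cross-validation so holdout ages stay inside the basis).
    """
    lo, hi = age_range if age_range is not None else cohort.age_range
    if spec.model in ("lwlinear", "lwquad"):
        return BasisDescriptor(spec.model, lo, hi)
    knots = default_knots(cohort, spec, age_range=(lo, hi))
    knots = knots[(knots > lo) & (knots < hi)]
    if spec.model == "brokenstick":
        return BasisDescriptor("brokenstick", lo, hi, knots=tuple(knots))
    # penalized_spline: subject knots default to min(population knots, 3)
    n_sub = spec.subject_knots if spec.subject_knots is not None \
        else min(len(knots), 3)
    sub = np.linspace(lo, hi, n_sub + 2)[1:-1]
    return BasisDescriptor("penalized_spline", lo, hi,
                           knots=tuple(knots), subject_knots=tuple(sub))
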