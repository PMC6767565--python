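"""LMS standardisation between raw anthropometry and age/sex Z scores.

A growth reference supplies, per sex, three smooth curves over age: the
Box-Cox power L(t), the median M(t) and the coefficient of variation S(t).
A raw measurement y at age t converts to a Z score by

    z = ((y / M)^L - 1) / (L * S)     for L != 0
    z = ln(y / M) / S                 for L == 0

which is Cole's LMS transformation; it is strictly increasing in y and has
an exact algebraic inverse, so trajectories fitted on one scale can be
carried to the other.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import Cohort, GrowthDataError, SEXES

_L_EPS = 1e-7  # |L| below this uses the logarithmic limit


class AgeOutOfRangeError(GrowthDataError):
    """Requested age falls outside the reference grid (no extrapolation)."""


class LMSReference:
    """Sex-specific age grid of (L, M, S) values.

    Lookup between grid ages is piecewise linear; ages outside the grid are
    errors, never extrapolated.
    """

    def __init__(self, tables: dict[str, pd.DataFrame]):
        self._tables = {}
        for sex in SEXES:
            if sex not in tables:
                raise GrowthDataError(f"reference missing sex {sex!r}")
            t = tables[sex].loc[:, ["age_days", "L", "M", "S"]].astype(float)
            t = t.sort_values("age_days", kind="stable").reset_index(drop=True)
            ages = t["age_days"].to_numpy()
            if len(ages) < 2 or np.any(np.diff(ages) <= 0):
                raise GrowthDataError(
                    f"{sex} age grid must be strictly increasing with >= 2 points")
            if (t["M"] <= 0).any() or (t["S"] <= 0).any():
                raise GrowthDataError("M and S must be positive everywhere")
            if not np.isfinite(t[["L", "M", "S"]].to_numpy()).all():
                raise GrowthDataError("non-finite L/M/S values")
            self._tables[sex] = t

    @classmethod
    def from_csv(cls, path) -> "LMSReference":
        """Load from CSV with columns ``sex,agedays,L,M,S``."""
        df = pd.read_csv(path)
        missing = {"sex", "agedays", "L", "M", "S"} - set(df.columns)
        if missing:
            raise GrowthDataError(f"reference CSV missing columns {sorted(missing)}")
        df = df.rename(columns={"agedays": "age_days"})
        df["sex"] = df["sex"].astype(str).str.lower()
        return cls({sex: df[df["sex"] == sex] for sex in SEXES})

    def to_csv(self, path) -> None:
        rows = []
        for sex in SEXES:
            t = self._tables[sex].copy()
            t.insert(0, "sex", sex)
            rows.append(t)
        out = pd.concat(rows).rename(columns={"age_days": "agedays"})
        out.to_csv(path, index=False)

    def age_range(self, sex: str) -> tuple[float, float]:
        a = self._tables[sex]["age_days"].to_numpy()
        return float(a[0]), float(a[-1])

    def lookup(self, sex: str, age_days) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Interpolate (L, M, S) at one or more ages for one sex."""
        if sex not in SEXES:
            raise GrowthDataError(f"unknown sex {sex!r}")
        t = self._tables[sex]
        age = np.atleast_1d(np.asarray(age_days, float))
        grid = t["age_days"].to_numpy()
        if (age < grid[0]).any() or (age > grid[-1]).any():
            bad = age[(age < grid[0]) | (age > grid[-1])]
            raise AgeOutOfRangeError(
                f"ages {bad[:5]} outside {sex} reference grid "
                f"[{grid[0]}, {grid[-1]}]")
        L = np.interp(age, grid, t["L"].to_numpy())
        M = np.interp(age, grid, t["M"].to_numpy())
        S = np.interp(age, grid, t["S"].to_numpy())
        if np.isscalar(age_days) or np.ndim(age_days) == 0:
            return float(L[0]), float(M[0]), float(S[0])
        return L, M, S


def lms_lookup(ref: LMSReference, sex: str, age_days):
    """Functional alias for :meth:`LMSReference.lookup`."""
    return ref.lookup(sex, age_days)


def raw_to_z(y, L, M, S):
    """Cole LMS transform of raw value(s) to Z score(s)."""
    y = np.asarray(y, float)
    L = np.asarray(L, float)
    M = np.asarray(M, float)
    S = np.asarray(S, float)
    if (y <= 0).any() if y.ndim else y <= 0:
        raise GrowthDataError("raw values must be > 0")
    ratio = y / M
    with np.errstate(divide="ignore", invalid="ignore"):
        z_pow = (np.power(ratio, L) - 1.0) / (L * S)
    z_log = np.log(ratio) / S
    z = np.where(np.abs(L) < _L_EPS, z_log, z_pow)
    return z if z.ndim else float(z)


def z_to_raw(z, L, M, S):
    """Exact inverse of :func:`raw_to_z`.

    For L != 0 the argument must satisfy 1 + L*S*z > 0, otherwise the
    transform is not invertible at that point.
    """
    z = np.asarray(z, float)
    L = np.asarray(L, float)
    M = np.asarray(M, float)
    S = np.asarray(S, float)
    base = 1.0 + L * S * z
    nonlog = np.abs(L) >= _L_EPS
    if np.any(nonlog & (base <= 0)):
        raise GrowthDataError("z outside the invertibility domain (1 + L*S*z <= 0)")
    with np.errstate(divide="ignore", invalid="ignore"):
        y_pow = M * np.power(np.where(nonlog, base, 1.0), 1.0 / np.where(nonlog, L, 1.0))
    y_log = M * np.exp(S * z)
    y = np.where(nonlog, y_pow, y_log)
    return y if y.ndim else float(y)


def standardize_cohort(cohort: Cohort, ref: LMSReference) -> Cohort:
    """Fill ``value_z`` for every record via the LMS reference.

    Raw values are untouched.  Any record whose age falls outside the
    reference grid for its sex raises :class:`AgeOutOfRangeError` listing
    the offending records.
    """
    frame = cohort.frame
    z = np.full(len(frame), np.nan)
    bad_rows = []
    for sex in SEXES:
        mask = (frame["sex"] == sex).to_numpy()
        if not mask.any():
            continue
        ages = frame.loc[mask, "age_days"].to_numpy(float)
        lo, hi = ref.age_range(sex)
        out = (ages < lo) | (ages > hi)
        if out.any():
            bad_rows.extend(np.flatnonzero(mask)[out].tolist())
            continue
        L, M, S = ref.lookup(sex, ages)
        z[mask] = raw_to_z(frame.loc[mask, "value_raw"].to_numpy(float), L, M, S)
    if bad_rows:
        raise AgeOutOfRangeError(
            f"{len(bad_rows)} records outside the reference age grid "
            f"(rows {bad_rows[:10]}...)")
    return cohort.with_z(z)
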