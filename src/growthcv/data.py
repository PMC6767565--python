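"""Core domain types and long-format anthropometry I/O.

The universal input is a long-format table with one row per measurement:
subject id, sex, age in days, measurement kind (height/weight) and the raw
value (cm or kg).  An optional Z-score column carries the age/sex
standardised value once a growth reference has been applied.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

SEXES = ("male", "female")
MEASURE_KINDS = ("height", "weight")
MODELS = ("lwlinear", "lwquad", "brokenstick", "penalized_spline", "face")
SCALES = ("raw", "z")

#: canonical internal column order
COLUMNS = ("subject_id", "sex", "age_days", "measure_kind", "value_raw", "value_z")

#: default external CSV column names
DEFAULT_CSV_COLUMNS = {
    "subject_id": "subject_id",
    "sex": "sex",
    "age_days": "agedays",
    "measure_kind": "kind",
    "value_raw": "value",
    "value_z": "zscore",
}

_SEX_ALIASES = {
    "male": "male", "m": "male", "boy": "male",
    "female": "female", "f": "female", "girl": "female",
}


class GrowthDataError(ValueError):
    """Invalid input data (bad columns, no valid rows, broken invariants)."""


class ConfigurationError(ValueError):
    """Invalid configuration (missing columns, bad model options)."""


@dataclass(frozen=True)
class GrowthRecord:
    """A single anthropometric measurement on one child."""

    subject_id: str
    sex: str                 # "male" | "female"
    age_days: float          # age at measurement, days, >= 0
    measure_kind: str        # "height" | "weight"
    value_raw: float         # cm for height, kg for weight, > 0
    value_z: float | None = None  # SD units relative to a reference, optional

    def problems(self) -> list[str]:
        """Return human-readable invariant violations (empty if valid)."""
        out = []
        if self.sex not in SEXES:
            out.append(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.measure_kind not in MEASURE_KINDS:
            out.append(f"kind must be one of {MEASURE_KINDS}, got {self.measure_kind!r}")
        if not np.isfinite(self.age_days) or self.age_days < 0:
            out.append(f"age_days must be finite and >= 0, got {self.age_days}")
        if not np.isfinite(self.value_raw) or self.value_raw <= 0:
            out.append(f"value_raw must be finite and > 0, got {self.value_raw}")
        if self.value_z is not None and not np.isfinite(self.value_z):
            out.append(f"value_z must be finite when present, got {self.value_z}")
        return out


class Cohort:
    """A validated collection of growth records for N children.

    Internally a :class:`pandas.DataFrame` with canonical columns
    ``subject_id, sex, age_days, measure_kind, value_raw, value_z``.
    The per-subject view is always sorted ascending by age with a stable
    sort, so same-day repeats keep their input order.
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.loc[:, list(COLUMNS)].reset_index(drop=True)
        if len(frame) == 0:
            raise GrowthDataError("cohort has zero records")
        # one sex per subject
        nsex = frame.groupby("subject_id", sort=False)["sex"].nunique()
        bad = nsex[nsex > 1]
        if len(bad):
            raise GrowthDataError(
                f"subjects with inconsistent sex: {list(bad.index[:5])}"
            )
        self._frame = frame

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_records(cls, records: Iterable[GrowthRecord]) -> "Cohort":
        rows = []
        for i, r in enumerate(records):
            probs = r.problems()
            if probs:
                raise GrowthDataError(f"record {i}: " + "; ".join(probs))
            rows.append(dataclasses.astuple(r))
        if not rows:
            raise GrowthDataError("no records supplied")
        frame = pd.DataFrame(rows, columns=list(COLUMNS))
        frame["value_z"] = frame["value_z"].astype(float)
        return cls(frame)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "Cohort":
        """Build from a canonical-column DataFrame, validating every row."""
        cohort, report = validate_rows(df)
        if len(report):
            raise GrowthDataError(
                f"{len(report)} invalid rows; first: {report.iloc[0]['reason']}"
            )
        return cohort

    # -- accessors --------------------------------------------------------

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    @property
    def n_records(self) -> int:
        return len(self._frame)

    @property
    def subject_ids(self) -> list[str]:
        """Subject ids in first-appearance order."""
        return list(self._frame["subject_id"].drop_duplicates())

    @property
    def n_subjects(self) -> int:
        return self._frame["subject_id"].nunique()

    @property
    def age_range(self) -> tuple[float, float]:
        a = self._frame["age_days"]
        return float(a.min()), float(a.max())

    def subject(self, subject_id: str) -> pd.DataFrame:
        """Records for one subject, stably sorted by age."""
        sub = self._frame[self._frame["subject_id"] == subject_id]
        if len(sub) == 0:
            raise KeyError(subject_id)
        return sub.sort_values("age_days", kind="stable")

    def by_subject(self):
        """Iterate ``(subject_id, records)`` with age-sorted stable views."""
        for sid, sub in self._frame.groupby("subject_id", sort=False):
            yield sid, sub.sort_values("age_days", kind="stable")

    def subset(self, subject_ids: Iterable[str]) -> "Cohort":
        keep = set(subject_ids)
        frame = self._frame[self._frame["subject_id"].isin(keep)]
        if len(frame) == 0:
            raise GrowthDataError("subset selects zero records")
        return Cohort(frame.copy())

    def values(self, scale: str) -> np.ndarray:
        """Response vector on the requested scale ("raw" or "z")."""
        if scale == "raw":
            return self._frame["value_raw"].to_numpy(float)
        if scale == "z":
            z = self._frame["value_z"].to_numpy(float)
            if np.isnan(z).any():
                raise GrowthDataError(
                    "value_z not filled; run standardize_cohort first"
                )
            return z
        raise ConfigurationError(f"unknown scale {scale!r}")

    def with_z(self, z: np.ndarray) -> "Cohort":
        frame = self._frame.copy()
        frame["value_z"] = np.asarray(z, float)
        return Cohort(frame)

    # -- I/O --------------------------------------------------------------

    def to_csv(self, path, column_map: Mapping[str, str] | None = None) -> None:
        write_cohort(self, path, column_map)

    def __len__(self) -> int:
        return len(self._frame)

    def __repr__(self) -> str:
        return f"<Cohort: {self.n_subjects} subjects, {self.n_records} records>"


def _normalise(df: pd.DataFrame) -> pd.DataFrame:
    out = pd.DataFrame({
        "subject_id": df["subject_id"].astype(str),
        "sex": df["sex"].astype(str).str.strip().str.lower().map(_SEX_ALIASES),
        "age_days": pd.to_numeric(df["age_days"], errors="coerce"),
        "measure_kind": df["measure_kind"].astype(str).str.strip().str.lower(),
        "value_raw": pd.to_numeric(df["value_raw"], errors="coerce"),
    })
    if "value_z" in df.columns:
        out["value_z"] = pd.to_numeric(df["value_z"], errors="coerce")
    else:
        out["value_z"] = np.nan
    return out


def validate_rows(df: pd.DataFrame) -> tuple[Cohort | None, pd.DataFrame]:
    """Split a canonical-column DataFrame into a Cohort and a rejection report.

    Returns ``(cohort, report)``; ``cohort`` is None when no row is valid.
    The report has one row per rejected input row: ``row`` (0-based input
    position) and ``reason``.
    """
    norm = _normalise(df)
    reasons = pd.Series("", index=norm.index, dtype=object)

    def flag(mask, msg):
        nonlocal reasons
        mask = mask & (reasons == "")
        reasons[mask] = msg

    flag(norm["sex"].isna(), f"sex not recognised (expected one of {SEXES})")
    flag(~norm["measure_kind"].isin(MEASURE_KINDS),
         f"kind not recognised (expected one of {MEASURE_KINDS})")
    flag(norm["age_days"].isna() | ~np.isfinite(norm["age_days"])
         | (norm["age_days"] < 0), "age_days must be finite and >= 0")
    flag(norm["value_raw"].isna() | ~np.isfinite(norm["value_raw"])
         | (norm["value_raw"] <= 0), "value_raw must be finite and > 0")
    had_z = "value_z" in df.columns and df["value_z"].notna()
    if isinstance(had_z, pd.Series):
        flag(had_z & ~np.isfinite(norm["value_z"].fillna(np.inf)),
             "value_z must be finite when present")

    bad = reasons != ""
    report = pd.DataFrame({
        "row": norm.index[bad], "reason": reasons[bad].to_numpy(),
    }).reset_index(drop=True)
    good = norm[~bad]
    if len(good) == 0:
        return None, report
    return Cohort(good), report


def read_cohort(path, column_map: Mapping[str, str] | None = None,
                strict: bool = False) -> tuple[Cohort, pd.DataFrame]:
    """Read a long-format CSV into a validated Cohort.

    Parameters
    ----------
    path : path to a delimited text file with a header row.
    column_map : optional mapping from canonical names
        (``subject_id, sex, age_days, measure_kind, value_raw, value_z``)
        to the file's column names; unmapped names fall back to the
        defaults ``subject_id, sex, agedays, kind, value, zscore``.
    strict : raise if any row is rejected instead of reporting it.

    Returns
    -------
    (cohort, rejection_report) — rejected rows are listed, never silently
    dropped.
    """
    cmap = dict(DEFAULT_CSV_COLUMNS)
    if column_map:
        unknown = set(column_map) - set(cmap)
        if unknown:
            raise ConfigurationError(f"unknown canonical columns: {sorted(unknown)}")
        cmap.update(column_map)
    df = pd.read_csv(path)
    required = {k: v for k, v in cmap.items() if k != "value_z"}
    missing = [v for v in required.values() if v not in df.columns]
    if missing:
        raise ConfigurationError(f"missing columns in {path}: {missing}")
    renamed = df.rename(columns={v: k for k, v in cmap.items()})
    cohort, report = validate_rows(renamed)
    if strict and len(report):
        raise GrowthDataError(f"{len(report)} invalid rows in {path}")
    if cohort is None:
        raise GrowthDataError(f"no valid rows in {path}")
    return cohort, report


def write_cohort(cohort: Cohort, path,
                 column_map: Mapping[str, str] | None = None) -> None:
    """Write a cohort as RFC-4180 CSV with the default external column names."""
    cmap = dict(DEFAULT_CSV_COLUMNS)
    if column_map:
        cmap.update(column_map)
    out = cohort.frame.rename(columns=cmap)
    if out[cmap["value_z"]].isna().all():
        out = out.drop(columns=[cmap["value_z"]])
    out.to_csv(path, index=False, lineterminator="\r\n")


def summarize_cohort(cohort: Cohort) -> pd.DataFrame:
    """One-row study summary: child/observation counts, per-child
    observation min/max/median and the age min/max/median (days)."""
    f = cohort.frame
    per_child = f.groupby("subject_id", sort=False).size()
    return pd.DataFrame([{
        "n_children": int(cohort.n_subjects),
        "n_obs": int(len(f)),
        "obs_per_child_min": int(per_child.min()),
        "obs_per_child_max": int(per_child.max()),
        "obs_per_child_median": float(per_child.median()),
        "age_min": float(f["age_days"].min()),
        "age_max": float(f["age_days"].max()),
        "age_median": float(f["age_days"].median()),
    }])


@dataclass(frozen=True)
class ModelSpec:
    """One model x scale arm of the comparison.

    Parameters
    ----------
    model : one of ``lwlinear, lwquad, brokenstick, penalized_spline, face``.
    scale : fit on ``raw`` values or on ``z`` scores.
    n_internal_knots : internal knot count for the spline-based models, or
        ``"auto"`` for the deterministic default rule; for ``face`` this
        sets the marginal basis size of the mean/covariance smoothers.
    knot_placement : ``even_age`` (equally spaced) or ``even_quantile``
        (age quantiles).
    pve_threshold : proportion of variance explained used to truncate the
        FPCA expansion (face only).
    subject_knots : number of subject-level spline knots
        (penalized_spline only).
    """

    model: str
    scale: str = "z"
    n_internal_knots: int | str = "auto"
    knot_placement: str = "even_age"
    pve_threshold: float | None = None
    subject_knots: int | None = None

    def __post_init__(self):
        if self.model not in MODELS:
            raise ConfigurationError(
                f"unsupported model {self.model!r}; choose from {MODELS}")
        if self.scale not in SCALES:
            raise ConfigurationError(f"scale must be 'raw' or 'z', got {self.scale!r}")
        if self.knot_placement not in ("even_age", "even_quantile"):
            raise ConfigurationError(
                f"unknown knot_placement {self.knot_placement!r}")
        if self.n_internal_knots != "auto":
            if not (isinstance(self.n_internal_knots, (int, np.integer))
                    and self.n_internal_knots >= 1):
                raise ConfigurationError("n_internal_knots must be 'auto' or >= 1")
        if self.model == "face":
            if self.subject_knots is not None:
                raise ConfigurationError("subject_knots is not a face option")
            if self.pve_threshold is not None and not (0 < self.pve_threshold <= 1):
                raise ConfigurationError("pve_threshold must be in (0, 1]")
        else:
            if self.pve_threshold is not None:
                raise ConfigurationError("pve_threshold is a face-only option")
            if self.subject_knots is not None and self.model != "penalized_spline":
                raise ConfigurationError(
                    "subject_knots is a penalized_spline-only option")
            if self.subject_knots is not None and self.subject_knots < 1:
                raise ConfigurationError("subject_knots must be >= 1")

    @property
    def label(self) -> str:
        return f"{self.model} ({self.scale})"
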