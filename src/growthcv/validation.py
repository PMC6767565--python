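"""Subject-level K-fold holdout cross-validation of growth models.

The procedure compares model x scale arms on their ability to predict a
single held-out measurement per validation child:

1. assign each child to one of K nearly equal, disjoint folds;
2. for each fold, fit the model on the other K-1 folds only;
3. for each validation child, remove one measurement (uniformly at random,
   or the oldest-age "last value") and predict it from the child's
   remaining measurements via the fitted model's conditional mean;
4. score with the mean squared error, always on the Z scale — raw-scale
   predictions are LMS-transformed at the holdout age/sex before scoring,
   which is legitimate because the transform is monotone.

The overall score is the average of the per-fold MSEs, so every eligible
child contributes exactly one squared error to exactly one fold.  Children
with a single measurement have no predictors left after the holdout; they
are ineligible, stay in the training folds, and are counted in the report.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .basis import RangeError
from .data import Cohort, ConfigurationError, GrowthDataError, ModelSpec
from .models import FitFailure, GrowthCurveModel
from .zscore import AgeOutOfRangeError, LMSReference, raw_to_z, standardize_cohort


@dataclass(frozen=True)
class FoldAssignment:
    """Disjoint, exhaustive subject partition into folds 1..K."""

    folds: dict[str, int]
    K: int
    seed: int

    def subjects_in(self, k: int) -> list[str]:
        return [s for s, f in self.folds.items() if f == k]


@dataclass(frozen=True)
class HoldoutEntry:
    """One child's held-out record index and remaining predictor indices
    (positions within the child's age-sorted record view)."""

    holdout_index: int
    remaining_indices: tuple[int, ...]


@dataclass
class CVResult:
    """Per-subject holdout predictions and the fold-averaged Z-scale MSE."""

    spec: ModelSpec
    K: int
    mode: str
    seed: int
    predictions: pd.DataFrame        # subject, fold, age, observed_z, predicted_z, sq_error
    fold_mse: dict[int, float]
    overall_mse: float | None
    n_ineligible: int
    failures: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return self.overall_mse is not None


def partition_subjects(subject_ids, K: int, seed: int) -> FoldAssignment:
    """Seeded uniform partition into K folds with sizes differing by <= 1.

    The permutation is keyed to the sorted id list, so the assignment is
    invariant to the input order of subjects.
    """
    ids = sorted(set(map(str, subject_ids)))
    N = len(ids)
    if K < 2 or K > N:
        raise ConfigurationError(f"need 2 <= K <= number of subjects ({N}), got {K}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(N)
    folds = {}
    sizes = np.full(K, N // K)
    sizes[: N % K] += 1
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    for k in range(K):
        for j in perm[bounds[k]:bounds[k + 1]]:
            folds[ids[j]] = k + 1
    return FoldAssignment(folds=folds, K=K, seed=seed)


def _subject_seed(seed: int, subject_id: str) -> int:
    # keyed by (global seed, id): one child's holdout never depends on the
    # rest of the cohort
    h = hashlib.sha256(f"{seed}:{subject_id}".encode()).digest()
    return int.from_bytes(h[:4], "big")


def select_holdout(subject_records: pd.DataFrame, mode: str,
                   seed: int, subject_id: str | None = None) -> HoldoutEntry | None:
    """Pick the held-out record for one child (or None if ineligible).

    ``mode="last"`` removes the oldest-age observation (ties break by input
    order: the last of the tied records); ``mode="random"`` removes one
    uniformly, seeded per subject.  Children with fewer than 2 records are
    ineligible.
    """
    n = len(subject_records)
    if n < 2:
        return None
    if mode == "last":
        ages = subject_records["age_days"].to_numpy(float)
        idx = int(np.flatnonzero(ages == ages.max())[-1])
    elif mode == "random":
        sid = subject_id if subject_id is not None \
            else str(subject_records["subject_id"].iloc[0])
        rng = np.random.default_rng(_subject_seed(seed, sid))
        idx = int(rng.integers(n))
    else:
        raise ConfigurationError(f"unknown holdout mode {mode!r}")
    remaining = tuple(i for i in range(n) if i != idx)
    return HoldoutEntry(holdout_index=idx, remaining_indices=remaining)


def mse(observed, predicted) -> float:
    """Mean squared error (1/m) sum (y - yhat)^2."""
    y = np.asarray(observed, float)
    yhat = np.asarray(predicted, float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise GrowthDataError("observed and predicted must be equal-length vectors")
    if len(y) == 0:
        raise GrowthDataError("MSE of zero predictions is undefined")
    return float(np.mean((y - yhat) ** 2))


def run_cv(cohort: Cohort, spec: ModelSpec, ref: LMSReference,
           K: int = 10, mode: str = "random", seed: int = 0,
           folds: FoldAssignment | None = None) -> CVResult:
    """Cross-validate one model x scale arm; see the module docstring.

    ``folds`` may be supplied so several arms share identical fold and
    holdout assignments (as :func:`compare_models` does).  The spline knot
    rule and basis range are computed once from the full cohort, so every
    fold's model shares the same basis and holdout ages stay in range.
    """
    cohort = standardize_cohort(cohort, ref)
    if folds is None:
        folds = partition_subjects(cohort.subject_ids, K, seed)
    elif folds.K != K:
        raise ConfigurationError("supplied folds disagree with K")

    age_range = cohort.age_range
    rows = []
    fold_mse: dict[int, float] = {}
    failures: list[str] = []
    n_inelig = 0

    subj_frames = {sid: sub for sid, sub in cohort.by_subject()}
    holdouts = {}
    for sid, sub in subj_frames.items():
        entry = select_holdout(sub, mode, seed, subject_id=sid)
        if entry is None:
            n_inelig += 1
        holdouts[sid] = entry

    for k in range(1, K + 1):
        valid_ids = folds.subjects_in(k)
        train_ids = [s for s in cohort.subject_ids if folds.folds[s] != k]
        train = cohort.subset(train_ids)
        model = GrowthCurveModel.from_spec(train, spec, age_range=age_range)
        fit = model.fit()
        if isinstance(fit, FitFailure):
            failures.append(f"fold {k}: {fit.reason}")
            continue
        for sid in valid_ids:
            entry = holdouts[sid]
            if entry is None:
                continue
            sub = subj_frames[sid]
            ages = sub["age_days"].to_numpy(float)
            vals = sub["value_raw" if spec.scale == "raw" else "value_z"] \
                .to_numpy(float)
            ho_age = float(ages[entry.holdout_index])
            obs_ages = ages[list(entry.remaining_indices)]
            obs_vals = vals[list(entry.remaining_indices)]
            observed_z = float(sub["value_z"].to_numpy(float)[entry.holdout_index])
            try:
                pred = float(fit.predict_subject(obs_ages, obs_vals,
                                                 [ho_age])[0])
                if spec.scale == "raw":
                    sex = str(sub["sex"].iloc[0])
                    L, M, S = ref.lookup(sex, ho_age)
                    if pred <= 0:
                        raise GrowthDataError(
                            f"non-positive raw prediction {pred:.3g}")
                    pred_z = float(raw_to_z(pred, L, M, S))
                else:
                    pred_z = pred
            except (GrowthDataError, RangeError, AgeOutOfRangeError) as e:
                failures.append(f"subject {sid}: {e}")
                continue
            rows.append((sid, k, ho_age, observed_z, pred_z,
                         (observed_z - pred_z) ** 2))

    preds = pd.DataFrame(rows, columns=["subject_id", "fold", "age_days",
                                        "observed_z", "predicted_z",
                                        "sq_error"])
    for k in sorted(preds["fold"].unique()):
        fold_mse[int(k)] = float(preds.loc[preds["fold"] == k, "sq_error"].mean())
    overall = float(np.mean(list(fold_mse.values()))) if fold_mse else None
    return CVResult(spec=spec, K=K, mode=mode, seed=seed, predictions=preds,
                    fold_mse=fold_mse, overall_mse=overall,
                    n_ineligible=n_inelig, failures=failures)


def compare_models(cohort: Cohort, specs: list[ModelSpec],
                   ref: LMSReference, K: int = 10, mode: str = "random",
                   seed: int = 0) -> pd.DataFrame:
    """Cross-validate several arms on identical folds and holdouts.

    Returns one row with an MSE column per arm (NaN for arms whose every
    fold failed), a ``min_arm`` column flagging the smallest MSE, and a
    failure count per arm.
    """
    if not specs:
        raise ConfigurationError("need at least one model spec")
    folds = partition_subjects(cohort.subject_ids, K, seed)
    results = {}
    fails = {}
    for spec in specs:
        res = run_cv(cohort, spec, ref, K=K, mode=mode, seed=seed, folds=folds)
        results[spec.label] = res.overall_mse if res.ok else np.nan
        fails[spec.label] = len(res.failures)
    row = {label: results[label] for label in results}
    finite = {l: v for l, v in row.items() if np.isfinite(v)}
    if finite:
        best = min(finite.values())
        # arms within numerical precision of the minimum share the flag
        # (nested models can tie to machine accuracy on model-true data)
        row["min_arm"] = " | ".join(
            l for l, v in finite.items()
            if v <= best + 1e-9 + 1e-6 * abs(best))
    else:
        row["min_arm"] = ""
    for label in results:
        row[f"failures[{label}]"] = fails[label]
    return pd.DataFrame([row])


def knot_sensitivity(cohort: Cohort, template: ModelSpec, knot_grid,
                     ref: LMSReference, K: int = 10, modes=("random", "last"),
                     seed: int = 0) -> pd.DataFrame:
    """MSE by knot setting, on shared folds and holdouts.

    ``knot_grid`` entries are internal knot counts, or ``(population,
    subject)`` pairs for the penalized-spline model.  One row per setting,
    one MSE column per holdout mode.
    """
    from dataclasses import replace

    if len(knot_grid) == 0:
        raise ConfigurationError("empty knot grid")
    if isinstance(modes, str):
        modes = (modes,)
    folds = partition_subjects(cohort.subject_ids, K, seed)
    rows = []
    for setting in knot_grid:
        if template.model == "penalized_spline" and not np.isscalar(setting):
            pop, sub = setting
            spec = replace(template, n_internal_knots=int(pop),
                           subject_knots=int(sub))
            label = {"population_knots": int(pop), "subject_knots": int(sub)}
        else:
            spec = replace(template, n_internal_knots=int(setting))
            label = {"knots": int(setting)}
        row = dict(label)
        for mode in modes:
            res = run_cv(cohort, spec, ref, K=K, mode=mode, seed=seed,
                         folds=folds)
            row[f"mse_{mode}"] = res.overall_mse if res.ok else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
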