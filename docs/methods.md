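# Methods

This note documents the statistical machinery behind `growthcv`: the
models, the estimation algorithms and their numerical safeguards, the
cross-validation protocol, what the synthetic data do and do not emulate,
and the design decisions taken where more than one defensible choice
existed.

## Data model and standardisation

The universal input is a long-format table of growth records: subject id,
sex, age in days, measurement kind (height in cm or weight in kg), raw
value, and optionally a Z score.  Ages are always stored in days and no
unit conversion is ever implicit.  Same-day repeat measurements are kept
(real data contain them); within a subject the view is stably sorted by
age, so repeats retain their input order, and "last value" ties at the
maximal age break deterministically to the last of the tied records.
Records with missing or inconsistent sex are rejected, because the Z
transform is sex-specific.  Ingestion never drops rows silently: invalid
rows are returned in a rejection report.

Standardisation uses Cole's LMS method.  A reference supplies, per sex, a
strictly increasing age grid with Box–Cox power L(t), median M(t) and
coefficient of variation S(t); lookup is piecewise linear in age and ages
outside the grid are errors, never extrapolated — the caller must decide
what to do with out-of-range children.  The forward transform is
`z = ((y/M)^L − 1)/(L·S)`, with the logarithmic limit `ln(y/M)/S` used
when |L| < 1e-7; the inverse is exact (round trip to 1e-10), valid while
`1 + L·S·z > 0`.

## Mixed-model engine

All four parametric models are Gaussian linear mixed models
`y_i = X_i β + Z_i b_i + ε_i` with unstructured (or structured, below)
random-effect covariance G and residual variance σ².  Time is internally
rescaled to u = (t − lo)/(hi − lo) ∈ [0, 1] for conditioning; everything
user-facing is in days.

Bases:

* `lwlinear` X = Z = [1, u]; `lwquad` X = Z = [1, u, u²].
* `brokenstick`: degree-1 B-splines on the knot vector (boundary knots at
  the range endpoints plus M internal knots); rows sum to one, and the
  basis value at a knot is the indicator of that knot's column.  Fixed and
  random designs share the columns; G is unstructured (M+2)², since
  correlated knot effects are the model's defining feature.
* `penalized_spline`: fixed [1, u]; population truncated lines (u − κ)₊
  with iid ridge variance σ²ᵤ (the standard mixed-model representation of
  a penalized spline); subject design [1, u] plus subject truncated lines,
  with unstructured 2×2 covariance for the linear part and an iid variance
  for the subject spline coefficients.  The spec of the subject smooth is
  independent of the population knots; by default it uses
  min(population knots, 3) knots.

The default knot rule is deterministic: the number of internal knots is
the rounded mean number of observations per child clamped to [2, 10]
(never more knots than the average observations per child), placed evenly
over the age range or at age quantiles.  During cross-validation the
placement range is the full-study range, so every fold's model shares one
knot vector and holdout ages always lie inside the basis.

### REML estimation

Subject-only models (lwlinear, lwquad, brokenstick) are fitted by the
exact REML EM algorithm: the E-step uses the REML projection
`P = V⁻¹ − V⁻¹X(X'V⁻¹X)⁻¹X'V⁻¹`, the M-step averages the posterior
second moments of the random effects and residuals.  EM was chosen over
quasi-Newton on a log-Cholesky parameterisation because it (a) keeps G
positive semi-definite by construction, (b) increases the restricted
log-likelihood at every step — the recorded iteration trace is monotone,
which the tests assert — and (c) costs one batched linear-algebra sweep
per iteration regardless of the dimension of G (subjects are padded to a
common length; padded rows are exactly zero, so their contributions to
every sum cancel identically).  Near a rank-deficient boundary of G plain
EM crawls, so each cycle takes two EM steps and then a SQUAREM-style
extrapolation along the parameter change, kept only if it does not lower
the likelihood — the trace stays monotone and the iteration count drops
by an order of magnitude.  Convergence is a relative likelihood change
below 1e-8, or eight consecutive cycles without meaningful improvement
(flat to numerical precision, which happens at variance boundaries).

The residual variance is floored at `1e-9 · var(y)`: far below any real
measurement-error variance, but large enough that V remains invertible in
double precision on noiseless data (condition ~1e9; with a floor of
1e-14·var the likelihood jitters by ±0.2 and nothing converges).

The penalized-spline model has a population-level random vector u shared
by all rows, which breaks subject independence; its profiled REML
criterion (β and σ² profiled out; Woodbury identities handle the K shared
columns against the block-diagonal subject part) is minimised directly
over the five variance ratios by Nelder–Mead from three starts — the
5-parameter surface has genuine local optima, and a single start gave
inconsistent smoothing ratios across basis sizes.  On (near-)noiseless
data every ratio diverges as the profiled σ² falls to its floor; a
boundary-continuation step walks that valley directly (scaling the whole
covariance up while the criterion improves) and a fit pinned at the σ²
floor is reported as a boundary optimum, not a convergence failure.

Non-convergence and degenerate designs are returned as structured
`FitFailure` values, not exceptions: a cross-validation run logs them and
the comparison table renders the arm blank with a failure count.

### Conditional prediction

Prediction for a child with observations (t, y) at target ages s is the
empirical-Bayes conditional mean under the fitted model:

    E[Y(s) | y] = m(s) + Z(s) G Z(t)' (Z(t) G Z(t)' + σ²I)⁻¹ (y − m(t))

where m is the fitted population curve (for the penalized spline this
includes the BLUP of the shared spline coefficients).  With no
observations the prediction is the population curve; with G = 0 the
observations are ignored.  The brokenstick conditional knot means
ψᵢ = β + E[bᵢ | y] reproduce the predicted trajectory exactly when
connected by line segments.  Growth indicators over a window [a, b] are
the mean derivative (trajectory(b) − trajectory(a))/(b − a) — exact for
any trajectory by the fundamental theorem of calculus — and the
trapezoidal mean level.

## Sparse FPCA

The functional model keeps a smooth population curve f and a mean-zero
process hᵢ with covariance surface C(s, t), estimated stagewise:

1. f: cubic penalized B-spline smoother of the pooled scatter, smoothing
   parameter by GCV over a log-spaced grid.
2. Raw covariance: within-child residual cross-products r_ij·r_il for
   j ≠ l; same-age products are set aside (they estimate C(t,t) + σ²).
3. C: products are binned to the work grid (average-preserving, counts as
   weights) and smoothed by a bivariate weighted local-linear fit with a
   Gaussian kernel, bandwidth by GCV over a geometric grid.  Local-linear
   smoothing is used instead of a tensor-product penalized spline because
   its boundary behaviour stays linear: on irregular sparse designs most
   grid cells hold at most one product, GCV cannot see the data-poor
   corners, and spline surfaces there oscillate by an order of magnitude
   more than the signal.  The result is symmetrised and clipped to the
   Cauchy–Schwarz envelope √(v̄(s)·v̄(t)) of the (stable, 1-D
   local-linear) smoothed diagonal v̄ — a bound every valid covariance
   satisfies.
4. Eigendecomposition under trapezoid quadrature weights normalised to
   total weight one, so eigenfunctions are orthonormal with respect to
   the uniform measure on the age range and eigenvalues are on the
   Z-score variance scale.  Negative eigenvalues are truncated to zero;
   the smallest number of components reaching the PVE threshold (default
   0.95) is kept.
5. σ² = mean of (v̄ − diag C) over the central half of the age range
   (near the ends the two curves are boundary-attenuated at different
   rates, which would leak systematic error into σ²), floored at
   `1e-8 · var(residuals)`.

Prediction is the conditional-expectation (PACE) score estimate
`ξ̂ = Λ Φₒ'(Φₒ Λ Φₒ' + σ²I)⁻¹ (y − fₒ)` followed by `f + Φ ξ̂`, with
eigenfunctions interpolated linearly off the 51-point work grid.  When a
knot count is set explicitly (the sensitivity harness), it fixes the mean
smoother's basis size and maps the covariance bandwidth to the matching
inter-knot spacing; "auto" leaves both to GCV.

Because every stage is nonparametric, the fit carries estimation error
O(N^(−a)) that does not vanish on noiseless data: on model-true noiseless
cohorts the parametric models reach machine-precision cross-validated
MSE, while the FPCA arm plateaus around 0.1–0.2 at N = 300.  This is a
property of the estimator class, not a defect.

## Cross-validation protocol

Children are assigned to K folds (default 10) by a seeded uniform
permutation keyed to the sorted id list, so the assignment is invariant
to input order; fold sizes differ by at most one.  Per fold, the model is
fitted on the other folds; each validation child has one record removed —
uniformly at random (seeded per (global seed, child id), so one child's
holdout never depends on the rest of the cohort) or the oldest-age record
("last value", testing short-term extrapolation).  The prediction at the
holdout age conditions on the child's remaining records only.  Scoring is
MSE on the Z scale: a raw-scale arm's predicted raw value is
LMS-transformed at the holdout age and sex first (a raw prediction whose
transform is undefined is logged as a per-child failure, not dropped);
for a Z-scale fit, scoring directly equals scoring after a z→raw→z round
trip because the transform is monotone.  The overall MSE is the
unweighted mean of per-fold MSEs, so every eligible child contributes one
squared error to exactly one fold.  Single-record children have no
predictors left after a holdout: they stay in the training folds, are
excluded from scoring, and are counted in the result.

`compare_models` reuses one fold and holdout assignment across arms so
all arms are judged on identical holdouts; arms whose every fold failed
render blank.  Arms within numerical tolerance of the row-minimum MSE
share the minimum flag (nested models tie to machine accuracy on
model-true data); printed tables flag ties at the displayed precision.
`knot_sensitivity` repeats the comparison over a grid of knot settings
(pairs of population/subject knots for the penalized spline) on shared
holdouts.

## Synthetic data

The generator emulates the structure of multi-country child-growth
studies: 150–30,000 children, 1–77 irregular measurements each, ages
0–2,000 days.  Simulation is on the Z scale — mean curve plus correlated
random intercept and slope plus optional smooth eigenfunction deviations
plus Gaussian noise — with raw values derived through the inverse LMS
transform of a synthetic sex-dimorphic reference (qualitatively shaped
like height/weight references; deliberately *not* a reproduction of any
published table).  Fitting on Z is then exactly model-true for the linear
generator while fitting on raw is misspecified through the age-varying
reference — the contrast the comparison harness studies.  Observation
schedules start uniformly near the range floor and advance by log-normal
gaps (right-skewed, irregular); counts follow a clipped rounded
log-normal matched to a preset's median/min/max.  Study presets reproduce
documented per-study summaries (children, observations per child, age
span); the `faltering` preset declines from Z = 0 to −1.5 over the first
eight months with partial recovery to −1.0 by age two.  Its changepoint
sits at day 245 — between the nodes of a 3-internal-knot even grid on
[0, 730] but close to a 5-knot node — precisely so that a 3-knot
brokenstick genuinely underfits while a 5-knot fit captures the kink,
which is the effect the knot-sensitivity harness is designed to detect.
Children in this preset also carry a small sine-shaped smooth deviation
(variance 0.04) and measurement noise of 0.2 SD (≈0.5 cm of height
error).

A second generator draws cohorts exactly from each mixed-model family
(fixed curve + random effects from G + noise), anchoring the basis to the
observed age range so a model rebuilt from the cohort with the same knot
counts is *exactly* the generating model; an optional stratified schedule
places every child's observations across the whole range, keeping their
random effects identifiable from any subset of all-but-one observations
(without it, a child whose records miss a spline segment has an
under-determined trajectory even with noiseless data — an identifiability
fact the model-true sanity checks must respect).

What the generator does not emulate: real reference-table values, cohort
attrition, informative missingness, secular trends, or measurement-device
heterogeneity.  Passing tests therefore demonstrate correctness of the
estimators and the harness under the stated generative assumptions, not
performance on any particular real study.

## Numerical choices and limitations

* Conditional prediction adds a relative jitter of 1e-12 to the
  observation covariance before solving, guarding exactly singular
  conditioning on noiseless fits.
* GCV ridge selection anchors basis coefficients with (near-)zero data
  support with a small ridge — the difference penalty alone leaves them
  free and GCV cannot see them.
* Eigenvalue recovery tolerances reflect two-stage smoothing bias
  (typically ~10–20% at N = 1,000 sparse subjects); the covariance
  surface itself is accurate to ~0.1 RMSE under the documented replicate
  designs, with sup-norm errors concentrated along the diagonal kink of
  non-differentiable covariances and in data-poor corners.
* Penalized-spline predictions are stable but not bit-identical across
  population knot counts (each basis re-estimates its smoothing ratios by
  REML); the invariance that holds — and is tested — is at the level of
  reported MSEs, not machine precision.
* The comparison harness never fits a shifted/warped-time model (a
  nonlinear mixed model outside this framework's scope), and no
  statistical test is attached to MSE differences: the tables report raw
  MSEs only.
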