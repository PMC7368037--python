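# Methods

## Scope

`neuromodes` implements a multivariate individual-differences analysis:
sparse canonical correlation between functional-connectome features and
cognitive task scores, cross-validated penalty selection, permutation
family-wise-error testing of the recovered modes, and multivariate
regression linking per-subject mode scores to experience-sampling (MDES)
item means, including per-condition and per-day stability analyses. fMRI
preprocessing, parcellation fitting, cortical-thickness modelling, and
meta-analytic decoding are upstream/downstream of this package and are not
implemented; ranked loading tables stand in for word-cloud figures.

## The sparse CCA solver

The solver is a penalized rank-1 matrix decomposition on the cross-product
matrix `M = XᵀY` of the column-standardized blocks, the standard
diagonal-covariance surrogate for sparse CCA. For each mode, `v` is
initialized from the leading right singular vector of the current `M`, and
the updates

```
u ← P(Mv, c_x·√p),    v ← P(Mᵀu, c_y·√q)
```

alternate, where `P(a, c)` soft-thresholds `a` with the smallest threshold
δ ≥ 0 such that the L2-normalized result has L1 norm ≤ c. Iteration stops
when the largest weight change falls below `tol` (default 1e-6, max 200
iterations; non-convergence is flagged, not raised). The objective `uᵀMv`
is recorded per iteration and is non-decreasing. After convergence `M` is
deflated by `(uᵀMv)·uvᵀ`; extraction stops early if the deflated `M`
becomes numerically zero relative to its initial Frobenius norm, so
rank-deficient (e.g. noise-free) problems cannot emit spurious extra
modes. Modes are oriented so the largest-magnitude task weight is positive
(`u` and `v` flip jointly; the canonical correlation — the signed sample
Pearson correlation of `Xu` and `Yv` — is unchanged).

Penalty fractions in (0, 1] map linearly to absolute L1 bounds clipped to
`[1, √dim]`; fraction 1 imposes no sparsity, in which case mode k equals
the k-th singular pair of `M` exactly (checked against a direct SVD in the
tests).

**Threshold search.** The critical threshold solves a piecewise-quadratic
equation in δ: on the segment where the top-k magnitudes stay active, the
squared L1/L2 ratio is rational-quadratic, so the crossing is available in
closed form after one sort. This exact path is the default; a bisection
reference (tolerance 1e-8) is retained and the two agree to ~1e-7 in
property tests. Weights below 1e-12 of the largest are zeroed at the end
so reported supports are not polluted by floating-point dust.

## Feature engineering choices

- **Upper-triangle order** is row-major with i < j and 0-based ROI indices
  internally; 100 ROIs give 4,950 features.
- **Fisher z** uses `atanh` after clipping r to ±(1 − 1e-7), bounding |z|.
- **MAD filter** keeps the `floor(fraction·p)` largest median absolute
  deviations (floor is forced by 0.05 × 4950 = 247.5 → 247); ties break
  toward the lower column index and the selection preserves column order.
  The filter runs before confound residualization by default (the order is
  configurable; the alternative is equally defensible and the package does
  not privilege either on scientific grounds).
- **Residualization** projects each column onto the orthogonal complement
  of `[1, age, sex, mean FD]`; it is exact least squares, idempotent, and
  applied to both the connectivity and the task block.
- **Standardization** uses the n−1 denominator. The public
  `standardize_columns` raises on constant columns; inside cross-validation
  folds and on degenerate noise-free matrices a safe variant maps constant
  columns to zeros instead, because a constant feature carries no
  information and must not abort a fold.

## The 13 cognitive scores

The battery summary is a declarative schedule over five operators (mean,
contrast, efficiency, accuracy, negate). The default schedule emits:
digit span (mean of forward/backward), verbal fluency (category − letter),
picture naming, four mountains, matrix reasoning (accuracies), flexibility
and inhibition (negated switching costs), feature matching and paired
associate (reversed efficiency, −RT/accuracy), strength / modality /
specificity (contrasts of condition-wise efficiency scores from the
picture-word matching task), and an unusual-uses generation score. This is
one consistent reading of a battery whose family groupings admit
alternatives; the schedule is configuration, not code, so other readings
are expressible. Efficiency reversal is negation rather than reciprocal to
preserve linearity for the CCA. Assembled scores are standardized across
the cohort.

## Model selection

- **Penalty search**: Cartesian grid (default fractions 0.1–1.0 in steps
  of 0.1 per side), 5 subject-wise folds shuffled once with a recorded
  seed. Training folds are standardized and their statistics applied to
  the held-out fold; the CV score is the mean held-out signed correlation
  of the rank-1 variates. Degenerate folds contribute 0 with a warning
  counter. Ties prefer weaker penalties (larger c_x + c_y, then larger
  c_x).
- **Permutation test**: the behavioural matrix rows are shuffled (the
  connectivity block stays in place), the rank-1 model is refit per
  permutation, and every observed mode is compared against the null
  distribution of *first* canonical correlations —
  `p_FWE(k) = (1 + #{null ≥ r_k}) / (1 + B)` with B = 1,000 by default.
  The (1+b)/(1+B) estimator avoids zero p-values and makes the test valid
  and slightly conservative under exchangeability. Modes with
  p_FWE < 0.05 are accepted. Fewer than 100 permutations triggers a
  resolution warning.

## Mode scores and the thought-pattern regression

A subject's mode score is the mean of the z-scored connectivity and task
variates; the sum differs only by a factor of 2 and yields identical
downstream statistics (asserted in tests). The 13 MDES item means are
z-scored and regressed on [intercept, mode scores, age, sex, mean FD].
Each predictor is tested with a Type III hypothesis (the L-contrast form
`H = b̂ᵀ(LGLᵀ)⁻¹b̂`, equivalent to full-vs-reduced for continuous
predictors), Pillai's trace `V = tr(H(H+E)⁻¹)`, and the standard F
approximation with parameters `s = min(df_h, p)`,
`m = (|df_h − p| − 1)/2`, `n = (df_e − p − 1)/2`. The multivariate effect
size is defined as `η² = V/s` (multivariate effect sizes have no single
universal formula; this is the common convention for Pillai). The
implementation reports its own exact degrees of freedom. Coefficients are
standardized (per SD of the predictor, items at unit variance) and form
the 13-element *thought pattern*; stratum re-fits z-score items within
stratum and drop subjects only from strata they miss.

## The synthetic-cohort generator

The generator emulates the data structure of a ~178-subject study:
100-ROI connectomes (4,950 Fisher-z features), 13 task scores, 13 MDES
items under two task conditions across three days, and age / sex / motion
covariates with linear nuisance effects on every block.

**Planted structure.** Latent scores `z_k ~ N(0,1)`, independent across
modes, load onto sparse unit vectors with disjoint supports and exact
nonzero counts. The signal scale `c_k = σ·√(ρ_k/(1−ρ_k))` makes the
population canonical correlation of the planted variates exactly ρ_k
(default ρ = 0.57, 0.59 for two modes). Support weights are normally
distributed by default; an equal-magnitude option (±1/√m) exists because
column standardization of *noise-free* data retains only the sign of each
support weight, which is the right regime for exact-recovery tests.

**Dispersion profile.** Connectivity noise is heterogeneous by default: a
small pool (5 % of connections, containing the planted supports) varies at
the full noise SD while the rest varies at a reduced SD. This encodes the
working premise of the MAD filter — only connections that vary across
subjects can carry individual differences — and makes the filter a
meaningful stage in end-to-end experiments. Default per-mode connectivity
sparsity is 0.025 so two disjoint supports fill the retained pool.

**Tasks.** The raw task table is synthesized by inverting the score
schedule: every raw measure is a cohort-constant affine image of its
target score with ranges kept physical (accuracies in (0,1), positive
reaction times), so assembling and standardizing the raw table reproduces
the planted scores to machine precision.

**Thought reports.** Item means are `Z·L` plus a stable per-subject item
style (SD 0.65, shared across conditions and days) plus independent
stratum noise (SD 1). Day participation defaults to (1.0, 0.97, 0.85),
so later days have smaller samples. The default coupling SD (0.14) and
the style SD were calibrated jointly so that the fitted multivariate
effect size and the cross-condition / cross-day pattern stability land in
the ranges reported for studies of this design (η² ≈ 0.19; condition
stability ≈ 0.93–0.98; day stability ≈ 0.83–0.96). The empirical
between-item correlation structure of real probes is not asserted; an
optional item-correlation matrix can be supplied rather than guessed.

**Time-series mode.** Per-subject ROI series are drawn from a multivariate
normal whose correlation matrix inverts the planted Fisher-z values, after
a nearest-positive-definite repair (eigenvalue clipping at 1e-6 with
diagonal renormalization); an irreparable matrix fails loudly naming the
subject. Finite scan length (177 volumes) then supplies realistic sampling
noise.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: spatial autocorrelation of connectomes,
heavy-tailed motion artifacts, trial-level probe dynamics, non-Gaussian
item distributions, and any nonlinearity in brain-behavior coupling.

## Replicate experiments and problem sizes

`neuromodes.experiments` packages the seeded validation studies: null
family-wise error (500 cohorts of n = 100 with 30 features and 200
permutations each, a size at which the permutation null is exercised
thousands of times while the whole study stays in the minutes range),
planted two-mode recovery with mode-2-specific MDES coupling (100
replicates at n = 178 on the full 4,950-feature grid), and stability
across strata (20 replicates). Replicate experiments fix the SCCA
penalties at (0.8, 0.7) — matched to the planted sparsity (supports are
dense within the retained pool; task vectors are ~half dense) — rather
than re-running the CV grid per replicate, which would multiply the cost
several-hundred-fold without changing what the experiments measure.
Fitted modes are matched to planted modes by the correlation of subject
scores with the latent ground truth, since near-equal planted strengths
make the fitted order arbitrary.

## Numerical conventions

- Bisection tolerance 1e-8; closed-form threshold clipped into its
  segment; alternation tolerance 1e-6 (relaxed to 1e-3–1e-4 inside large
  permutation studies, applied identically to observed and permuted fits
  so exchangeability is preserved).
- r-clipping 1e-7 before `atanh`.
- Master seeds derive per-stage seeds via `SeedSequence`, all below 2³¹;
  identical config + seed reproduces byte-identical outputs (manifest
  timings excluded).
- Degenerate inputs fail loudly and name the offending column/ROI/stratum;
  the only silent repairs are the documented constant-column conventions.

## Known limitations

- The penalized-matrix-decomposition surrogate assumes within-block
  covariance ≈ identity after standardization; covariance-aware sparse CCA
  is out of scope.
- Permutation and CV loops are serial; large grids at 1,000 permutations
  take minutes at the full study size.
- The Type III implementation covers continuous single-df predictors (the
  design used here); multi-df categorical hypotheses would need L-matrices
  with more rows.
- Day/condition strata are modelled as exchangeable re-measurements; no
  session-order or practice effects.
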