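# Methods

This note records the models, conventions and numerical choices behind
`bmprog`, and what the synthetic experiments do and do not demonstrate.

## Progression labeling

A lesion's record is its pre-treatment baseline (three orthogonal diameters
`d_pa, d_ml, d_si` in mm and the RANO-BM nodal diameter) plus follow-up
measurements at known months post-treatment. A *definition of progression* is
a triple (window, metric, TRSC scheme); the engine composes four steps:

1. **Window.** Keep follow-ups strictly before the bound (`<9 … <24` months).
   The bound is exclusive by convention of the grid's labels.
2. **Size metric.** Volume is the diameter product (no ellipsoid constant —
   the constant cancels in every ratio and threshold). Volume progression at
   threshold p ∈ {10, 15, 20, 25}% requires, at **any** in-window timepoint,
   `V ≥ V₀(1 + p/100)` **and** `V − V₀ ≥ 27 mm³`. Thresholds are inclusive
   (≥): the grid's occasional ">" is read as shorthand for the stated
   minimum change. The 27 mm³ floor applies to every lesion; it only binds
   for small ones. Comparison is always to the pre-treatment baseline, never
   to a nadir. The RANO-BM metric requires a ≥20% nodal-diameter increase,
   and additionally ≥3 mm absolute when the baseline is <10 mm (taken
   literally — a 9.9 mm baseline is subject to the 3 mm rule); timepoints
   whose nodal diameter was not measurable (cystic lesions) are skipped, and
   a missing *baseline* nodal diameter is an error, mirroring the exclusion
   of unmeasurable lesions from such studies.
3. **TRSC adjudication.** A size-based progression is kept or vetoed by the
   scheme: lesions annotated as pseudo-progression (PP) count as progression
   only under schemes that include PP, radiation necrosis (RN) likewise.
   Annotations are inputs (clinician adjudications), never inferred from the
   size data.
4. **Stable vs regressing.** Not defined numerically in the source
   literature; the package's convention mirrors the progression criterion on
   the **last** in-window measurement (`V ≤ V₀(1 − p/100)` with the same
   27 mm³ floor; RANO branch: last nodal diameter ≤ 70% of baseline, the
   partial-response convention). Lesions with no usable in-window follow-up
   default to stable. This choice affects only the three-way counts and the
   alternate task, not the primary progression-vs-rest labels.

The binary outcome is failure = progressing (primary task) or failure =
progressing + stable (alternate task).

## Synthetic cohort

The generator is the package's stand-in for a clinical cohort that is not
publicly available; it produces the *phenomena* the labeling engine must
discriminate, not realistic tumor biology.

- **Kernel.** Noiseless volume `V(t) = V₀ · exp(g·(t − t₀)⁺) · (1 + bump(t))`.
  Exponential growth is the simplest monotone kernel and keeps every
  threshold crossing analytically checkable. Defaults: true progressors and
  late progressors double every 6 months (`g = ln2/6 ≈ 0.116 /month`),
  regressors halve every 6 months, stable lesions `g = 0`. Late progressors
  start growing at `t₀ = 12` months so the follow-up-window axis has
  something to detect.
- **TRSC bumps.** PP: a raised-sine pulse `A·sin²(π(t−onset)/6)` with onset
  uniform in [3, 6] months, back to zero within 6 months of onset. RN: a
  saturating ramp `A·(1 − e^{−(t−onset)/6})` with onset ≥6 months that never
  resolves. Default relative amplitude A = 0.8, large enough that bumps cross
  the 25%+27 mm³ criterion for typical lesions.
- **Geometry and noise.** Each lesion draws three axis fractions with unit
  product, held fixed over time, so the diameter product tracks the kernel
  volume exactly when noise is off. Every measured diameter (including
  baseline) carries independent multiplicative log-normal noise, CV 5% — the
  scale of inter-reader diameter variability on MRI; the RANO diameter is
  the largest orthogonal diameter with its own noise term, unmeasurable with
  probability 0.02 per timepoint. Follow-up schedule: every 3 months to 24.
- **Cohort composition.** Defaults emulate the printed summaries of the kind
  of single-center SRS cohort this apparatus targets: 62 patients, 115
  lesions (per-patient counts resampled to an exact total when requested),
  ~76% lung primaries, baseline geometric-mean diameter median 6.2 mm
  (product-volume median ≈ 240 mm³, log-normal dispersion 0.4). Class
  prevalences (true 0.15, late 0.10, stable 0.30, regressor 0.30, PP 0.10,
  RN 0.05) are configurable defaults; no source reports quantitative PP/RN
  prevalence, so none of these is claimed as any study's.
- **Feature tables.** Informative columns are class-conditional unit-variance
  Gaussians with standardized mean separation d (single-feature AUC is then
  Φ(d/√2), giving closed-form targets); remaining columns are standard
  normal; optional equicorrelated blocks (shared-factor construction) supply
  the redundancy the correlation filter exists to remove. With 107 columns
  the radiomic feature names are reused so downstream tables look alike
  whether features came from images or simulation.

What passing tests on this cohort do **not** show: performance on real MRI
radiomics (real feature–outcome relationships are weaker, non-Gaussian and
heteroscedastic), robustness to reader drift, scanner effects, or informative
censoring of follow-up schedules (the simulator measures every lesion at
every scheduled visit).

## Radiomics stage

- Resampling to 0.5 mm isotropic: linear interpolation for the image,
  nearest-neighbor for masks (standard for intensity vs label volumes),
  nearest-edge extrapolation for the half-voxel grid overhang. Inputs
  already at target spacing pass through bit-identically.
- Normalization: z-score with μ, σ over brain voxels **excluding** the
  lesion, then clipping to ±3. "At three standard deviations" is ambiguous
  between clipping inputs, outputs, or trimming the statistics; clipping the
  normalized output standardizes the range without changing ranks within
  ±3 SD, and is the reading adopted here.
- Features: 107 scalars in seven classes (shape 14, first-order 18, GLCM 24,
  GLRLM 16, GLSZM 16, GLDM 14, NGTDM 5), computed in-repo with
  pyradiomics-v3-compatible names. Gray levels use a fixed bin **count** of
  64 over the ROI range ("64 intensity value bins" names a count, not a
  width), which makes all histogram-based features invariant to affine
  intensity maps. GLCM/GLRLM use the 13 unique 3D directions at distance 1,
  feature values averaged over directions; GLSZM zones and GLDM/NGTDM
  neighborhoods are 26-connected; GLDM uses α = 0 with the center voxel
  counted in its own dependence. Shape features mesh the mask by marching
  cubes after a light Gaussian anti-aliasing (σ = 0.8 voxels) — a binary
  staircase surface otherwise inflates surface area by ~8% and depresses
  sphericity of a digital sphere to ~0.92; with smoothing a sphere scores
  ~0.99 with volume error under 1%. Axis lengths come from the eigenvalues
  of the physical-coordinate covariance (`4√λ`). Degenerate single-voxel
  masks fall back to the voxel box. Texture formulas are pinned by
  hand-traced single-strip fixtures in the test suite.

## Evaluation harness

- **Bootstrap unit = patient.** All of a patient's lesions enter the training
  multiset together as many times as the patient is drawn; lesions of
  never-drawn patients form the test set. This prevents within-patient
  leakage; the expected out-of-bag fraction is `(1 − 1/P)^P → e⁻¹`, i.e.
  ~36.5% of lesions for P = 62 — matching the ~36% test fractions such
  bootstrap designs report. A lesion-level unit is a config switch. Splits
  leaving a single class in either partition are redrawn with a fresh
  counter-derived seed and logged.
- **Correlation filter.** Greedy keep-first scan in fixed feature order on
  training rows only; a feature survives iff |Pearson r| ≤ 0.8 against every
  survivor so far. Constant columns (r undefined) are dropped first.
- **Hyperparameter search.** Objective: stratified *group-aware* inner-CV
  AUC on the training rows (5 folds by default). Group-aware matters:
  bootstrap multisets repeat rows, and plain CV lets duplicates straddle
  folds, rewarding memorization — empirically this drove depth selection to
  the deep end and cost ~0.1 AUC on held-out data in the single-feature
  benchmark. Search space: trees 10–1000, depth 1–n_train, both treated as
  scale parameters (log-uniform). The initial design is deterministic: depth
  probed on a doubling ladder from 1 with the last point at full depth
  (test-error curves bend within the first few doublings), tree counts
  stratified with larger ensembles paired to shallower trees; a Matern-5/2
  Gaussian-process surrogate with expected improvement proposes the
  remaining points (25-evaluation default budget), degrading to random
  search if the surrogate cannot fit.
- **Metrics.** AUC and AU-PRC (average-precision step integration) via
  scikit-learn, cross-checked in tests against an exhaustive pairwise
  concordance oracle. Sensitivity/specificity are computed on test data at
  the threshold maximizing Youden's J on the **training** ROC (ties toward
  higher specificity; the returned threshold is the midpoint between
  adjacent training scores). Baseline AU-PRC = positive prevalence.
  Per-experiment aggregation: mean over iterations with a normal-theory 95%
  CI of the mean (±1.96·SD/√n).
- **Importance.** Default score is the forest's impurity importance
  (nonnegative, deterministic under seed; permutation importance is a
  switch). Pipeline per experiment: zero at filtered features →
  per-iteration min-max to [0, 1] → mean over iterations → renormalize to
  [0, 1]; an all-equal aggregate renormalizes to all zeros.
- **Subgroups.** Per-site metrics pool every iteration's held-out
  probabilities (with each iteration's own operating point for the
  thresholded metrics) rather than training per-site models — small
  subgroups make the latter infeasible. Single-class groups report NaN.
- **Seeding.** A master seed expands to per-(iteration, attempt) seeds via
  `SeedSequence(master, spawn_key=(iteration, attempt))`, so any iteration
  replays independently; all derived seeds are below 2³¹.

## Experiment grid

The 14 definitions comprise three categories (follow-up F, size metric S,
TRSC T) sharing the anchor (<24 months, ≥25% volume, true-progression-only);
the 12 unique cells are computed once and reported wherever they appear. Per
category the summary reports max − min of each mean metric across its
definitions. A definition yielding one class overall is reported degenerate
and skipped; others are unaffected. Outputs are long-format CSV plus a JSON
summary; the importance matrix is exported as plain CSV rather than rendered.

## Problem sizes

The analysis drivers and test suite run reduced configurations chosen as
sensible desk-scale defaults: the drivers use 25 bootstrap iterations with a
tuning budget of 8; the signal-recovery benchmark uses 2,000 lesions, 50
iterations and a 4-point tuning budget (the deterministic depth ladder makes
tiny budgets informative); the window-trend experiment uses ~150 patients
and 20 iterations. The 250-iteration, 25-evaluation configuration remains
the default of `HarnessConfig` and is what the bootstrap test-fraction
computation uses.

## Known limitations

- The stable/regressing boundary is a package convention (see above), not a
  literature rule.
- The feature extractor follows IBSI-style definitions with
  pyradiomics-compatible naming but is not bit-identical to any external
  implementation; its contracts are fixed by closed-form, hand-traced and
  invariance tests instead.
- Impurity importance is biased toward high-cardinality features; with
  z-scored continuous radiomics this is benign, but permutation importance
  is available where it matters.
- The GP tuner optimizes a noisy CV estimate; with small budgets it is
  closer to a guided grid than a converged Bayesian optimization.
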