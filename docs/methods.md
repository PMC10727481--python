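# Methods

## Scope and shape

`actipat` is a pipeline for predicting which of two recovery trajectories —
upward linear or S-shape — an older hip-fracture patient will follow, using
only the first 5–8 days of daily overall physical-activity intensity plus
clinical admission scores.  The package is organised as scikit-learn-style
estimators (`TrajectoryFeatureExtractor`, `MinMaxNormalizer`,
`SymmetricalUncertaintySelector`, `PatternClassifierCV`) so the stages compose
with sklearn pipelines and model selection; module-level functions are thin
wrappers over them.  Hill-shape/cubic/“else” trajectory classes, wear-time
detection, frequency-domain features and wrapper feature selection are out of
scope.

## Synthetic cohort generator

No patient-level data are deposited for this problem, so the generator is a
first-class module that emulates the cohort structure the analysis assumes.

* **Archetypes.** Upward linear: expected intensity `i0 + s·d` on rehab day
  `d` (1-based).  S-shape: logistic `L0 + (L1−L0)/(1+exp(−k(d−t0)))`.  Both
  are non-decreasing in expectation; intensities are in arbitrary SMA units.
* **Class structure.** Default cohort composition is 41% upward linear / 59%
  S-shape (15/22 at n = 37, by largest-remainder rounding).  Stay lengths are
  truncated-normal and class-conditional — upward linear (16, SD 10) days,
  S-shape (38, SD 12), truncated at 8 — giving a mixture mean of ~29 days.
  The class-conditional stays are deliberate: they reflect the association
  between pattern and stay duration, and they keep the S-shape inflection
  (drawn at ~50% of the stay) outside the first week, which is what makes the
  S-shape class “slow-starting” there.  A class-independent stay distribution
  remains available via `CohortSpec`.
* **Noise.** Day-level noise is multiplicative lognormal with unit mean
  (`exp(σZ − σ²/2)`, default σ = 0.2): intensities are positive and
  right-skewed, and zero noise reproduces the archetype curve exactly.
* **Clinical scores.** Truncated-normal per class, rounded to integers within
  the legal ranges (BI 0–20, FMS 0–5, FAC 0–5, MoCA 0–30).  The BI class
  means differ by 3 points (higher for upward linear); the other scores get
  small, plausible gaps.  No effect sizes are published for these
  associations; the defaults are fixed once and used everywhere.
* **Raw streams.** `generate_raw_stream` emits a 25 Hz triaxial stream whose
  per-day SMA after the preprocessing chain matches given daily targets: a
  3 Hz sinusoid on one axis with amplitude `target·(π/2)/gain`, where `gain`
  is the analytic moving-average (Dirichlet-kernel) times Butterworth gain at
  3 Hz, plus a constant +1 g gravity component on the z axis.  Round-trip
  accuracy is ~0.1%, tested at 10%.
* **What it does not emulate.** Sensor artefacts (clipping, drift), non-wear,
  within-day activity structure, and the visual-rating process that produced
  the real labels.  Passing tests show the pipeline recovers structure the
  generator put in; they do not certify performance on real cohorts.

## Preprocessing

Per calendar day, restricted to 07:00–22:00: a centred 0.12 s moving average
(3 samples at 25 Hz, rounded to the nearest odd count; shrinking windows at
the edges), then a 4th-order Butterworth high-pass at 1 Hz.  The high-pass is
run forward-only (causal) per day segment, with the filter state initialised
to the steady state of the first sample: a constant (gravity-only) input maps
to an output that is numerically zero, start-up transients are suppressed,
and missing days cannot contaminate neighbours.  The SMA is normalised by the
epoch duration — `(1/T) Σ_axes Σ_t |a|Δt`, i.e. the time-mean of
`|ax|+|ay|+|az|` in g — so days with different in-window durations stay
comparable; the un-normalised “area under the curve” differs only by the
constant factor `T`.  A day with no in-window samples is flagged missing, not
zeroed.  Gaussian-weighted smoothing (window 5 days, σ = (window−1)/4,
edge-renormalised) is provided for visual pattern assessment only; features
are computed on unsmoothed series by default.

## Features

Day index for the slope and cubic fits is `x = 1..W`.  SD uses the sample
(n−1) denominator; IQR uses linear-interpolation quantiles.  The cubic’s
`d` coefficient is computed but not emitted (only a, b, c are features).
Min–max normalisation is fitted on the training rows only by default
(`normalize_scope="train"`), preventing test-set leakage; `"all"` reproduces
whole-cohort normalisation.  Constant features on the fit rows are dropped
with a warning.  The full vector is 15 trajectory features + 4 clinical
scores.

## Feature selection

SU is computed from empirical base-2 entropies (the SU value itself is
base-invariant).  Continuous features are discretised into equal-frequency
bins, default 3 — with ~30 training rows, finer bins degrade the entropy
estimates; integer-valued columns (the ordinal clinical scores) are treated
as already discrete.  Both rule clauses use strict `>`, and the pairwise
clause is evaluated against *all* other features (a sequential FCBF-style
mode is available as `mode="fcbf"`).  The classic merit-function CFS is
intentionally not used; the implemented rule is threshold + pairwise
dominance.

A consequence worth stating plainly: with equal-frequency binning, the SU of
a continuous feature with a binary class is bounded by
`2·H(class)/(H(bins)+H(class))` (≈0.77 at 3 bins), so the 0.9 threshold can
never be met and the selection is empty — the pipeline then falls back to all
features, with a warning and a `fallback` flag in the selection result.  The
SU *ranking* is still informative and is what the selection report should be
read for.  Likewise, two identical copies of a perfect feature reject each
other under the all-pairs rule (SU(f,g)=1 is never exceeded); this redundancy
semantics is tested, not hidden.

The quadratic cubic coefficient (`coef_b`) is only class-informative when the
S-shape bend actually lies inside the observation window; on the default
cohort (inflection mid-stay) it is noise-dominated, and the tests assert the
comparative property — its SU rises substantially on cohorts that bend within
the window — rather than a universal top rank.

## Model

Stratified 80:20 split with per-class test counts `round(0.2·n_c)` adjusted
by largest remainder (15/22 → 3+4 test patients), seeded.  The classifier
suite uses fixed presets (no nested hyperparameter search): fine/medium
trees, linear discriminant (lsqr + shrinkage, which stays well-defined when a
CV fold has fewer samples per class than features), quadratic discriminant
(regularised; a family whose fit fails on a given fold scores NaN and cannot
win), logistic regression, linear/RBF SVMs, k-NN with k ∈ {1,5,10} ×
{euclidean, cosine} (k clamped to the fold size on tiny cohorts, with a
warning), and bagged/AdaBoost trees.  Winner = highest stratified 5-fold CV
accuracy, ties broken by the listing order (trees → discriminant → logistic →
SVM → k-NN → ensembles).  Cosine distance treats a zero vector as distance 1
from everything.  Default k for cosine k-NN is 5 and configurable.

## Evaluation

Per-class precision/recall/F1 and micro-F1 follow the standard definitions;
micro-F1 equals accuracy for single-label problems, which the tests verify by
exhaustive enumeration of small confusion matrices.  Degenerate conventions:
TP = 0 with errors present scores 0; a class absent from both truth and
predictions is undefined and reported as NaN with a warning.
`reconstruct_confusion` enumerates integer TP per class (in the two-class
case each class's FP equals the other's FN) and keeps matrices whose
half-up-rounded percentages match the printed integers; for the reference
per-window percentages the solution is unique in all four windows.  The
reference micro-F1 values are recomputed with the standard micro-F1
denominator (2ΣTP + ΣFP + ΣFN); they match the published overall scores
exactly, which is also the internal consistency check on the printed formula
variant that mentions true negatives in that position.

## Reproducibility and problem sizes

One master seed expands into per-stage seeds (cohort, split, model) via
`numpy.random.SeedSequence`; a fixed seed makes cohorts bit-identical and
pipeline report JSONs byte-identical.  The packaged default evaluation cohort
is n = 200 with the default (well-separated) archetype parameters — large
enough for stable held-out estimates while the whole end-to-end run stays in
the low seconds.  The SU oracle check is exhaustive over 2×2 joint tables
(total ≤ 40) and 3×3 tables (total ≤ 12) with a seeded random sample of
larger 3×3 tables.

## Known limitations

* The generator's archetype separation is a modelling choice; real cohorts
  will be harder, and the reported synthetic accuracies are upper bounds in
  that sense.
* The SU threshold rule is implemented literally; on continuous features it
  acts as a ranking with fallback (see above), not a filter.
* The suite's presets approximate, but cannot reproduce, the exact presets of
  the original point-and-click training environment.
* `reconstruct_confusion` supports two classes (the use case here).
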