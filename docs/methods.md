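# Methods

`suturemetrics` quantifies the spatial quality of a running suture from
annotated still images and relates it to the mechanical resistance of the
closure.  This note documents the models and procedures the package
implements, the parameters that matter, and the choices made where the
design was genuinely open.

## Measurement model

A trial is one sutured specimen photographed with a checkerboard of known
square size in frame.  The annotation supplies pixel coordinates for needle
entry and exit points (proximal to distal), a polyline tracing the incision,
and the checkerboard's interior corners.

**Scale calibration.**  The pixel-to-millimetre scale is a single isotropic
scalar: `mm_per_px = square_mm / median(nearest-neighbour corner distance)`.
On a square lattice every interior corner's nearest neighbour is an adjacent
corner one square away, so the median of these distances is a robust
estimate of the lattice pitch; it is exactly invariant to rigid motion of
the image and robust to annotation jitter on individual corners.  The RMS
deviation of the adjacency distances from the fitted pitch is reported as
`residual_rms_px`, which surfaces anisotropy or perspective distortion
without attempting to correct it — the capture protocol (fixed camera
distance, top-down view) makes a homography unnecessary, and a single
scalar keeps all distance measurements convention-free.  Calibration
accepts any non-degenerate corner set with at least two corners; it never
assumes a corner count, since "a 3 × 3 checkerboard" can denote either 3 × 3
squares (4 interior corners) or 3 × 3 interior corners.

**Distance extraction.**  Two distance families are measured per trial:

* *PM (point-to-margin)*: the minimum Euclidean distance from each entry and
  exit point to the incision polyline (perpendicular foot inside a segment,
  nearest vertex otherwise).  The supplied polyline defines the reference —
  cut edge or fitted midline is the annotator's choice, and a perpendicular
  distance rather than a horizontal pixel difference keeps the quantity
  invariant to image rotation.
* *PP (point-to-point)*: Euclidean distances between consecutive entry
  points, then between consecutive exit points, concatenated.  Pairing is
  within each side; with S stitches per side a compliant trial yields
  2S PM values and 2(S−1) PP values.

Uncalibrated (pixel-unit) operation is supported; error metrics against the
5 mm target then require an explicit px-per-mm override so the target can be
expressed in pixels.

## The 18 spacing metrics

For each family (PM, PP, and the pooled "P all") six statistics are
computed: max, mean and population-SD of the absolute distances, and the
same three applied to the absolute deviations from the instructed target
g (default 5 mm, the small-bites prescription).  Conventions:

* SDs use divisor n (population form), matching the printed definitions;
  a flag switches to n − 1.
* The pooled mean is the value-weighted mean over all 2n pooled distances,
  while the pooled *mean error* is the unweighted average of the two family
  mean errors — both as printed, even when the family lengths differ.
* The printed pooled-SD formula lacks a square root (a variance-like
  quantity) while its error counterpart has one; the default applies the
  root for unit consistency, and `p_all_std_as_printed=True` reproduces the
  rootless form.  Every downstream use is rank-based, hence invariant to
  this monotone choice.
* Absolute values are applied before every operation (harmless for true
  distances, which are nonnegative).

Entry-side and exit-side values are pooled within each family; the metric
definitions index one list per family and nothing in the protocol
distinguishes the sides.

## Cohort statistics

Outcomes (burst pressure in mmHg, task time in s) are compared across the
three platforms and three experience strata:

* **Outlier screening**: Tukey fences at Q1 − k·IQR and Q3 + k·IQR with
  k = 1.5, quartiles by linear interpolation, applied once per comparison to
  the outcome variable only (no re-fencing); removed trial ids are always
  reported.
* **Global tests**: Kruskal–Wallis with tie correction is the default
  (several outcome distributions are non-normal); one-way ANOVA is offered
  behind an explicit caller choice with no automatic distribution-based
  switching, since any such rule would be arbitrary.
* **Post hoc**: Dunn's pairwise z tests on the pooled ranks with tie
  correction; unadjusted by default (the upstream analysis names no
  correction), with Bonferroni and Holm available and the choice recorded in
  the output.
* **Retrospective power**: Monte-Carlo simulation under Gaussian group
  models at the observed means/SDs.  The required per-group n is the
  smallest balanced n whose simulated rejection rate reaches the target
  power (default 0.80 at α = 0.05), found by a doubling sweep plus linear
  refinement; t-test and ANOVA paths are vectorised, the Kruskal–Wallis path
  calls the test per simulated dataset.  Against the closed-form two-sample
  answer (n = 2(z_{0.975}+z_{0.8})²/d², ≈17 per group at d = 1 with the
  conventional small-sample correction) the simulated answer agrees within
  ±2 at 4000 simulations per candidate n.

## Strength model

The link between spacing precision and burst pressure is analysed in two
steps, mirroring a screen-then-model design:

1. **Spearman screen** over the 18 metrics (plus task time) against burst
   pressure; metrics with two-sided p < α = 0.05 are selected, deliberately
   without multiplicity correction (the screen is reported as run; Holm and
   Benjamini–Hochberg are available by flag).  Each metric carries a
   retrospective power analysis via the Fisher-z approximation at the
   observed rho.  For Spearman's rho the standard error is inflated to
   √((1 + ρ²/2)/(n − 3)) (Bonett–Wright); the plain √(1/(n−3)) variant is
   reported alongside, as either convention is found in practice.  Constant
   metric columns have undefined rank correlation and are flagged and
   excluded, never reported as zero.
2. **Gradient-boosted regression** of burst pressure on the selected
   features under repeated K-fold cross-validation (k = 5 splits, 10
   repeats: each repeat trains on 80 % and validates on 20 %, 50 validation
   folds in total).  Hyperparameters are not prescribed upstream; the
   defaults are the common library settings (100 trees, learning rate 0.1,
   max depth 3, subsample 1.0), echoed verbatim in every report.  Per-fold
   MSE, R² and MAE are reported with their mean; per-fold R² on 9-sample
   validation folds is a harsh, high-variance criterion (negative whenever
   the model underperforms the fold mean), so the pooled-prediction R² is
   reported alongside.  A fold with zero target variance reports R² as
   not-applicable rather than a number.

Collinearity is diagnosed with variance inflation factors
(VIF_j = 1/(1 − R²_j), intercept included; exact collinearity reported as
infinite).  Residual analysis flags shrinkage-to-the-mean when the lowest
actual value is overpredicted and the highest underpredicted.  SHAP
attributions are exact TreeSHAP values computed natively by the gradient
boosting library; local accuracy (base value + attributions = prediction)
holds to numerical precision and is asserted in the tests.  SHAP is
computed on a full-data refit by default (labelled in the report); a
per-fold mode is a trivial variation the user can run on any fold's model.

Seeds: one master seed deterministically derives the shuffle, model and
power-simulation seeds via SHA-256 of `"<master>:<label>"`, all echoed in
the reports, making every pipeline artifact byte-reproducible.

## Synthetic cohort generator

No trial data are distributed, so the package ships a generator that
emulates the study design: 15 operators (5 beginners, 5 advanced,
5 masters) × 3 platforms (laparoscopy, dVRK, flexible endoscope) = 45
trials, platform order counterbalanced across three rotation groups,
7-stitch running sutures targeting 5 mm spacing and margins.

* **Geometry**: stitch x-advances ~ Normal(5, σ_pp) truncated positive;
  margin offsets ~ Normal(5 + bias, σ_pm) truncated positive on each side of
  a straight incision drawn long enough to span the suture run.  The ground
  truth PP distance is the realized Euclidean gap between consecutive points
  (advance plus margin-offset component) — exactly what landmark extraction
  recovers.  Defaults σ_pp = 2.10 mm, σ_pm = 2.25 mm put the mean absolute
  deviations from the 5 mm target in the 1.4–2.2 mm range reported for this
  task family.  Dispersion is homogeneous across strata by default so that
  the explicit coupling below is the *only* pathway from spacing to
  pressure; per-device and per-experience multipliers are available when a
  platform-dependent precision structure is wanted.
* **Burst pressure**: max(0, μ₀ + device offset + experience offset −
  γ·(true PP-SD − 1.90) + Normal(0, 7)) mmHg, with offsets anchored at the
  reported stratum means (platforms 17.38/15.99/13.60, experience
  15.13/13.89/17.95).  Centering the coupling term at the expected PP-SD
  (1.90 mm) keeps stratum means at their anchors for any γ.  The default
  γ = 7.8 mmHg/mm was calibrated by simulation so that the pooled sample
  Spearman correlation between measured PP-SD and pressure at n = 45
  averages −0.375, the reported effect size; with γ = 0 the generator is an
  exact null for the metric screen, and the type-I selection rate of each
  spacing metric is ~5 % at α = 0.05.  The driver is the *true* PP-SD, so
  calibration jitter attenuates the observable correlation realistically.
* **Task time**: lognormal per platform at the reported means/SDs
  (1341/1595/3141 s), with a mild multiplicative experience factor making
  masters faster.
* **Questionnaires**: SUS item contributions are shifted binomials with
  per-platform success probability (0.72/0.70/0.45 — the flexible endoscope
  scores "low" usability while the others score "good"); TLX ratings are
  shifted binomials with elevated mental-demand and frustration
  probabilities for the flexible endoscope.  Magnitudes are free config;
  only the qualitative ordering is asserted.
* **Rendering**: landmarks are scaled (default 10 px/mm), rigidly rotated
  (±10°) and translated per trial; a 2 × 2 interior-corner checkerboard
  (3 × 3 squares of 5 mm) is added with 0.2 px Gaussian corner jitter.
  Jitter-free rendering round-trips distances to 10⁻⁶ mm.

What the generator does **not** emulate: real annotation error on landmarks
(only checkerboard jitter is modelled), curved or irregular incisions,
tissue heterogeneity, the "weakest-link" failure mechanics of burst testing,
operator learning across the session, or any image content.  Passing tests
therefore demonstrate that the *analysis chain* is correct and calibrated
under its own assumptions — not that those assumptions hold for real tissue.

## Problem sizes and numerical choices

Monte-Carlo characterisations in the test suite use 1000 null cohorts
(type-I calibration), 500 cohorts at the default coupling (effect-size
recovery), and 4000 simulations per candidate n in power checks; the
acceptance script uses 400-cohort batches.  These sizes put the Monte-Carlo
standard error well inside the asserted bands while keeping a full run in
the low minutes on one core.  Ties in ranks are handled by midranks with
the standard tie corrections everywhere; Kruskal–Wallis on all-identical
data returns H = 0, p = 1 by definition.  Degenerate inputs (collinear
checkerboards, constant metric columns, zero-variance folds, empty strata)
are reported as such rather than coerced to numbers.

## Known limitations

* The isotropic scale model ignores perspective; images taken off-axis
  inflate `residual_rms_px` but are not corrected.
* Required-n simulation assumes Gaussian, balanced groups.
* The Fisher-z power formulas are asymptotic; at n < 10 they are rough.
* Reported stratum means/SDs for pressure and time anchor the generator,
  but per-stitch distance distributions are unpublished; the dispersion
  defaults reproduce aggregate error magnitudes only, and the printed
  pixel-vs-millimetre unit ambiguity in those aggregates is resolved by
  working in millimetres throughout (both unit modes remain supported in
  the pipeline).
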