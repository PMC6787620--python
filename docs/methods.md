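# Methods

This note documents the models, the numerical choices, and the open design
decisions behind `dermafluor`, in the spirit of a statistical package's
methods appendix.  Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Data model

A *lesion scan* couples three things: a rectangular grid of fluorescence
spectra (one per 200 µm step inside an operator-chosen rectangle), an
8-bit grayscale photograph of the lesion, and three independent binary
pathologist diagnoses whose majority (≥ 2 of 3) is the ground truth.
Image coordinates are top-left origin, 0-based; the scan rectangle is
half-open `[x0, x1) × [y0, y1)` in photo pixels.  Grid position
`(row, col)` maps to pixel `(y0 + row·s, x0 + col·s)` with
`s = step_um / um_per_pixel`, rounded to the nearest pixel — the device's
actual mapping is not public, so the simplest deterministic convention is
used.  Scan bundles are stored as human-inspectable text: a wide CSV of
counts (header row carries the raw wavelengths in nm), a PNG photograph,
and a small YAML metadata document; the round trip is lossless.

## Synthetic scan generator

The generator produces the *structure* the analysis assumes, not a
radiative-transfer simulation:

* **Spectral shapes.**  Each spectrum is a sum of Gaussians on an extended
  raw grid (canonical 0.3979 nm spacing continued to ~720 nm): a melanin
  fluorescence band (amplitude 120 counts, σ = 40 nm) peaked at 590 nm
  (benign type) or 640 nm (malignant type); a narrow second-harmonic line
  at 400 nm (amplitude 200, σ = 5 nm) present in every spectrum; a small
  spurious band at 700 nm (amplitude 40) so the >680 nm truncation has
  something to remove.  Skin-type spectra replace the fluorescence
  amplitude by 3 counts — below the 10-count retention filter in
  expectation.  Only the peak positions are documented device physics; the
  Gaussian shape is the minimal controllable-peak model, with the width
  chosen so the two classes overlap and the classifier is not trivially
  perfect.
* **Counting noise.**  Observed counts are per-wavelength Poisson draws
  around the expected spectrum, matching photon-counting detection.  A
  consequence worth knowing: a skin-type spectrum has a noticeable chance
  that *some* of the ~300 window wavelengths fluctuates to ≥ 10 counts, so
  a minority of off-lesion spectra survive the filter; they carry almost
  no signal and their classification follows the sign of the decision
  function near the origin.
* **Mixture probabilities.**  A grid position inside the lesion emits a
  malignant-type spectrum with probability 0.63 for melanomas and 0.29 for
  nevi (else benign-type); positions outside emit skin-type.  These
  defaults are calibrated so the expected raw scores, 0.63·60 ≈ 38 and
  0.29·60 ≈ 17, bracket the score distributions a well-behaved scoring
  system should produce; they are generator settings, not measured tissue
  properties.
* **Geometry.**  The photograph is a centered dark ellipse
  (pigment level 60) on brighter skin (level 200) with additive Gaussian
  noise (sd 8), defaults 96×96 px at 50 µm/pixel with semi-axes
  (16, 10) px — giving ~30 retained spectra per lesion, small enough that
  full cohorts train in seconds on one CPU while leaving binomial score
  variance realistic.  The operator rectangle follows one of four
  scenarios: (a) congruent with the lesion bounding box, (b) dilated by
  50 % of each dimension per side, (c) the left half of the box, (d) the
  left half-box shifted left by half of its own width so a substantial
  part of the scan lies on skin.  Scenario (d)'s exact geometry is a
  package convention; only its qualitative description (partial coverage
  plus skin dilution) is fixed by the application.
* **Labels.**  All three pathologist labels equal the generating diagnosis
  by default; an independent per-pathologist flip rate (default 0) can
  inject disagreement.  No per-pathologist error model is implied.

What the generator does **not** emulate: hair/ruler artifacts, amelanotic
or heavily regressed lesions (outside the method's domain), within-class
spectral variability beyond Poisson noise, spatial correlation of pixel
types, and any absolute fluorescence-vs-SHG intensity calibration (the
amplitudes are free parameters).  Passing tests therefore demonstrate the
*pipeline's* correctness and calibration under these conditions, not
clinical performance.

## Preprocessing

"Low signal intensity" is read as the **maximum** count over the inclusive
480–600 nm window: counts are integer photon counts, so a 10-count bound
most naturally caps the peak.  The predicate is isolated in one function
so a mean- or integral-based reading is a one-line change.  Exactly
10 counts is retained ("below 10" is excluded).  Resampling onto the
canonical grid uses linear interpolation and is a pure cut when the raw
grid already contains the canonical points (the generator's case).  No
smoothing, baseline subtraction or normalization is applied anywhere.

## SVM

The classifier is a standard soft-margin SVM on the 750 raw-count
predictors with the inhomogeneous polynomial kernel
`(1 + ⟨x,z⟩/σ²)^d`, d = 3, C = 0.165.  Two solver-level choices matter:

* **Dual solver.**  The dual is solved by coordinate ascent on the
  maximal-violating pair: two variables per update, the smallest working
  set that can respect the equality constraint Σαᵢyᵢ = 0 (single-variable
  updates cannot).  The gradient is maintained incrementally; the stop
  rule is the maximal KKT violation m(α) − M(α) ≤ tol (default 10⁻³), with
  at most 10⁶ updates; non-convergence raises an error carrying the
  remaining gap.  The bias is the mean of the KKT-implied values over free
  support vectors, else the midpoint of the violation interval.
  Correctness is defined by oracle equivalence — on small instances the
  dual objective, decision values and KKT residuals are checked against a
  direct QP solve (SciPy SLSQP) in the test suite — never by matching
  another library's internals.
* **Kernel scale.**  σ defaults to 1 at the function level, but raw count
  vectors have inner products of order 10⁶; the experiment pipeline uses
  σ = 1000 so the scaled inner products are O(1) and the cubic kernel is
  numerically tame.  No value is documented for the original device; σ is
  an explicit configuration field.  No feature standardization is applied
  (also configurable by pre-scaling inputs, which is exactly equivalent to
  changing σ — an equivalence the tests verify).

**Class-balanced box constraints.**  Every spectrum inherits its lesion's
diagnosis as training label.  Under the mixture model above this mislabels
37 % of melanoma spectra and 29 % of nevus spectra *by construction*, and
the cohort is imbalanced (≈ 7 melanoma vs 42 nevus training lesions).  The
empirical-prior optimum of either 0-1 or hinge loss is then the constant
"benign" classifier: most malignant-type spectra occur in nevi, every
lesion scores 0, and the score system degenerates.  The pipeline therefore
trains with per-class bounds `C_k = C · n/(2 n_k)` (the usual "balanced"
weighting), which makes the per-spectrum optimum the spectrum-*kind*
detector that a linear malignancy score presupposes.  Uniform bounds
remain the `train_svm` default for the plain textbook behavior; the
balanced variant relaxes the per-point bound from C to C·n/(2n_k).

**Cross-validation.**  k-fold (default 20) folds partition *lesions*:
spectra within a lesion share a label source and are spatially correlated,
so spectrum-level folds would leak the validation lesions into training.
Fold sizes differ by at most one lesion; the per-fold statistic is the
held-out per-spectrum error rate.

## Li thresholding and ROI factors

The lesion is dark (melanin absorbs), so the mask is `intensity <
threshold`, followed by one deterministic cleanup: keep the largest
4-connected component.  The threshold minimizes the Li–Tam minimum
cross-entropy criterion

    η(t) = −Σ_{g<t} g·h(g)·ln μ_below(t) − Σ_{g≥t} g·h(g)·ln μ_above(t)

via the fixed-point iteration t ← (μ_below − μ_above)/(ln μ_below −
ln μ_above) (the logarithmic mean of the class means), initialized at the
image mean, converged when the move is under 0.5 gray level.  Gray level 0
is offset to 0.5 before the log-means — a standard guard with
sub-quantization impact.  Numerical facts the tests encode:

* On the default synthetic photographs the two intensity populations
  leave an empty histogram gap and η is exactly flat across it: every
  threshold in the gap is a co-minimizer and induces the same partition.
  Equivalence with the exhaustive search is therefore asserted on
  criterion values and partitions (canonicalized thresholds), not on raw
  threshold coordinates.
* On dense overlapping histograms the fixed point is the stationary point
  of the *continuous* relaxation and can sit one or two gray levels from
  the discrete argmin, with a criterion excess below 10⁻⁴ relative; the
  in-module exhaustive search (`li_threshold_bruteforce`) is the oracle
  for both regimes.

A constant image has no threshold; segmentation then reports
`contrast_ok=False` with an empty mask and downstream scoring falls back
to the uncorrected score with a logged warning.

From mask M and scan rectangle R, two normalization factors are derived:

* `f_cov = |M ∩ R| / |M|` — the scanned fraction of the lesion;
* `f_pig = min(1, (|M ∩ R|/|R|) / (|M|/|bbox(M)|))` — the scan area's
  on-lesion density, normalized by the lesion's fill of its own bounding
  box.

The normalization in `f_pig` is a deliberate design choice: the
recommended operator procedure — a rectangle congruent with the lesion's
bounding box — must be an exact no-op, yet a non-rectangular lesion can
never fill a rectangle (an ellipse fills π/4 of its box).  Dividing by the
bounding-box fill makes scenario (a) return exactly (1, 1), leaves
`f_pig = 1` for any rectangle lying fully on pigment (scenario (c)), and
still penalizes rectangles diluted by surrounding skin (scenarios (b),
(d)).  For a lesion that fills its box the factor reduces to the plain
on-lesion fraction.

## Scoring

The device's score is linear in the number of malignant spectra, spans
0–60, and uses the cut-off 28; its exact coefficients are not public.
The reconstruction used here,

    raw_score = round(60 · n_malignant / n_retained)       (half away from zero)

is the unique linear-in-count form (at fixed denominator) that attains
both printed extremes, and puts the cut-off at a ≈ 46.7 % malignant
fraction.  Rounding half away from zero makes boundary arithmetic exact
(27.5 → 28, still benign under the strict `score > 28` rule).  A decision
value of exactly 0 classifies a spectrum as benign: a zero margin carries
no evidence of malignancy and must not inflate the score.

The ROI correction is likewise a reconstruction constrained by its
documented behavior: it divides the raw score by both factors, each
floored at 0.2 to prevent blow-up on sliver overlaps, clamped to [0, 60]:

    corrected = clamp(round(raw / (max(f_pig, 0.2) · max(f_cov, 0.2))), 0, 60)

It is a no-op at factors (1, 1) and can otherwise only raise the score —
raising sensitivity and lowering specificity, the reported direction of
the correction.  Because sub-threshold skin spectra are already removed
from the score's denominator, the correction deliberately over-compensates
dilution scenarios; this double-counting is inherent to correcting a
filtered score by geometric areas and is visible in the scenario (b)/(d)
tests.

## Evaluation

Melanoma is the positive class.  Reported quantities: sensitivity,
specificity, accuracy (all exact rationals, rounded for display at 1, 1
and 2 decimals respectively), diagnostic odds ratio (TP·TN)/(FN·FP)
(flagged infinite when FN·FP = 0), number needed to excise defined as
*excised lesions per pathology-confirmed melanoma* (total/(TP+FN)), and
excision reduction 100·TN/(TN+FP) — the share of benign excisions a
score-guided policy avoids.  The ROC sweeps every integer cut-off from −1
to 60 with the same strict `score > c` rule as the classifier and
integrates by trapezoid over the (FPR, TPR) staircase; this equals the
Mann–Whitney pairwise concordance, which the tests verify independently.

`run_experiment` chains the stages — simulate, stratified 49/165 split,
preprocess, train (optional lesion-wise CV), score each test lesion with
and without ROI correction, evaluate both variants — deriving all
sub-seeds from one master seed, so a rerun is bit-identical.  The default
cohort is 31 melanoma + 183 nevus lesions: with a proportional 49-lesion
training allocation this leaves ≈ 24 melanomas among the 165 test
lesions, matching the validation-cohort composition the metrics refer to.

## Known limitations

* The score and ROI-correction formulas are reconstructions (see above);
  alternative linear maps consistent with the same published anchors
  exist.
* The per-spectrum classifier's behavior on near-empty spectra (the few
  skin spectra that pass the filter) is governed by the decision function
  near the origin and is not separately calibrated.
* Synthetic cohorts have no within-class spectral heterogeneity, so
  per-spectrum separability — and hence end-to-end performance — is
  optimistic relative to clinical data; the synthetic results validate
  the machinery and its calibration, not the device.
* The dual solver stores the full kernel matrix (fine up to a few
  thousand spectra); very large training sets would need row caching.
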