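# Methods

This note documents the measurement conventions, the statistical model, the
synthetic-data generator and the numerical choices behind `ivmetrics`, in
enough detail to reimplement or audit each step.

## Coordinate conventions and geometry

Landmark files use image coordinates (x rightward, y downward, arbitrary
units — typically pixels of unknown magnification).  The `facing` flag
records which screen direction is anatomically anterior; internally every
computation happens in an anatomical frame (anterior +X, cranial +Y), so a
patient imaged facing left and the mirror of that exam imaged facing right
yield identical metrics.

* **Endplates** are directed lines from the posterior to the anterior
  corner of one vertebral side.  The %EPW normalizer of a motion segment is
  always the *superior endplate width of the inferior vertebra*.
* **Disc angle** = orientation of the superior vertebra's inferior endplate
  minus orientation of the inferior vertebra's superior endplate, wrapped to
  (−180°, 180°].  Anterior disc opening (extension) is positive.
* **Rotation** = extension disc angle − flexion disc angle.  With this sign
  a normally moving segment has positive rotation; swapping the phases
  negates it.  Reporting the extension-minus-flexion difference (rather
  than its magnitude) preserves sign information for hypomobile or
  paradoxically moving segments.
* **Translation**: the inferior vertebra's four corners are registered from
  extension onto flexion by a least-squares similarity transform (Umeyama
  closed form; uniform scale is included because the two films may differ
  in magnification).  The transform is applied to the extension pose of the
  superior vertebra; the displacement of its posterior-inferior corner is
  projected onto the flexion inferior superior-endplate direction and
  divided by that endplate's width.  Anterior displacement from extension
  to flexion is positive.  Registration refuses collinear landmark sets
  (singular-value ratio < 1e-9).
* **Disc heights** are corner-to-corner Euclidean distances (anterior pair,
  posterior pair).  A perpendicular-to-endplate construction would also be
  defensible; corner-to-corner is landmark-native, reproducible, and makes
  the posing problem (below) exactly invertible, so it is used throughout.
* **Segment angle** (impairment-guide convention) uses the *inferior*
  endplates of both vertebrae; its adjacent-level differences are computed
  from the flexion radiograph only.
* **Total C2–C7 rotation** is the relative rigid-body rotation of C2 versus
  C7 between phases (Procrustes rotation angle per vertebra).  For rigid
  bodies this equals the sum of the five segmental rotations, and it
  remains defined when intermediate levels are obscured.  It is reported
  only when C2 and C7 are analyzable in both phases.
* **Millimetric translation** multiplies %EPW translation by a per-level
  average endplate width (14.9, 14.9, 14.9, 15.8, 16.7 mm for C2–C3 …
  C6–C7), the population ratio of millimetric to %EPW translation at each
  level; the table is user-overridable.

Missing data are handled per level: a segment is computed iff both of its
vertebrae are present in both phases; adjacent-level differences use only
available neighbors and are absent (never zero) when no neighbor exists.

## Normative model and indices

Reference cohorts are filtered to segments with rotation ≥ 5° (a segment
moving less does not stress its restraints; the boundary value is kept
because the exclusion drops strictly smaller rotations) and, where
degeneration grades are provided, Kellgren–Lawrence grade < 2 ("definite"
degeneration excluded; the cutoff is configurable).

Per-level statistics use the sample SD (n−1) and report mean + 1.96 SD as
the upper 95% reference limit.  Translation-on-rotation (RDT) is fitted
per level — the slopes genuinely differ across levels — while the
anterior and posterior disc-opening-on-rotation regressions (RDDW) are
pooled across levels, where the slopes are practically common.  The disc
openings are defined so both grow with rotation: ΔADH = ADH_ext − ADH_flex,
ΔPDH = PDH_flex − PDH_ext.

Every regression stores (slope, intercept, n, x̄, Sxx, residual SD s, R²),
which closes the standard error of the forecast:

    SEF(x0) = s · sqrt(1 + 1/n + (x0 − x̄)² / Sxx)

SEF is minimal (s·sqrt(1+1/n)) at the cohort's mean rotation and widens
away from it, so an index of ±2 always corresponds to the ≈95% prediction
band *at the observed rotation*.  The quadratic-in-x0 expression under the
root is exact for simple OLS; no numerically fitted variability bound is
involved.  Indices are (observed − predicted)/SEF; a degenerate reference
with SEF = 0 is refused rather than propagated.

Decision thresholds (all strict, boundary values normal): |index| > 2,
rotation difference > 11°, flexion segment-angle difference > 11°,
|translation| > 20 %EPW, SDH < −2, minimum rotation 5°, effort filter 60°
total C2–C7 rotation.  Translation uses the absolute value so
retrolisthesis counts.  The legacy > 3.5 mm criterion is implemented but
disabled by default: it presumes ≈30% radiographic magnification, which
magnification-free measurements do not have; enabling it requires an
explicit flag.  Prevalence denominators count *segments*; each criterion's
denominator drops segments whose inputs for that criterion are missing.

## ROC and threshold selection

Candidate cutoffs are the midpoints between consecutive distinct metric
values plus ∓∞ sentinels; a case is called positive when its value strictly
exceeds the cutoff (strictly below, for low-abnormal metrics).  This grid
realizes every achievable confusion table, the trapezoidal AUC equals the
pairwise concordance probability with ties counted ½, and the operating
point maximizes Youden's J = sensitivity + specificity − 1.  Ties in J are
broken toward the smallest threshold — the most sensitive rule, matching a
screening intent.  Sectioning reports either pool all sectioned stages
against intact (default) or contrast each stage separately.

## Synthetic-data generator

The generator emulates the statistical structure the method assumes, not
images or tissue mechanics.

* **Rotations**: per-level normals with means (8.7, 14.1, 17.9, 19.1,
  16.5)° and SDs (2.8, 3.4, 3.2, 4.5, 4.7)° for C2–C3 … C6–C7 — the
  normative full-effort values for radiographically normal segments.  The
  `effort` multiplier scales the means only, emulating under-stressed
  exams (e.g. 0.6 reproduces the ≈46° vs ≈74° total-rotation contrast seen
  between symptomatic and asymptomatic populations).
* **RDT**: translation = M·rotation + B + ε per level, with (M, B, sd ε)
  *derived* from the normative translation moments and per-level R²
  (M = sd_t√R²/sd_r, B = mean_t − M·mean_r, sd ε = sd_t√(1−R²)), so a refit
  on generated data reproduces the published marginal means/SDs and R²
  simultaneously.
* **RDDW**: pooled lines with anterior slope 1.0 and posterior slope 0.75
  %EPW/deg, intercept 0.  The slope pair is chosen so the implied
  disc-wedge change per degree of rotation is geometrically
  self-consistent ((Mₐ+Mₚ)/100 ≈ tan 1° per degree), which keeps the
  posed corner geometry compatible with the prescribed rotations; the
  noise SDs (1.35, 1.25 %EPW) put the per-level and pooled R² in the
  0.8–0.95 band of the normative fits.  Disc-height baselines (anterior
  15 ± 1.5, posterior 12 ± 1.5 %EPW, split half-and-half around the
  opening) keep all four per-phase heights in a plausible 2–25 %EPW range.
* **Posing**: vertebrae are convex quadrilaterals (superior width per
  level, 0.88 taper, 0.55 height ratio, small posterior offset and a 1–3°
  body wedge); only corner positions matter to the metrics.  Prescribing
  rotation, translation and all four per-phase corner disc heights is an
  exactly determined six-constraint problem per segment: given the disc
  angle of a phase, the two corner distances pin the posterior-inferior
  corner to a two-circle intersection (two branches); the one remaining
  degree of freedom — the flexion/extension split of the disc angle — is
  solved by bracketed root finding (Brent, xtol 1e-13) so the registered
  translation hits its target, trying the four branch pairs in a fixed
  order.  The achieved angle split is recorded back into the ground truth.
  Prescriptions violating the circle inequalities raise a `PoseError`;
  the landmark-cohort generator rejection-resamples such draws (bounded
  retries), so landmark cohorts follow the metric model *conditioned on
  geometric feasibility* — metric-level cohorts, used for all reference
  fitting and calibration, are drawn from the exact configured model.
  Each radiograph finally receives a random global similarity transform
  (scale 0.85–1.25, rotation ±12°, offset), which all %EPW/angle metrics
  must ignore; the pipeline recovers posed ground truth to better than
  1e-6 (typically 1e-12).
* **Sectioning experiments**: 12 specimens per arm, intact plus three
  anterior-to-posterior stages at C4–C5.  Specimen anatomy (baseline
  rotations, disc baselines) is paired across arms; each imaging session
  redraws residual noise.  A stage adds (+3/+4.5/+6)° rotation and
  (+8/+11/+14 anterior, +6/+8/+10 posterior) %EPW disc-opening excess
  *beyond the rotation-predicted value*, while translation follows the RDT
  line at the *baseline* rotation — the sectioned segment rotates further
  without recruiting the normal rotation-translation coupling, emulating
  intact facet joints maintaining translational stability.  The opening
  excesses are several times the RDDW noise SD, so vertical instability is
  detectable from the first stage.

What passing tests on these cohorts shows — and does not.  The generator
realizes the model's assumptions exactly: linear rotation-coupling,
Gaussian noise, no landmark jitter, no projection error, no degenerative
remodeling.  Green tests therefore validate the *implementation* (geometry,
fitting, standardization, thresholds, ROC) and the *internal consistency*
of the method, not its clinical accuracy on real radiographs, which would
require imaging data with ground-truth outcomes.

## Problem sizes and numerical choices

Validation suites use 2,000-segment reference cohorts, a 10,000-segment
calibration cohort, 200 posed exams for the geometric round trip, 100
random ROC instances, and 20 seeds (majority rule) for the sectioning
AUC ordering — sizes at which Monte-Carlo error is far below every
asserted tolerance while the whole suite runs in seconds.  Angles are
wrapped to (−180°, 180°]; similarity registration uses SVD with the
reflection branch excluded; index calibration is asserted on non-excluded
segments only.  Canonical JSON (sorted levels, fixed corner order) makes
serialization byte-reproducible.

## Known limitations

* Only sagittal-plane motion is modeled; axial/coronal coupling is out of
  scope.
* The synthetic disc-height distributions are conventions; no normative
  disc-height table is published, so SDH calibration on real data would
  need a real reference cohort.
* The corner-distance disc-height definition differs from a
  perpendicular-distance construction on tilted endplates by a cosine
  factor; reference and subject must use the same convention (they do,
  within this package).
* Landmark noise is not simulated; sensitivity of the indices to landmark
  jitter is an open empirical question for any deployment.
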