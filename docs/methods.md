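# Methods

This note documents the models and procedures `periskin` implements, the
assumptions of its synthetic-data generators, the numerical choices that
were genuinely open, and what the test suite's passing does and does not
establish about real data.

## The periorbital indices

Seven per-subject indices, all on a common 0-100 scale:

| index | meaning | source |
|-------|---------|--------|
| Wb, Wu | wrinkles beside / under the eyes | area-fraction scoring (device-style) |
| Wa | wrinkles above the inner corner of the eyes | ridge-filter pipeline |
| Pb, Pu | pigmented spots beside / under the eyes | blob-detection scoring |
| Md | eye droopiness, `H1 - H2` (px) | landmarks |
| Mw | temporal width, `(L2 + L3) / L1` | landmarks |

Left and right regions are scored separately and averaged, so each subject
carries one value per index.

**Coordinate conventions.** Pixel coordinates, origin top-left, x right,
y down, 0-based; all region boxes are half-open `(x0, y0, x1, y1)`.
Heights are measured image-up (`height = image_height - y`), so Md is
positive when the lateral (outer) canthus sits *lower* than the medial one
-- drooping increases Md. Md is invariant to horizontal translation and
flips sign under vertical reflection (tested). L2 and L3 are horizontal
distances from each outer canthus to the facial outline interpolated at
the canthus height, and L1 is the horizontal facial width at the mean
canthus height; dividing by L1 makes Mw invariant to rigid translation and
uniform scaling of the face.

## Wrinkle detection

The wrinkle path is: crop region-of-interest -> grayscale (BT.601
luminance) -> multi-scale Hessian ridge response -> Fourier enhancement ->
area-fraction score.

**Ridge filter.** At each scale sigma in {1, 1.5, 2} px the patch is
Gaussian-smoothed and the Hessian computed with sigma^2-normalized
derivatives. With eigenvalues ordered |l1| <= |l2|, the response is

    exp(-(l1/l2)^2 / (2 beta^2)) * (1 - exp(-F^2 / (2 gamma^2)))

zeroed where l2 <= 0 (a dark line is an intensity valley, so the
cross-line second derivative must be positive), maximized over scales and
rescaled to [0, 1]. `F` is the Hessian Frobenius norm. Defaults:
`beta = 0.5` (blob suppression; the first term is ~1 for line-like
structure where |l1| << |l2| and small for blobs where the ratio
approaches 1) and `gamma` = half the maximum Frobenius norm at that scale
(so the strength term adapts to patch contrast). The patch mean is
subtracted before filtering; in exact arithmetic the Hessian ignores
constants anyway, and subtracting the mean keeps the truncated discrete
kernels from leaking a constant offset into the response, making the
documented offset-invariance exact. Localization: on matched-scale
straight-line fixtures the per-cross-section response maximum sits within
1 px of the true centerline for >= 95% of cross-sections (tested straight
and at 45 degrees).

**Fourier enhancement.** The response spectrum is restricted to radial
wavelengths in [2, 32] px; the DC coefficient is kept so the map's mean
(and hence nonnegativity) survives. Retained coefficients below the 98th
magnitude percentile of the in-band distribution are zeroed. The inverse
transform is clipped to >= 0 and min-max rescaled to [0, 1]. Rationale for
the defaults: a coherent curvilinear ridge concentrates its energy in a
thin spectral ridge occupying roughly 1-2% of the band, while incoherent
speckle spreads its energy uniformly over the whole band, so a strict
magnitude gate (98th percentile) removes speckle while the ridge survives;
and a wrinkle's spectral support includes its low-frequency envelope, so
the band's upper wavelength must comfortably exceed the wrinkle width
(32 px rather than a tight 16 px, which measurably hollows the ridge and
*reduces* overlap with ground truth). Both choices are configuration
parameters (`BandParams`); the defaults were fixed from the line-plus-
speckle fixture behavior and are exercised by the enhancement tests.

**Scoring.** The raw score is the fraction of pixels above 0.2 x the
enhanced map's maximum (the monotonicity tests hold across +-50%
perturbations of this binarization choice). Spots: background skin tone is
estimated by a large-kernel (sigma = 12 px) Gaussian blur; pixels darker
than background by > 10 intensity units form candidates, and connected
components are kept when their equivalent radius is 1.5-12 px and their
minor/major axis ratio is >= 0.35 (rejecting elongated wrinkles).

**Calibration.** Raw area fractions are mapped affinely onto [0, 100]
using bounds estimated from a reference cohort of >= 30 patches: the 1st
and 99th percentiles taken with outward-conservative interpolation
(`lower` / `higher`), persisted as JSON and reloadable bit-exactly. The
conservative percentile methods mean that on reference cohorts of n <= 100
the bounds equal the observed min/max, nothing in the reference cohort
clips, and the affine map preserves ranks and Pearson correlations
exactly; on larger cohorts the bounds become genuinely robust percentiles
and up to ~2% of extreme values clip. The same machinery normalizes the
raw morphology values.

## Age models

Nine fixed feature subsets (see the README table). Each model is an OLS
fit of chronological age on its subset (statsmodels under the hood; the
tests verify the estimates against directly solved normal equations to
1e-8). Evaluation is the mean over 10 folds of the Pearson correlation
between held-out predictions and actual ages; folds are a seeded random
partition of subjects (age-stratified folding is available but off by
default, since simple random folding is the plainer design). Subjects are
ordered by id before partitioning so the result does not depend on row
order. Final models are refit on the full build cohort, then *refined*:
while any coefficient is negative, the most negative one's feature is
dropped and the model refit. Refinement is iterative rather than
single-pass because removing one collinear feature can flip another's
sign; the removal sequence is recorded on the results object. The refined
("double-prime") model's prediction is the periorbital skin age, reported
unclipped (with a warning outside [0, 120]) because it is a biomarker, not
a bounded age estimate.

## Disease association

Logistic regressions (maximum likelihood, Wald p-values by default; a
likelihood-ratio option exists since the choice is conventional) of each
disease flag on a predictor, optionally adjusted for covariates. The
reported family is the eight rows D0-D7; BH-FDR is applied across the
eight skin-age tests (matching the printed-table convention; a
seven-disease family with D0 outside it is available via
`fdr_family="individual"`). PCA of the seven binary indicators is
performed on the correlation convention (columns standardized); the paper
trail for binary-indicator PCA does not fix a centering/scaling choice, so
this is a documented decision. PC1's sign is fixed so its loading sum is
positive, which makes the sign of the PC1-skin-age correlation
reproducible across seeds and platforms. Zero-variance disease columns are
dropped with a warning.

## Synthetic data

**Cohorts.** The build design draws 400 subjects per 10-year interval over
ages 20-69 (n = 2,000); the validation design draws 103 per decade
(n = 515). Ages are uniform within each decade with exact counts. Feature
i is generated from a single age factor,

    x_i = r_i * z(age) + sqrt(1 - r_i^2) * eps_i,

with independent standard-normal noise and z the age standardized by its
design mean and SD, then mapped affinely onto [0, 100] over +-4 latent SD
and clipped (clipping touches ~6e-5 of draws, so configured correlations
survive essentially exactly; the Monte-Carlo tests confirm sample r within
+-0.03 of target at n = 2,000). The default correlation targets are
0.588/0.603/0.584 for the three wrinkle indices, 0.723/0.758 for the two
spot indices, and 0.174/0.518 for Md/Mw -- the structure the analysis
assumes: spots strongest, wrinkles moderate, morphology weakest with Md
much weaker than Mw.

Features are **conditionally independent given age**. This is the key
simplification: only marginal age correlations are specified, so the
single-factor model is the minimal generator consistent with them, and it
makes the population multiple correlation of any feature subset available
in closed form via Sherman-Morrison:

    R = sqrt(S / (1 + S)),   S = sum_i r_i^2 / (1 - r_i^2).

The all-feature model's cross-validated r is tested against this oracle
(itself first verified by a 200k-sample simulation). At the default
targets R = 0.904 -- higher than real cohorts show, because real indices
share variance beyond age (sun exposure, skin type), which lowers the
joint ceiling. Passing the oracle test shows the modelling machinery is
correct at the configured design, not that real performance would reach
0.9.

Disease flags are Bernoulli with per-disease logistic models in age,
`logit p = logit(prev_45) + slope * (age - 45)`. Defaults: the five
chronic conditions (hypertension, hyperlipidemia, fatty liver, kidney
disease, diabetes) have prevalence 5-12% at age 45 and positive slopes
0.05-0.08 per year; heart disease and cancer are rare (3%) and
age-independent. These are stated modelling assumptions -- source cohorts
for this kind of analysis do not publish their prevalences -- chosen so
the association analysis has a known recoverable structure: five diseases
genuinely age-linked, two null. Lifestyle covariates (lognormal weekly sun
hours, ordinal sunscreen frequency 0-4, 10% smoking) are independent noise
by default. D0 is the OR of D1-D7.

**Images.** A face patch (square canvas >= 128 px) is a flat skin-toned
background plus Gaussian pixel noise, with landmark geometry laid out as
canvas fractions (canthi, five-point eyebrow and eyelid arcs, facial
outline polylines, cheek/temple anchors). Wrinkles are quadratic Bezier
centerlines with a Gaussian cross-section (depth 35 intensity units, width
3 px by default), placed inside the landmark-derived region boxes --
line-like intensity valleys, the morphology a Hessian ridge detector is
built for. Spots are smooth dark ellipses (depth profile falling to zero
at the boundary) with semi-axes 2.5-6 px. Ground truth records the
analytic curve parameters, the half-depth footprint mask (pixels within
half a width of the centerline), the 1-px centerline raster, and
per-region masks. Identical spec + seed is bit-identical by construction.
What the generator does *not* emulate: texture (pores, flaking),
illumination gradients, specular highlights, hair, eyelashes, or the
actual appearance of an eye -- so passing image tests demonstrates the
detector's geometric correctness, not robustness to photographic
confounds.

## Pipeline and reproducibility

`run_pipeline` executes simulate -> extract -> fit -> associate. The age
models are fitted on the simulated cohort *table* (the cohort generator's
contract provides the seven indices directly, mirroring the study design);
the extract stage runs the full image->score path on a smaller imaging
subset (12 faces by default) with self-calibration, as a continuous
integration of the image pipeline rather than a per-subject measurement of
the cohort. One global seed fans out per stage as
`(seed * 1_000_003 + stage_index) mod 2^31`, so stages rerun in isolation
reproducibly. Artifacts are CSV/JSON/PNG; the manifest records a SHA-256
checksum per file, and reruns under an unchanged config are byte-identical
(tested).

## Degenerate inputs and guards

Constant patches give identically zero ridge response; empty p-value
families, single-class outcomes, separable logistic fits, zero-variance
calibration cohorts, rank-deficient designs (reported with the collinear
feature names), zero facial width, and out-of-canvas landmarks all raise
explicit errors rather than propagating NaNs.

## Known limitations

* The spot scorer is a transparent stand-in for device-measured
  pigmentation indices; it is validated against synthetic ground truth
  only.
* The conditional-independence cohort overstates achievable model
  performance relative to real cohorts (see above); comparisons between
  models (orderings, nesting) transfer, absolute r values do not.
* Disease prevalences, slopes and lifestyle distributions are assumptions;
  association results on synthetic cohorts demonstrate calibration and
  power of the machinery, not epidemiology.
* Landmarks are inputs throughout; detecting them from photographs is out
  of scope.
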