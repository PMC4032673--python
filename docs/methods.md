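# Methods

## Problem and model

The package classifies the sex of a subject from a single flat-bed palm
scan using three geometric features of the hand silhouette and a linear
classifier. The modelling assumptions are:

* the scan shows one hand, brighter than the background, fully inside the
  frame (the acquisition protocol this emulates uses a flat-bed scanner,
  which yields uniform illumination and a fixed scale);
* sex enters the features only through overall hand size: adult male hands
  are stochastically larger than female hands, while hand *shape* (the
  aspect ratio) is essentially shared;
* a linear decision boundary in (length, width, ratio) space is adequate —
  no kernels, no finger-level landmarks.

### Preprocessing

Grayscale conversion uses the BT.601 luminance weights
(0.2989, 0.5870, 0.1140), rounded half-up to 8-bit integers. The
background filter keeps a pixel iff its intensity is `>=` the image mean
`H` (the mean is kept as an unrounded real; the `>=` convention means a
constant image passes unfiltered). This exploits the bright-hand/dark-
background structure: `H` always falls between the two intensity modes as
long as the hand occupies a non-trivial fraction of the frame.

### Silhouette geometry

Segmentation: nonzero pixels → 3×3 morphological closing → largest
8-connected component (ties broken toward the smaller top-left bounding
box corner) → hole filling; components below `min_area` (default 500 px)
are rejected. The closing bridges noise-induced single-pixel gaps; hole
filling removes noise dropouts inside the hand; the largest-component rule
removes background pixels that survive the threshold by chance.

Pose normalization: subjects place the hand freely, so the silhouette is
rotated/shifted arbitrarily. The mask is rotated so the principal axis of
its second central moments is vertical, flipped so the heavier half (the
palm) is at the bottom, cropped to its bounding box, and padded so the
centroid is the raster center. A silhouette with isotropic second moments
(anisotropy below 1e-9 relative, e.g. a perfect disc) has no principal
axis and is rejected. Rotation uses bilinear interpolation on the float
mask with a 0.5 threshold, which keeps boundary erosion/dilation within
about one pixel.

Measurement: **length** is the number of rows spanned by the normalized
mask (wrist line to longest fingertip — the full hand, since the
silhouette carries no wrist landmark); **width** is the maximal
count-of-true-pixels over the rows of the *proximal (bottom) half* of that
span. Restricting to the bottom half excludes the fingers from the width
without any finger-valley detection; the palm is the widest solid region
there. Features are reported in pixels at the native scan resolution; the
classifier standardizes them anyway, so no mm conversion is performed.

### PSSVM

The hinge-loss SVM is reformulated as an unconstrained smooth minimization
by replacing `max(x, 0)` with the piecewise cubic `h(x, k)` (see README).
Analytic facts used by the implementation and verified by tests:

* `h(x, k) = max(x, 0)` exactly outside `[-1/k, 1/k]`; the maximal
  deviation is `3/(16k)` at `x = 0`;
* `h` is C¹ with `h'(x) = -(k³/4)(x + 1/k)²(x - 2/k)` on the middle piece
  (1 above, 0 below), and piecewise-C¹ with
  `h''(x) = -(3k³/4)(x + 1/k)(x - 1/k) >= 0` there (boundaries assigned to
  the middle piece — a measure-zero choice since `h''` vanishes at them);
* the objective's Hessian is `ν Σ wᵢ cᵢcᵢᵀ + I` with weights
  `wᵢ = h'² + h·h'' >= 0`, hence symmetric positive definite with smallest
  eigenvalue `>= 1`: the problem is strictly convex and the minimizer is
  unique.

The solver is Newton's method with Armijo backtracking (σ = 1e-4, step
halving, at most 30 backtracks), started at the origin, stopping when
`‖∇F‖ <= 1e-8` (default) or after 100 iterations; non-convergence is
flagged on the model and warned about, never raised. Because the Hessian
is SPD, each Newton system is solved by Cholesky factorization.

Features are z-scored per column with statistics computed **on the
training split only** before training; the statistics are stored in the
model and re-applied at prediction time. Without this, pixel-scale
features (hundreds of px) would dominate the fixed unit regularizer.
Prediction is `sign(xᵀω - γ)` with the deterministic tie rule
`sign(0) = +1`.

Default hyperparameters: `ν = 100` (loss weight; larger values track the
hard-margin SVM more closely) and `k = 10` (smoothing sharpness;
approximation error `3/160 ≈ 0.019` per margin unit). Both are exposed on
the CLI and in `PipelineConfig`. The train/test protocol draws
`⌈f·m⌉` training rows uniformly without replacement (default `f = 0.2`;
for the 180-image database that is 36 train / 144 test rows).

## Synthetic data

`render_hand` draws a rectangular palm of given length × width with five
capsule fingers (rectangle + semicircular tip) attached to the distal
edge, rotates and shifts the silhouette, and adds clipped Gaussian pixel
noise on a darker background. Extents are drawn at integer-rounded sizes,
so the drawn area matches the analytic rectangle+capsule composition to
raster precision (tested at 1%). The ground-truth hand length is
`palm_length + max(finger_length) + finger_width/2` (the tip cap).

`sample_population` draws a database: per subject, base palm length and
width come from a sex-specific lognormal (lognormal guarantees
positivity); each image jitters them (within-subject CV, default 1%) and
adds a uniform rotation in ±15° and a uniform shift within ±20 px.
Defaults mirror the reference layout: 30 subjects × 6 images (3 per
hand), 15 male, female palm 200 × 150 px at the default quarter-scale
canvas of 632 × 450, male means 1.1× female, between-subject CV 4%. The
1.1× / 4% dimorphism is an engineering stand-in chosen once — roughly a
2.4 σ size separation per feature, which is in the plausible range for
adult hand dimensions — since no measurement distributions are available
for the private reference data.

`sample_feature_table` draws (length, width, ratio) rows from the same
two-level scheme without rendering, for fast classifier tests.

What the generator does **not** emulate: skin texture, palm lines,
finger spreading and thumb abduction, perspective, illumination gradients,
scanner artifacts. Passing tests therefore demonstrate correctness of the
geometry and the classifier under the stated silhouette model, not
performance on real scans.

## Experiment design notes

* **Null control.** With the two-level population and an image-level
  random split, images of one subject land on both sides of the split; a
  classifier can then re-identify subjects by size alone, which lifts
  zero-dimorphism accuracy to ≈ 55% without any defect in the code. The
  degenerate-signal control therefore uses the null population with
  between-subject CV 0 and all size variation at the image level (iid
  features): there, any above-chance accuracy could only come from label
  leakage in the pipeline. The same subject-memorization effect is present
  in any protocol that splits at the image rather than the subject level
  and should be kept in mind when reading accuracies from such protocols.
* **Problem sizes.** The end-to-end benchmark renders the 30 × 6 database
  and runs the full image pipeline over 20 seeds at both 20% and 10%
  training fractions (the dataset is simulated once per seed and split
  twice). Geometry recovery uses 50 hands with rotations up to ±30°,
  shifts up to ±20 px, and noise σ = 8. Solver checks compare against a
  derivative-free Nelder-Mead minimization of the same objective on
  m = 20, n = 2 problems.
* **Numerical choices.** The Armijo acceptance test carries a slack of
  10 ε · max(1, |F|): near the minimizer the predicted decrease drops
  below the floating-point resolution of the objective, and without the
  slack the full Newton step — quadratically convergent exactly there —
  would be rejected on rounding noise and the iteration would stall.
  Isotropy tolerance 1e-9 (relative) for the
  undefined-orientation error; rotation interpolation order 1 with 0.5
  threshold; segmentation tie-break by bounding-box corner; zero-spread
  feature columns get scale 1 in standardization; split sizes use
  ceiling on the training side.

## Limitations

* Features are raster measurements; accuracy below ~1 px is not
  attainable, so sub-percent feature differences are not meaningful at the
  default canvas scale.
* The pose normalizer assumes the hand is the only foreground object and
  that the palm half is heavier than the finger half; gloves, jewellery,
  or partially closed hands violate this.
* The classifier is linear on three features; it cannot express
  interactions beyond the ratio it is given.
* Reported accuracies on synthetic data depend directly on the assumed
  dimorphism (1.1×, CV 4%); they characterize the pipeline, not human
  populations.
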