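# Methods

## Problem and model

The package classifies nutritional risk (NRS-2002 ≥ 3 vs < 3) from the
appearance of the sub-orbital fat-pad region of a face image.  The pipeline
is fully modular: geometry normalization, region segmentation, texture
description, dimensionality reduction, and a kernel classifier.  Each stage
is usable on its own; `run_pipeline` / `run_synthetic_experiment` wire them
together.

### Geometry

Alignment rotates rigidly about the midpoint of the two eye centroids
(landmarks 36–41 and 42–47 of the standard 68-point scheme) by the negative
of the interocular angle, measured in a y-down frame and folded to
(−90°, 90°].  Cropping is realized as **one** similarity transform rather
than a sequential crop-then-resize: the three stated constraints (face
midline at x = 150, eye center at 30% from the top, mouth centroid at 35%
from the bottom of a 300 × 300 frame) determine the uniform scale
s = 105 / (y_mouth − y_eye) and translation exactly, and a single resampling
pass is strictly less lossy than two.  Raster warps are bilinear with black
fill; black borders contribute near-zero HOG energy.  Coordinates are
0-based with pixel centers on integers.

### Segmentation network

A classic U-net, written in NumPy (im2col convolutions running on BLAS,
gradients derived by hand): per level two 3×3 same-padding convolutions
with ReLU, 2×2 max pooling down, 2×2 stride-2 transposed convolutions and
skip concatenation up, a 1×1 convolution and sigmoid at the end.  Depth is
counted in resolution levels; the default is 4 levels (three poolings) with
64 base channels doubling per level.  Weights use He initialization; the
output bias starts at −4, the approximate prior log-odds of the sparse
fat-pad foreground, so early updates concentrate on the region of interest
rather than on re-learning the class prior.

Training follows the recipe: batch size 1, 50 epochs, binary cross-entropy
(masks stored as {0,255} are converted to {0,1} targets), RMSProp with
learning rate 10⁻⁵, weight decay 10⁻⁸, momentum 0.9.  One numerical
choice: the RMSProp square-average is bias-corrected by 1 − αᵗ (as in Adam)
before the square root.  Uncorrected RMSProp scales its first steps by the
arbitrary zero initialization of the accumulator, which produces a large
random jolt at the start of training; with the correction the update
coincides with the textbook rule after the burn-in but is properly scaled
from step one.  Predictions binarize the sigmoid output at 0.5, the
standard threshold for a BCE-trained probability.

**Desk-scale configuration.**  The test suite trains on 128 × 128 rendered
fixtures with 16 base channels, 3 resolution levels, and learning rate
5 × 10⁻⁴ with momentum 0.5 and α = 0.8 (≤ 50 epochs).  The clinical-scale
default learning rate of 10⁻⁵ is calibrated to a schedule of roughly 20,000
updates (hundreds of images × 50 epochs); a 50–400-update run cannot move
the weights appreciably at that rate, so the scaled-down schedule uses a
proportionally larger step and a faster-adapting square average.  These are
configuration values of the same code path, not a different algorithm.

### HOG descriptor

Dalal–Triggs HOG with the package's fixed parameterization: centered
differences [−1, 0, 1] with replicated borders; unsigned orientations
folded to [0°, 180°); each pixel's magnitude vote split linearly between
the two nearest of 9 bin centers at i·π/9 (wrapping between bins 8 and 0);
8×8-px cells (partial border cells truncated — 300/8 = 37.5 → 37 cells);
2×2-cell blocks at 1-cell stride (the only stride consistent with the
46,656-feature dimensionality of a 300×300 image); L2-Hys normalization
(L2-normalize, clip at 0.2, renormalize), with an all-zero guard for
zero-gradient blocks.  Concatenation order is blocks row-major, cells
row-major, bins ascending.  A naive per-pixel reference implementation
lives in the test suite and the vectorized extractor is required to match
it to 10⁻¹⁰.

### Standardization and PCA

z-scoring uses population σ computed on the **training split only**;
constant features (σ = 0, common outside the mask) standardize to exactly
0.  PCA is likewise fitted on training features only and reduces to k = 100
components (clamped to min(n_train, d) for small cohorts); component signs
are fixed so the largest-magnitude loading is positive, making projections
reproducible.  Fitting scaler and PCA on pooled train+test would leak test
statistics into the features, so the train-only convention is the default
throughout.

### Classifier and metrics

Soft-margin SVM (scikit-learn's SMO solver) with RBF kernel, C = 50,
γ = 10⁻⁵; no class weighting by default (a `balanced` flag exists).  The
positive class is NRS-2002 < 3.  Grid search is exhaustive over a
user-supplied C/γ/kernel grid, scored by stratified k-fold accuracy, ties
broken toward smaller C then smaller γ.  Metrics with a zero denominator
are reported as NaN ("undefined"), never silently as zero.  Note that on a
99/35 test split, accuracy 73.1% and recall 93.9% imply the confusion
quadruple (TP 93, TN 5, FP 30, FN 6) and hence precision 75.6% and F1
83.8%; a precision of 97.3% is not simultaneously attainable, which is why
the package treats accuracy/recall as the anchor quantities in its
reference checks.

### Cohort statistics

All 2×2 tests are Pearson chi-square with Yates continuity correction
(each observed count moved 0.5 toward its expectation, never past it), 1
df.  This choice reproduces the five reference p-values (0.306, 0.315,
0.629; 0.169, 0.867) from their printed tables to three decimals, which the
uncorrected statistic does not (e.g. it gives ≈ 0.13 instead of 0.169 for
the age table).  A degenerate subgroup table in which every prediction is
correct (or every one incorrect) in both levels is reported as statistic 0,
p = 1 — outcomes are perfectly homogeneous.  A validity warning is attached
when any expected cell is below 5.

## Synthetic cohorts

`nutriface.synthetic` renders schematic faces: elliptical head, eyes,
brows, nose, mouth, and a crescent-shaped sub-orbital fat pad under each
eye, with the 68 landmarks placed analytically on the same shapes (eye and
mouth landmark groups are symmetric, so their centroids coincide exactly
with the feature centers).  Jitter is a rigid rotation (default ±10°) about
the eye midpoint plus translation (default ±10 px); the raster is rendered
by inverse-mapping pixels into the canonical frame while landmarks are
forward-mapped, so geometry and annotation are exactly consistent.

Cohort structure defaults mirror the reference clinical cohort: prevalence
123/515 ≈ 0.239, elderly fraction 0.165, male fraction 0.615, remote-site
fraction 194/515 ≈ 0.377; demographics are sampled independently of the
label (the cohort's chi-square tests found no association).  NRS scores are
uniform on {0,1,2} or {3,4,5} given the class.

The class signal is a latent appearance value a = effect·z + ε, ε ~ N(0,1),
z the at-risk indicator, which drives both the crescent's thickness
(24 ± 3·a px at the 512-px canvas, clipped to [10, 40]) and its brightness
(0.18 + 0.02·a above skin), over a ridged texture — so the descriptor sees
a structural (gradient) signal, not merely a mean shift.  The crescent is
rendered prominently (≈ 1.5–2% of pixels): the real anatomical region is a
salient, clinician-visible feature, and the generator's purpose is a
well-conditioned testbed for the pipeline, not a hard perception benchmark.
The default effect size is 2 appearance-noise SDs.

What the generator does **not** emulate: photographic texture and identity
variation, lighting/pose/occlusion effects (glasses, masks, blur — the
cohort filtering that removes such photos is emulated by never rendering
them), inter-annotator mask variability, and any genuine physiological link
between periorbital appearance and nutrition.  Passing tests therefore
demonstrate that the pipeline is implemented correctly and recovers a
planted signal of realistic size — not that the clinical effect itself is
reproduced.

## Problem sizes used by the tests

Unit and acceptance tests run on one CPU: geometry/HOG/stats examples are
instantaneous; segmentation sanity uses 128-px fixtures (one-sample
memorization ≤ 50 epochs; 40 fixtures × 10 epochs); signal recovery uses
three 300-subject cohorts (≈ 74/26 split, mirroring the 381/134
classification split of the reference cohort) with ground-truth masks.  The
full 300 × 300 / 64-channel / 50-epoch recipe is exercised through the same
code path at reduced size and remains available via configuration.

## Known limitations

- The NumPy U-net is single-image (batch size 1 only) and CPU-bound; the
  clinical-scale recipe is supported but slow without a GPU framework.
- `interocular_angle` is undefined for a 90° head roll (folded range); the
  generator never produces such poses and real detectors rarely do.
- Chi-square p-values are asymptotic; small subgroup tables trigger a
  validity warning rather than an automatic exact test.
- Landmarks for real photographs must come from an external 68-point
  detector; the package consumes them via the `index,x,y` CSV adapter.
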