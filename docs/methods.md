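# Methods

This note documents the models, parameters and design choices behind
`tmagleason`, and what the synthetic validation does and does not show.

## Pipeline model

The system grades one TMA spot in five steps: tissue detection, patch
extraction, patch classification, fully convolutional probability
mapping, and weighted-threshold score aggregation.  Agreement and
survival analyses sit on top of the per-spot scores.

### Tissue detection

Grayscale conversion uses ITU-R 601 luminance (0.299 R + 0.587 G +
0.114 B).  The pipeline is Gaussian filter → Otsu threshold → dilation
→ erosion, in that order; the darker Otsu class is tissue because H&E
slides are scanned on a bright background.  Defaults: σ = 2 px and a
disk structuring element of radius 10 px at full resolution (radius 5
in the half-resolution profile).  These sizes close gland-lumen-sized
holes without bridging separate tissue fragments.  A constant-intensity
image has no Otsu threshold; the function returns an empty mask and
warns rather than guessing.

### Patch geometry and labeling

Full-resolution geometry: 750-px patches on a 375-px stride grid,
anchored at (0, 0); patches that do not fit inside the spot are
skipped (no padding).  A patch is labeled by the single distinct
nonzero annotation inside its central 250×250 window.  Unannotated
(code 0) pixels inside the window are ignored — pathologist regions
legitimately contain internal stroma — but a window with no annotated
pixel at all discards the patch, as does a window containing two or
more annotations.  A 3100×3100 spot that is single-labeled everywhere
therefore yields exactly (⌊(3100−750)/375⌋+1)² = 49 patches.

Patches are resized 750 → 250 before augmentation.  Augmentation order:
resize → random 224 crop → rotation → flips → color jitter.  Rotations
are multiples of 90° (lossless) and flips have probability 0.5 each;
the color jitter scales brightness/contrast/saturation by factors in
[0.9, 1.1] and shifts hue by ±0.02 — mild enough to preserve stain
identity.  All four jitter components are affine in RGB, so they are
folded into a single 3×3 matrix per sample and applied in one pass.
With randomness disabled the augmentation degenerates to the center
crop, which is also what evaluation uses.

Balanced sampling: every mini-batch of 32 contains exactly 8 patches
per class, drawn uniformly with replacement within class.  A dataset
missing a class raises an error naming the class.

### Classifier

A depthwise-separable convolution network in the MobileNet-v1 layout:
a 3×3 stride-2 stem, then 13 blocks of (3×3 depthwise convolution,
batch norm, ReLU, 1×1 pointwise convolution, batch norm, ReLU), with
depthwise strides of 2 at blocks 2, 4, 6 and 12 (output stride 32),
then global average pooling, dropout 0.2, and a dense softmax head
over (Benign, G3, G4, G5).  The width multiplier α scales every
channel count; α = 1 runs 32 → 1024 channels, the default α = 0.5 runs
16 → 512.  Non-integer channel counts are rounded up with a warning.
Inputs are scaled to [0, 1] and centered by the per-channel training
mean.  Weights use He-normal initialization; batch norm uses momentum
0.9 and ε = 1e−3.

Two training regimes are exposed: `scratch` (Adam, lr 0.001) and
`finetune` (SGD, lr 0.0001, Nesterov momentum 0.9), both minimizing
categorical cross-entropy for a configurable number of iterations
(default 50,000); learning rates are constant (no decay schedule).  A
non-finite loss aborts with a diagnostic.  An ImageNet-pretrained
initialization hook is not shipped: pretrained weights are not
redistributable, and the scratch regime is what the synthetic study
exercises.

The engine behind the layers is a small NumPy implementation with
reverse-mode gradients, written for this package.  Depthwise
convolutions and fused batch-norm+ReLU passes are memory-bound, so
they run as single-pass numba kernels (with a pure-NumPy fallback);
pointwise convolutions and the dense head go through BLAS.  Analytic
gradients are verified against finite differences in the test suite.
At the desk-scale network size one training iteration takes ~0.1 s on
one CPU core.

### Fully convolutional conversion

For pixel-level maps the global pooling (which sees a 7×7 map for
224-px inputs) becomes a local average pooling of that same window
size with stride 1, and the dense head a 1×1 convolution with
identical weights; softmax is applied per location and the map is
upsampled ×32 (nearest neighbour — chosen because it preserves the
per-pixel probability simplex exactly).  The pooling window always
equals the model's own pre-pooling map side at its training input
size, so the conversion is defined for any input size that is a
multiple of the output stride (7×7 pooling at input 224, 3×3 at input
96); other input sizes are rejected.

Convolutions use same-padding for whole-image inference.  With valid
pooling a single training-size patch produces exactly one output
location, which matches `predict_patch` to float precision — the
equivalence is asserted over random inputs in the tests.  Border
locations whose receptive field (507 px of network input, plus the
pooling window) leaves the image are still reported, and the map
metadata flags the affected border band width.

Spots enter the network at the training scale: patches were resized by
resize_to/patch_size = 1/3, so whole spots are downscaled by the same
factor before inference and the finished map is restored to spot
resolution by nearest-neighbour resizing.  Tile-wise inference aligns
tile origins to the output stride and carries a context margin that
covers the receptive field, making tiled and untiled maps identical up
to float roundoff (asserted at 1e−4).  Probabilities are zeroed
outside the tissue mask after the softmax, and all downstream sums run
over tissue pixels only.

### Score aggregation

Class weights and final scores follow

    w^k      = Σ_{i,j} o_{i,j}^k / Σ_{i,j,k} o_{i,j}^k
    w_final^k = 1{w^k > c} · w^k,   c = 0.25.

The Benign channel participates in the normalization but never in
primary/secondary selection; a spot is benign exactly when no cancer
pattern's weight clears the threshold.  The comparison is strict, so
four classes at exactly 0.25 each would zero everything; the default
tie rule keeps the argmax class in that degenerate case so an
assignment always exists (a `strict` rule that reports benign instead
is available).  Exact ties between two cancer patterns' final scores
resolve toward the lower (less aggressive) pattern.  Because w^k is
normalized, scaling all probabilities by a constant cannot change the
assignment, and raising c can only remove patterns, never add them.

### Agreement metrics

Quadratic weighted kappa is computed from the contingency matrix O
with weights w_ij = (i−j)²/(N−1)² and expected counts E = outer
product of the marginals over the grand total.  Patch-level
comparisons use the ordered classes (Benign, G3, G4, G5), N = 4.
Spot-level comparisons embed composite scores as Benign < 6 < 7 < 8 <
9 < 10 with unit spacing, N = 6 — treating benign as rank-adjacent to
score 6 is the simplest consistent ordinal reading, and the report
metadata flags this choice.  Macro recall averages per-class recall
over classes present in the truth; absent classes are excluded rather
than counted as zero.  Consensus precision counts a prediction as
correct when it matches at least one of two raters.

### Survival analysis

Risk groups: low (benign or score ≤ 6), intermediate (7), high (≥ 8).
Placing benign spots in the low-risk group is a deliberate choice
(the grouping rule covers scores only) and is flagged in the report
metadata.  Kaplan–Meier estimation, Greenwood-based log-transformed
95% bands and the two-tailed logrank test are delegated to lifelines;
Benjamini–Hochberg correction (over the family of the three pairwise
comparisons) to statsmodels.  Tied censoring times follow the standard
convention (censored subjects remain at risk at their own time).  The
tests verify the product-limit values by hand, the logrank statistic
against a direct observed-minus-expected computation and a label-
permutation null, and the null uniformity of p-values.

## Synthetic data

The generator emulates an annotated TMA cohort.  Each spot is a tissue
disk (radius 0.48 × spot side) on a bright background, partitioned
into angular sectors whose areas are proportional to the requested
region fractions; the remainder stays unannotated stroma.  Textures at
reference resolution (3100 px, ~0.23 µm/px; all sizes scale with the
spot side):

* **benign** — gland radius 58 px, spacing 260 px, lumen ratio 0.74,
  dark basal outline;
* **G3** — radius 26 px, spacing 80 px (non-touching), lumen 0.52;
* **G4** — radius 26 px, spacing 44 px with placement jitter 0.35
  (chains/fusion), lumen 0.30, and every 7th gland replaced by a
  cribriform disc with 5–8 punched lumens;
* **G5** — near-solid epithelium (radius 20, spacing 26) with dense
  nuclei, no lumens.

Gaussian pixel noise (σ = 3) is added last.  These values were fixed
once, by checking that the four patterns have clearly separated mean
gland-count and lumen-area statistics (asserted by Welch tests in the
suite) while remaining visually plausible; within-pattern variability
knobs are otherwise free parameters with no empirical calibration.

Cohort scores are drawn from a mix loosely imitating a prostatectomy
test cohort (13% benign, 25% score 6, 30% score 7, 12/12/8% scores
8–10).  A drawn score is realized geometrically: mixed scores (7 = 3+4,
9 = 4+5) get ~0.50/~0.35 area for primary/secondary, pure scores a
single ~0.80 region, the rest benign — so exactly the intended
patterns clear the 0.25 weight threshold and the ground-truth mask
reproduces the score under the package's own scoring rule (this
closure is the scoring-oracle test).  Survival times are exponential
with hazard 0.004/month in the low tier multiplied by 3 per risk tier,
censored uniformly on [0, 120] months.

What the synthetic study does **not** show: the textures are far
cleaner than real H&E (no stain variation, artefacts, nuclear atypia,
or ambiguous intermediate morphology), so classifier accuracy here is
an upper bound that validates the machinery, not a clinical
performance claim.  Region shapes are convex sectors; real lesions
interdigitate.  Survival links to the true score deterministically
through the tier hazard, with no covariates.

## Problem sizes and numerical choices

The test and reproduction runs use a half-resolution profile: 1550-px
spots, 375/187/125 patch geometry, α = 0.25, 96-px inputs, 2,000
training iterations, 20 training + 10 held-out spots — a complete run
takes a few minutes on one CPU core; defaults elsewhere keep the
full-scale values (3100 px, 750/375/250, α = 0.5, 224, 50,000).
Probability maps agree between tiled and untiled evaluation to 1e−4;
per-pixel simplex sums hold to 1e−5; kappa is checked against brute
force to 1e−12.  All randomness flows through seeded NumPy generators;
identical seeds reproduce training trajectories, generated cohorts and
pipeline artifacts bit-for-bit (single-threaded execution).

## Known limitations

* No stain normalization or artefact/stroma exclusion network; border
  misclassification within the receptive-field band is flagged but not
  corrected.
* The 300-px patch-size variant is configurable but untested; learned
  upsampling and test-time augmentation are out of scope.
* Grade-group (1–5) conversion, percent-pattern and tertiary-pattern
  reporting are not implemented.
* The pure-NumPy engine targets desk-scale networks; it is not a
  general training framework (no GPU, no arbitrary graphs).
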