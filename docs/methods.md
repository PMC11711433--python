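# Methods

## Problem setting

Breast-tumour histopathology slides imaged at four magnifications
(40×, 100×, 200×, 400×) are classified two ways: benign vs malignant, and
into eight subtypes — four benign (adenosis-type AD, fibroadenoma FI,
phyllodes PH, tubular adenoma TU) and four malignant carcinomas (ductal DU,
lobular LO, mucinous MU, papillary PA). Images are loaded as 8-bit RGB,
scaled to [0, 1] and bilinearly resized to 224×224×3. Models are trained
and evaluated per magnification stratum; strata are split independently.

## Architectures

All four models share channels-last tensors, row-major patch order and
0-based indexing. The transformer models patchify with P = 14
(N = 224²/14² = 256 patches of 588 values) and use pre-norm encoder blocks:
LN → multi-head attention → residual → LN → GELU MLP → residual. Attention
projects Q, K, V to `heads × key_dim`, applies
`softmax(QKᵀ/√d_K)V` per head, concatenates and projects back.

Frozen configurations (see "Configuration constraint search"):

| model        | key settings                                                                 | total params |
|--------------|------------------------------------------------------------------------------|-------------|
| ViT          | D=64, 8 blocks, 4 heads (key dim 64), MLP (128, 64), flatten → (2048, 1024) → 2 | 36,376,521 |
| TokenLearner | D=128, S=4 tokens, 4 map convs 3×3 (no bias), 6 blocks, 4 heads (key dim 64), MLP (128), flatten → (512, 256) → 2 | 1,402,169 |
| TokenMixer   | TokenLearner + depthwise 3×3 (bias) + batch norm on the embedded grid          | 1,403,961  |
| ConvMixer    | h=256, stem patch p=4, depth 8, depthwise kernel 3, GAP → 2                    | 577,282    |

The adaptive tokenizer normalises the 16×16×D embedded grid (layer norm),
optionally mixes it depthwise (TokenMixer only), generates S spatial maps
with four stacked 3×3 convolutions (GELU between, sigmoid last so every map
value is in [0, 1]), and emits token `z_i` as the spatial mean of the grid
weighted by map i broadcast over channels. With all map weights zero each
map is identically sigmoid(0) = 0.5 and every token equals half the pooled
grid — a useful exactness check. ConvMixer follows the printed equations
literally, including the residual addition *inside* the first batch
normalisation of each block.

Binary heads use two output units (softmax); this is what the parameter
totals demand. A single sigmoid unit is supported for users who prefer the
classic binary head, at a slightly different parameter count.

## Configuration constraint search

The published tables pin image size 224, patch 14, ViT depth 8 and 4 heads,
and one total parameter count per model — but not the latent width, MLP
widths, token count or ConvMixer geometry. `tokenmixer.param_search`
provides exact closed-form totals per family and a grid-search helper; the
shipped defaults are the unique structurally valid solutions (residual
MLP widths must end at the token dimension; head widths restricted to round
values) that reproduce all four totals exactly.

Two facts anchor the search. First, totals are *full inventories*:
trainable weights plus batch-norm moving statistics plus the 7-value input
standardisation (per-channel mean, variance, sample count) — the figure a
framework model summary prints. The ViT total equals the classic reference
ViT layout's trainable count plus exactly 7, which identifies both the
layout and the counting convention; no trainable-only configuration matches
any of the four totals. Second, the TokenMixer − TokenLearner difference of
1,792 decomposes only as a depthwise 3×3 with bias over 128 channels
(1,280) plus its batch normalisation (512 incl. statistics), which pins the
token models' embedding width at D = 128 and places the depthwise mixing
after patch embedding.

## Training protocol

Adam (learning rate 10⁻³ — the optimiser is named without a rate, so the
common default is used), minibatches of 32, 100 epochs by default, binary
or categorical cross-entropy. No early stopping or schedules. Training
images are augmented on the fly each epoch: rotation ±5°, width/height
shift ±10%, zoom ±0.1%, border fill by edge replication ("nearest" — the
published table's fill-mode entry repeats the zoom value and is treated as
a typographical artifact). Validation and test images are never augmented.
Class imbalance is addressed by augmentation only, no class weighting.

The split is 80/20 test holdout, then 80/20 of the remainder for
train/validation — 64/16/20 overall — stratified by the active label:
within each class the records are shuffled by seed, the test slice is cut
first (floor rounding), then validation, remainder to train, so the
arithmetic is exact and reproducible. Every class must be able to populate
all three partitions (≥ 6 records), otherwise the split raises naming the
class. Multi-class experiments additionally run stratified threefold
cross-validation on the train+validation pool, keeping the test holdout
untouched; fold validation sets are pairwise disjoint and cover the pool.

Timing is reported as total wall-clock training seconds and the per-epoch
average total/num_epochs (an exact identity in the report object).

## Metrics

Accuracy, sensitivity, precision, specificity and F1 follow the standard
confusion-matrix formulas; MCC uses the binary form and the generalised
K-way form; Cohen's κ = (Po − Pe)/(1 − Pe). Undefined ratios evaluate to 0
and are flagged in the report rather than raising. Two published formulas
do not produce what their names promise and are therefore dual-reported:

* The formula list prints "AUC" as sensitivity/specificity, a ratio that
  cannot produce area-like values; the headline `auc` is conventional
  trapezoidal ROC area over a threshold sweep (equal to the Mann–Whitney
  pair statistic with ties as ½, verified in tests), and the literal ratio
  is reported as `sens_spec_ratio`.
* The printed G-mean √(precision·recall/(precision+recall)) has maximum
  √½ ≈ 0.707; it is reported as `g_mean` alongside the conventional
  `g_mean_conventional` = √(sensitivity·specificity).

Multi-class reports include per-class one-vs-rest rates plus macro
(unweighted mean) and micro (pooled) aggregates; for single-label data
micro precision = micro sensitivity = accuracy.

## Synthetic data generator

The generator emulates the archive's structure, not its biology: 2 coarse
classes, 8 subtypes, 4 magnification strata, and the archive's class
imbalance (default counts are the published per-cell counts divided by 10,
rounded up — 806 images, malignant ≫ benign). Each subtype is a distinct
texture: Gaussian background noise around a subtype hue plus Poisson-many
elliptical "nuclei" with subtype-specific hue, density and radius.
Magnification scales blob radii proportionally and blurs the two lowest
strata. Default canvas is 460×700 (H×W) so the resize path sees a
realistic aspect ratio. Generation is keyed by (spec, seed) with one
independent stream per (magnification, subtype) cell, giving byte-identical
PNGs across runs.

What passing tests on this data do and do not show: subtype hues are
separated by ≥ 0.3 in RGB, so a nearest-centroid probe on mean colour
already exceeds 90% — models that train to high accuracy here demonstrate
that patchification, tokenization, optimisation and evaluation are wired
correctly, not that they would reach the published accuracies on real
stained tissue, which has stain variability, morphology-dependent signal
and far harder class boundaries. Full-scale replication requires the real
archive and GPU-scale training and is out of scope.

## Numerical choices

* Autodiff core is float32; oracles and metrics compute in float64.
* Convolutions are sums of spatially shifted matmuls (zero padding), exact
  for the 3×3 kernels used; the strided stem is patchify + dense, which is
  algebraically identical to a kernel=stride convolution.
* GELU is the exact erf form. Softmax subtracts the row max.
* Batch norm: momentum 0.99, eps 10⁻³ (inference uses moving statistics);
  layer norm eps 10⁻⁶. Oracle tests set eps = 0 with identity statistics
  so scalar recomputation is exact.
* Glorot-uniform initialisation from a per-build seeded generator; a model
  is fully determined by (config, seed). Dropout (0.1 encoder, 0.5 head by
  default) draws from the same build generator and is disabled in the
  reduced test-scale configurations.
* The training-scale choices used in tests and the acceptance script —
  56×56 inputs (16 patches), embed width 32, 2 blocks, 20 epochs, 100
  images per class — were picked as the smallest sizes at which the
  trainability property is comfortably demonstrated on one CPU core.

## Known limitations

* No stain normalisation, no whole-slide formats, no pretrained weights,
  no GPU kernels; the numpy core is intended for correctness and
  small-scale experiments, not throughput.
* The full-scale accuracy tables of the original study are not reproduced
  here (external archive + GPU training); the package reproduces the
  architecture totals exactly and the protocol/metric arithmetic to
  oracle precision.
* The frozen head width (2 units) for binary tasks follows the parameter
  totals; a 1-unit sigmoid head is available but changes the count.
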