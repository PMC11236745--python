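# Methods

## The model

PL-Net is a U-shaped encoder–decoder for 2D medical image segmentation whose
central idea is *progressive learning* along two axes:

* **Internal progressive learning (steps).** Each stage's encoder–decoder is
  traversed `n_steps` times. Every level owns one conv unit per step on the
  encoder side and one per step on the decoder side, so each traversal uses
  its own weights. Traversal *s* receives traversal *s−1*'s same-scale decoder
  features through **backward skip connections (BSC)**: at every encoder level
  the incoming (pooled) feature is concatenated with the previous traversal's
  decoder output at that scale before the step conv. Successive traversals
  therefore see progressively wider receptive fields. **Forward skip
  connections (FSC)** are the classical same-scale encoder→decoder
  concatenations, consumed by the decoder step convs.

* **External progressive learning (stages).** Two nested sub-networks of
  different depth share blocks: stage 1 stops at the 28² level (depth 4 at the
  default 224² input); stage 2 reuses all stage-1 blocks and adds the 14²
  bottleneck level. Stage 2's first traversal takes its backward features from
  stage 1's final features, so the fine stage starts from the coarse stage's
  solution. Each stage has its own 1×1 pre-activation prediction head.
  Predictions are fused with equal weight: `y = σ(Σ_n y^n)` for binary masks,
  a channelwise softmax of the per-class sums for multi-class. The per-stage
  sigmoid layers are never materialized at inference ("pruned heads") — the
  fusion consumes pre-activations directly.

Blocks are plain conv(3×3) + batch norm + ReLU; downsampling is 2×2 max
pooling; upsampling is a channel-preserving 3×3 stride-2 transposed conv
(+BN+ReLU), one per decoder transition, shared across steps and stages.

### Wiring conventions the reference text leaves open

The published description is ambiguous in three places; the printed parameter
counts were used as the arbiter, fixed once before any training:

1. **First traversal of stage 1 has no backward source.** The backward slot is
   filled with zeros (the concatenation of `x` with a zero block), so every
   traversal's convs have identical shapes. This both realises the
   "self-concatenation" reading of the published merge rule and makes the
   parameter count exactly affine in `n_steps`.
2. **Stage sharing.** Stage 1's blocks are a strict subset of stage 2's; only
   the deepest level (and one fixed 3×3 "bridge" conv at that global
   bottleneck, in the style of bidirectional U-Net bridge blocks) is
   stage-2-exclusive. Separate per-stage networks are incompatible with the
   published counts.
3. **Upsampling operator.** Channel-preserving 3×3 transposed convolution.
   A channel-halving variant undercounts the published budget by >6%; the
   preserving variant lands every printed count within 2% (see below).

### Parameter budget

Counting convention: one conv unit = `9·in·out` kernel weights + `out` biases
+ `2·out` batch-norm scales/shifts; transposed convs likewise; running BN
statistics are buffers and not counted. Under this convention:

| configuration | count | published |
| --- | --- | --- |
| default (Ocs=1, 2 steps) | 14,908,098 (14.91 M) | 15.03 M |
| Ocs=0.5 | 3,730,786 (3.73 M) | 3.77 M |
| 1 step | 10,202,658 (10.20 M) | 10.33 M |
| 3 steps | 19,613,538 (19.61 M) | 19.73 M |

Each extra step adds exactly 4,705,440 scalars (one identically-shaped conv
unit per block), so the step increments are exactly equal; halving the
channel scale quarters the count up to the linear (bias/norm/head) terms
(ratio 0.2503). Whether the published figures include transposed-conv kernels
or norm parameters is not stated; the ±2% agreement is the closest consistent
reading we found, and all four configurations agree simultaneously under it.

## Training procedure

* **Loss.** Soft Dice per stage: `1 − (2Σpt+ε)/(Σp+Σt+ε)` with ε = 1e-6 in
  numerator and denominator (makes empty-vs-empty lossless and keeps the loss
  in [0,1]). Multi-class masks are one-hot encoded and the per-class maps
  share one softmax.
* **Two phases.** Phase 1 optimizes the stage-1 Dice loss through stage-1
  blocks only; phase 2 optimizes the equal-weight *mean* of all stages' Dice
  losses with every parameter trainable (stage 1 is not frozen). Equal
  weights that sum to one keep the recorded total in [0,1] and mirror the
  equal-weight output fusion. The phase boundary defaults to 25% of
  `max_epochs` (the reference schedule gives no split); `phase1_epochs: 0`
  disables the coarse phase, which is also how the "no external progression"
  ablation is expressed — the architecture is unchanged.
* **Optimizer.** Adam, first-moment decay β₁ = 0.9 (the stated "momentum"),
  lr 1e-4, batch 16, ≤200 epochs by default. The Adam moments are reset at
  the phase boundary because the trainable set changes.
* **Early stopping.** "No significant change" is operationalized as: no new
  minimum of the validation loss for `patience` (default 20) epochs; the
  best-on-validation weights are restored. Without a validation set the
  training loss is monitored instead.
* **Determinism.** All randomness flows through `numpy` generators seeded
  from `RunConfig.seed`; two runs with the same seed produce bitwise
  identical loss histories.

### Desk-scale settings

The test suite exercises full training loops on synthetic fixtures at 64²
with Ocs=0.25 and a depth-4 channel plan (32, 64, 128, 256) — below 128² the
fifth level would operate on 4² maps, so the fixture workflows drop it. These
runs use lr 1e-3: the 1e-4 default is the full-dataset setting, while the
fixture checks memorize 8 images inside a 200-epoch budget, for which the
larger step size is the appropriate regime. Problem sizes (8 lesion images
for the memorization check, 50 ring images for the multi-class report, ~10
epochs for the latter) keep every loop in CPU minutes.

## Data pipeline

* Images resize bilinearly, masks nearest-neighbor (anything else corrupts
  labels); intensities live in [0,1]; a sample already at the target size
  passes through bit-identical.
* Gray-world color constancy rescales each RGB channel by
  (mean of channel means)/(channel mean), clipped to [0,1]; it is applied
  only when `color_constancy: true` (dermoscopy-style data) — whether the
  original study applied it beyond dermoscopy is unstated, so the default is
  off. Grayscale input passes through with a warning; a zero-mean channel is
  left unscaled.
* Augmentation: rotation uniform in ±25°, per-axis shifts uniform in ±15%,
  independent 50% horizontal/vertical flips, composed into a single affine
  warp (bilinear + reflect padding for images, nearest + background-0 padding
  for masks) applied identically to image and mask.
* Folder datasets pair `images/` and `masks/` by filename stem
  (case-insensitive extensions png/jpg/jpeg/tif/tiff); {0,255} masks load as
  {0,1}; orphans are reported and skipped. Splits are a seeded shuffle of the
  sorted ids, so membership is reproducible and partitions are exact.

## Synthetic fixtures

The generators are pure functions of (seed, spec) and quantize images to the
8-bit grid so PNG round-trips are lossless.

* `lesion`: one dark blob (ellipse with a low-order Fourier boundary
  perturbation) on a lighter skin-toned background, smooth illumination
  gradient, Gaussian noise, optional dark hair-like Bezier polylines.
* `nuclei`: 5–40 small bright ellipses, possibly touching, on a dark noisy
  background; the mask is their union.
* `ring`: inner disk (label 1) strictly surrounded by an annulus (label 2,
  width ≥ 2.5 px so the surround holds at pixel resolution) with an adjacent
  crescent blob (label 3) — the three-class short-axis cardiac geometry.

What the fixtures do *not* emulate: real acquisition physics, texture
statistics, anatomical variability, annotation noise, class imbalance at
clinical severity. Passing the desk-scale checks therefore demonstrates that
the architecture, losses, schedule and metrics are implemented coherently and
can fit structured data — not that published benchmark scores on dermoscopy,
nuclei or cardiac datasets would be reproduced.

## Evaluation

Accuracy, IoU, Dice, sensitivity and specificity from one-vs-rest confusion
counts. Metrics are computed per image and then averaged (matching ±std
reporting conventions); a pooled mode (counts summed before scoring) is
available by flag. Undefined ratios score 1 when the class is absent from
both maps, else 0. Multi-class reports list every foreground class and their
unweighted mean; the background class is excluded from averages. Repeated-run
reports carry mean and sample standard deviation (ddof=1).

## Known limitations

* Pure-numpy execution: fine at fixture scale, not at 224² dataset scale on
  CPU; there is no GPU path.
* Recursion depths beyond 3 steps and the 3D variant are out of scope.
* The fusion sum runs over all stages (the prose reading of the published
  fusion rule); the alternative that stops before the last stage is available
  via `fuse_through_stage`.
* Checkpoints store weights as `.npz` plus a YAML sidecar of the
  architecture; there is no cross-version migration.
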