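# Methods

`maefew` implements a few-shot deployment framework for pretrained MRI
transformers: self-supervised masked-autoencoder (MAE) pretraining with a
brain-coverage-weighted loss, frozen-encoder linear probing for MRI sequence
classification, and a CNN–transformer fusion segmenter (MAE-FUnet) for skull
stripping and multi-class anatomical segmentation. Everything runs at desk
scale on a synthetic brain phantom with exact ground truth.

## Coverage-weighted MAE pretraining

Each 2D slice is clamped to its volume's [0.1, 99.9] percentile range,
max-min normalized to [0, 1], padded to square and resized to the model
input size. Slices are split into non-overlapping patches (16×16 for the
ViT-Base-sized configuration; 8×8 for the tiny preset), 75% of patches are
masked uniformly at random, and an encoder–decoder transformer reconstructs
the masked patches under a mean-squared-error objective computed on masked
patches only. The reconstruction target is the raw normalized pixels (no
per-patch normalization).

Aggregated MRI cohorts contain many slices with little or no brain tissue
(apex/base slices, cropped fields of view). Each sample's masked-patch MSE
l̃ᵢ is therefore weighted by a monotone increasing function of its brain
coverage αᵢ (the fraction of pixels inside the binary brain mask):

    L = (1/N) Σᵢ wᵢ l̃ᵢ,   wᵢ = f(αᵢ) = w_min + (1 − w_min) αᵢ,  w_min = 0.1

with no renormalization by Σw. The linear f is one admissible monotone
choice; w_min = 0.1 keeps a gradient floor so background statistics are
still learned. By linearity of differentiation the batch gradient is the
same weighted average of per-sample gradients; the test suite verifies this
numerically at 1e-5 relative tolerance.

Positional embeddings are fixed 2D sin-cos; the learning-rate schedule is
constant (AdamW, lr 1e-4, batch 48 in the full-scale configuration; batch 8
for the tiny preset). Whether α should be recomputed after augmentation is
an open choice; `augment` recomputes it from the transformed mask.

## Linear probing (MAE-classify)

The frozen encoder runs without masking; the final-layer-normed CLS
embedding (dimension d) feeds a linear head W ∈ ℝ^{C×d}, b ∈ ℝ^C trained
with cross-entropy, so the trainable parameter count is exactly C(d+1).
Two numerical choices matter at desk scale:

* CLS embeddings concentrate around a large mean direction with small
  per-dimension variance, so features are z-scored with training-set
  statistics before the fit (the analogue of the batch-norm layer commonly
  placed before MAE linear probes); the affine standardization is folded
  back into the returned (W, b), which stays a plain linear map.
* Training is full-batch (tens to hundreds of samples), so the probe uses
  AdamW at lr 1e-3 for 2000 steps rather than the mini-batch 1e-4 used for
  the other stages; with 1e-4 the head cannot reach its optimum in any
  reasonable number of full-batch steps.

Probe evaluation never augments. Augmentation during probe training is off
by default: on the phantom it measurably does not help, and determinism
makes the duplicate-training-set invariance testable. Ties in the argmax
break toward the lowest class index.

## MAE-FUnet

A U-Net backbone (double 3×3 conv + ReLU per stage, 2×2 max pooling,
nearest-neighbor upsampling, channel count doubling from `base_channels`
per stage, depth 4 at full scale / depth 3 for the tiny preset) is fused
with frozen MAE encoder states at depth+1 scales: the bottleneck plus every
decoder stage output. Token states are tapped at encoder layers 1, 3, 6, 9
and 12 (1, 2, 3, 4 for the tiny preset); the deepest tap fuses at the
bottleneck and shallower taps at progressively finer decoder scales,
matching representation depth to spatial scale.

The projection Π_s is a linear channel map d → C_s applied to the patch
tokens (CLS excluded), reshaped to the token grid and bilinearly resized to
the target scale. Fusion strategies, all emitting C_s channels so they are
drop-in interchangeable:

* **concat** — channel concatenation followed by a 1×1 channel-reducing
  convolution. The 1×1 (rather than 3×3) reduction is fixed by the
  published trainable-parameter ladder of the three variants (+2ΣC_s² for
  concat, +4ΣC_s² for attention over add), which our implementation
  reproduces at 36.0/38.8/41.6 M versus the printed 35/38/41 M;
* **add** — element-wise sum with the projected map;
* **attention** — single-head cross-attention with CNN features as queries
  and projected tokens as keys/values, residual-added to the CNN stream.

This yields the strict trainable-parameter ordering add < concat <
attention at any width, and width ordering 32 < 64 < 96 (10.1/38.8/86.2 M
at full scale versus the printed 10/38/84 M). With fusion disabled the same
code path is a plain U-Net; MAE-direct instead feeds final-layer tokens
through conv + 2× upsample blocks with no fusion and has strictly fewer
trainable parameters than any FUnet at matched width.

Training uses the hybrid loss

    L = L_dice + L_focal + L_ce   (unit weights)

with the per-sample soft Dice (ε = 1e-5 in numerator and denominator,
background class included, averaged class-then-sample), focal loss
−α(1−p)^γ log p with γ = 2.0 and α = 0.25 applied uniformly to all classes,
and pixel-wise multi-class cross-entropy. Probabilities are clamped at
1e-12 inside logarithms. The encoder is frozen: its token states are
computed once with gradients disabled and cached; only CNN, fusion and head
parameters are optimized (AdamW, lr 1e-4).

## Few-shot protocols

* **Slice-level (classification)** — n slices per sequence sampled without
  replacement from a shuffled pool of training volumes; train and test are
  disjoint at the volume level. The pool spans up to three volumes per
  sequence, mirroring slice sourcing from several patients/cohorts. The
  pipeline keeps slices with at least 10% brain coverage, because sequence
  contrast is a property of brain tissue.
* **Sparse stride (skull stripping)** — one training volume per sequence;
  keep slices at 1-based multiples of k (0-based indices k−1, 2k−1, …), so
  a 224-slice axis yields exactly floor(224/k) = 56, 44, 37, 32, 28, 24, 22
  training slices for k = 4…10. A stride larger than the axis produces an
  empty selection with a warning. When stride sampling meets tri-axial
  remapping, the stride applies independently per axis after remapping
  (configurable).
* **Volume-level (anatomy)** — n whole volumes for training; each volume is
  resampled to isotropic voxels (axis lengths scale by the voxel-size
  ratio, labels nearest-neighbor), remapped to 2D slices along the
  sagittal, coronal and axial axes, and slices with label foreground below
  `min_foreground` (default 1 pixel) are dropped.

All sampling is reproducible under a fixed seed; per-stage seeds derive
from the master seed by a counter-based hash (values below 2³¹).

## Metrics

One-vs-rest confusion counts give accuracy, micro precision/recall, and
micro/macro/weighted F1 exactly as in the standard formulations;
zero-denominator classes contribute 0 with a warning. Segmentation uses
per-class Dice = 2|P∩G|/(|P|+|G|) and IoU = |P∩G|/|P∪G|; when prediction
and truth are both empty for a class, both scores are defined as 1.0 and
flagged, which keeps anatomy classes absent from a slice from producing
NaNs. Class means exclude the background by default. Sweep stability is
summarized by the arithmetic mean and the **population** standard deviation
(divide by n): on the published seven-value stride sweep of the fusion
model, only the population convention rounds to the printed STD cells
(0.045/0.023; the sample convention gives 0.049/0.025).

## The phantom: what it emulates and what it does not

The generator builds concentric-ellipsoid subjects — skull ring (non-brain),
cortex shell, white-matter interior, ventricles, and two small off-center
blobs standing in for small structures — rendered under four sequence
contrasts (T1/T2/FLAIR/PD-like) from per-tissue intensity LUTs, with ±3%
per-subject jitter of the ellipsoid axes (adult head size variation after
field-of-view normalization is of this order), additive Gaussian noise
(sd 0.02) and clipping to [0, 1]. Apex/base slices naturally provide empty
and partial brain coverage, so the coverage-weighted loss is exercised. At
noise 0 every tissue renders exactly at its LUT value, so a nearest-LUT
classifier is a perfect oracle for sequence identity.

The phantom has no texture, no bias field, no pathology, no partial-volume
effects and no registration errors. Passing tests therefore demonstrate
that the implementation is correct and that the pipeline behaves as designed
under controlled conditions — not that the tiny encoder would match the
published full-scale accuracy on clinical data.

## Desk-scale problem sizes

The test suite and worked examples use the tiny preset (64×64 slices, 8×8
patches, 4 encoder layers, width 64; U-Net base 16, depth 3): pretraining
on 320 slices from 8 phantom subjects for 25 epochs, probing with 10 slices
per sequence from a disjoint 6-subject cohort, and skull stripping from
stride-7 sampling (about 20 training slices). These sizes were chosen so a
single end-to-end run completes in minutes on one CPU core while leaving
every mechanism (masking, weighting, fusion, few-shot splits) fully
exercised.

## Known limitations

* The neural-network layer is a small numpy autograd engine written for
  this package; it is single-threaded apart from BLAS matmuls and is not
  intended for GPU-scale training, although the `vitbase` configuration is
  implemented and correct.
* The Eq.-style decomposition of the per-sample loss into brain and
  non-brain parts is interpretive; the package computes only l̃ᵢ and wᵢ.
* The attention fusion head count is fixed at one; the printed parameter
  ladder does not constrain it further.
* Whether clamping percentiles should be slice-wise or volume-wise for 3D
  inputs is not externally fixed; the default is volume-wise before
  slicing, configurable by normalizing slices individually.
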