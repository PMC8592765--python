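# Methods

## Problem and model family

`dermseg` segments melanoma-suspect lesions in RGB dermoscopic images: each
pixel is classified lesion (1) or surrounding skin (0).  The architectures
are encoder-decoder ("transcoder") networks with skip connections:

* **U-Net** — a five-level contracting path (channels doubling per level)
  and an expanding path using kernel-2 stride-2 transposed convolutions,
  with the same-resolution encoder feature concatenated at every step.
* **UNet++ (dense)** — a triangular grid of decoder nodes X(i, j), row *i*
  at the resolution of encoder level *i*, column *j* counting refinement
  steps.  Node X(i, j) receives *all* same-row predecessors X(i, 0..j−1)
  plus the 2×-upsampled X(i+1, j−1), concatenated channel-wise.
* **Pruned ("improved") UNet++** — the package's headline decoder: the
  dense same-row fan-in is cut to the immediate predecessor X(i, j−1) only.
  This keeps the deep-to-shallow gradient path while shrinking every node's
  input, hence the parameter count and compute, and avoids flooding the
  upsampling path with redundant features.

Encoders produce a five-level feature pyramid at strides 2–32 of the input:

| encoder | channels at strides (2, 4, 8, 16, 32) |
|---|---|
| `plain` (base width w) | w, 2w, 4w, 8w, 16w |
| `efficientnet_b0` | 16, 24, 40, 112, 320 (MBConv stages with squeeze-and-excitation) |
| `xception` | 64, 128, 256, 728, 2048 (separable-conv blocks with residual shortcuts) |

The pinned **EfficientUNet++** configuration is: B0 encoder, pruned
decoder, decoder widths (16, 32, 64, 128, 256) shallow→deep, batch norm on,
ReLU, single head, dropout rate 0.2, 3 input / 1 output channels.  Decoder
nodes are `[conv3×3 → BN → activation] × 2` + spatial dropout; grid
upsampling is bilinear ×2; the 1×1-conv head sits at X(0, 4) and its logits
are bilinearly upsampled from stride 2 to input resolution.  The sigmoid is
applied only at prediction time.  Deep supervision (heads at X(0, 1..4),
losses averaged) is available behind a flag and off by default: it belongs
to the original nested-decoder design but is not part of the default
training protocol here.

B0 keeps its canonical structure but honours the network-wide activation
switch (relu/prelu/gelu/swish/mish) used by the activation ablation; the
swish-native variant is selected by `activation="swish"`.

## Objective and metrics

Training minimises `(1 − α)·BCE + α·DiceLoss` on sigmoid probabilities,
α ∈ [0, 1], default 0.5.  BCE is the canonical mean binary cross-entropy
with probabilities clamped to [1e-7, 1 − 1e-7]; the Dice loss is the global
soft form `1 − (2 Σ p·y + ε)/(Σ p + Σ y + ε)`, ε = 1e-6.  The combination
counters foreground/background imbalance, where plain BCE is dominated by
skin pixels.  Both terms are implemented in their canonical forms — global
soft Dice over the raster (not a per-pixel sum of ratios) and standard
signed BCE — as these are the quantities the overlap/cross-entropy
descriptions actually define.

Evaluation binarises probabilities at a threshold (default 0.5, strict
greater, ties to background), tallies pixel TP/FP/FN/TN, and reports
accuracy, Dice = 2TP/(2TP+FP+FN) and IoU = TP/(TP+FP+FN).  Dice and IoU
obey Dice = 2·IoU/(1+IoU) exactly, so Dice ≥ IoU always — any report of
IoU exceeding Dice for the same run cannot arise from these definitions,
and this package makes no attempt to reproduce such figures.  Images
where prediction and reference are both empty are skipped with a warning at
dataset level (and raise at single-image level); the dataset summary is the
unweighted mean of per-image metrics, with pooled-count aggregation behind
a flag.

## Preprocessing and augmentation

Normalisation chain: (1) gray-world colour constancy — each channel scaled
by (mean of channel means)/(channel mean), output clipped to [0, 255] —
correcting illumination casts, (2) resize/augmentation, (3) subtraction of
the ImageNet channel means (123.68, 116.779, 103.939) on the 0–255 scale,
(4) division by 255.  Colour constancy deliberately comes first; placing
mean subtraction after augmentation is this package's convention so that
photometric jitter acts on the raw intensity scale.

The seven-operation stochastic augmentation policy: random scale
(0.9–1.1), rotation (±30°), horizontal/vertical flips (p = 0.5 each),
brightness/contrast shifts (±20%), CLAHE (p = 0.25), random crop, HSV
shifts (±10 units).  The operation set is fixed; the magnitudes are this
package's defaults, chosen at conventional dermoscopy-augmentation values,
and all are configurable.
Geometric operations are applied with identical parameters to image and
mask — nearest-neighbour resampling keeps the mask binary — while
photometric operations touch the image only.  Random crop is the one
augmentation also applied to validation (with a fixed per-epoch seed so
curves are comparable across runs).  Masks at ingest are binarised at
value > 127, tolerating anti-aliased or JPEG-fringed boundaries.

## Training protocol

Adam with default moments (β₁ 0.9, β₂ 0.999, ε 1e-8), learning rate 1e-4,
batch size 2, no schedule, no weight decay.  The 1e-4 default suits
fine-tuning pretrained encoders; from-scratch runs use 1e-3, the rate of
the activation-ablation protocol (see "Sanity experiments").  Early stopping is realised retrospectively:
validation loss and metrics are recorded every epoch and the returned
checkpoint is the weights at the epoch optimising `checkpoint_metric`
(min val_loss by default, max val_dice optional).  Training is bitwise
deterministic for a fixed seed on one device: shuffling, augmentation,
dropout and validation-crop draws all derive from the config seed.

## Numerical engine

No deep-learning framework is used: the package carries a small
reverse-mode autodiff engine on NumPy (`dermseg.nn`) whose op set is
exactly what these networks need.  Convolution is im2col + one BLAS matmul,
with dedicated fast paths for pointwise (1×1) and depthwise kernels; the
input gradient is reassembled by a kernel-offset loop rather than a
scatter.  Every backward pass is verified against central finite
differences in float64.  Forward math is float32; weight init is He-uniform
for convolutions (zero biases) and ones/zeros for batch-norm; BN uses
momentum 0.1 and ε 1e-5, with running statistics (buffers, not trainable)
used in eval mode.  Sigmoid inputs are clipped at ±60 to avoid float32
overflow where the function is saturated anyway.

## Synthetic data generator

`dermseg.synthetic` draws dermoscopy-like pairs: a skin-tone background
(red-dominant base colour) with Gaussian texture noise and an optional
linear illumination gradient; a darker, star-convex lesion whose boundary
is an ellipse radially modulated by a low-order harmonic series scaled by
`boundary_irregularity`; optional thin dark hair arcs drawn on the image
only.  The mask is the exact blob indicator, and rejection sampling
guarantees the lesion area fraction lies in `lesion_area_range` (default
10–35% of the image, a typical dermoscopic framing).  Defaults: 64×64
canvas, contrast 0.45, irregularity 0.15, hair probability 0.3,
illumination gradient 0.15, noise SD 5 (0–255 scale).  Per-sample RNG
substreams derive from the dataset seed by counter, so generation is
reproducible and order-independent.  The generator emulates the gross
photometric structure of dermoscopy (dark irregular lesion, hair occlusion,
uneven illumination) but not its full variability — no multi-lesion
images, rulers, gel bubbles, or realistic pigment networks — so passing
the sanity experiments demonstrates that the pipeline can learn and
segment, not that it reaches any particular accuracy on real clinical data.

## Sanity experiments and problem sizes

`dermseg.experiments.learning_sanity` trains the pinned EfficientUNet++
from random init on generated data and scores held-out Dice/IoU/accuracy.
The reference problem size is 100 training / 20 validation / 40 held-out
64×64 images, 8 epochs, batch 2 — chosen so the experiment completes in a
few minutes on a single CPU core while passing its Dice ≥ 0.90 bar with a
wide margin (observed ≥ 0.96 across seeds).  From-scratch runs use the
ablation-protocol rate 1e-3 and disable dropout (a scarce-real-data
regulariser, irrelevant to a generated-data capacity check).
`overfit_one_batch` memorises a single two-image batch for 200 steps at
lr 1e-2 — an aggressive rate appropriate for a capacity smoke test.

## Parameter accounting

`count_trainable_parameters` sums elements over all trainable tensors
(conv weights and biases, batch-norm scale/shift, PReLU slopes), excluding
BN running statistics.  At the pinned configuration the package's
EfficientUNet++ has 4,651,149 trainable parameters (3,595,388 in the B0
trunk) and XceptionUNet++ 25,724,817.  Counts reported elsewhere for
models of the same name (6,653,549 and 38,370,009) depend on
framework-specific implementation details that were never published: no
shared decoder-width tuple can reconcile both integers with any decoder in
this family (the implied decoder sizes differ by ~14M parameters at equal
widths), so the package reports its own true counts and asserts instead
the structural properties
that are implementation-independent — pruned < dense at equal spec, counts
invariant to input size, and hand-computable layer counts.

## Known limitations

* CPU-only, float32, single-device; no mixed precision or distribution.
* ImageNet-pretrained encoder weights are not downloaded; `build_model`
  initialises randomly and external state dicts can be loaded explicitly.
* The generator's simplicity means headline benchmark scores on real
  PH2/ISIC data are out of scope; desk-scale evidence is architectural
  contracts, exact metric algebra, and learnability on synthetic data.
* PReLU uses a single shared learnable slope per layer.
* Xception follows the canonical 14-module layout but with BN placed after
  each depthwise and pointwise convolution; parameter counts therefore
  differ slightly from keras' SeparableConv2D convention.
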