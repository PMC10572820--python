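# Methods

## Problem and pipeline

Glomerulus segmentation in whole-slide kidney images (WSIs) is a binary
semantic-segmentation problem: given an RGB patch of PAS-stained tissue,
predict for every pixel whether it belongs to a glomerulus. WSIs are far too
large for direct network input, so the pipeline runs: decode RLE ground
truth → tile slides into fixed-size patches → label patches by glomerulus
presence → balance the classes by augmenting the minority patches → train an
encoder–decoder network → evaluate with pixel-wise confusion-matrix metrics.
Every stage is a separate module with a plain-array interface.

## RLE codec

Masks are serialized as alternating 1-based `start length` integer pairs
over the linearized pixel grid. The linearization is **column-major** (down
the first column, then right), the convention of the Kaggle segmentation
ecosystem the data dialect comes from; it is held in a single module
constant, so a row-major dialect is a one-line change. The encoder always
emits the canonical form — strictly increasing starts, adjacent runs merged,
the empty mask as the empty string (never `"0 0"`) — while the decoder
accepts any valid run list, including unsorted or overlapping runs. Decoding
is O(total run length) via flat-array slicing; encoding finds run boundaries
from the sign changes of a first difference. Correctness is pinned by a
brute-force per-pixel membership oracle and by 200-case round-trip tests.

## Tiling

Tiles come from a non-overlapping grid anchored at the slide's top-left
corner, stride equal to the tile size (512 by default), windows half-open in
0-based (row, col) coordinates. Two border policies are exposed because
real-world slide dimensions are rarely divisible by the tile size and the
right choice is application-dependent: `pad-zero` (default) zero-pads
partial bottom/right tiles, giving ⌈H/T⌉·⌈W/T⌉ tiles; `drop` discards them,
giving ⌊H/T⌋·⌊W/T⌋. A tile is labeled *glomerulus* iff its mask crop has at
least one positive pixel. The train/test split shuffles with a seeded
generator at tile level by default; a `group_by_slide` option keeps all
tiles of a slide on one side of the split and is recommended whenever more
than one slide is available, since tiles of one slide share appearance and a
per-tile split leaks that appearance into the test set.

## Balancing augmentation

Tiled WSI datasets are dominated by background: at full scale, 13,441
glomerulus tiles against 37,045 background tiles. Balancing keeps every
original glomerulus tile and adds `copies_per_tile` augmented copies (2 by
default, tripling the class: 13,441 → 40,323), each produced by one
technique drawn with a seeded generator from {horizontal flip, horizontal
shift, vertical shift}. Shift offsets are uniform in [1, 0.1·T] pixels with
a random sign; the vacated band is filled with black in the image and 0 in
the mask, and the label is recomputed because a shift can evict every
positive pixel. Image and mask always receive the identical transform
(verified with an image whose channels encode pixel coordinates).
Augmentation is a training-set operation only; evaluation tiles are never
augmented.

## Network

Encoder block *k* (of 5) is `3×3 conv (identity activation) → batch norm →
3×3 conv (ReLU) → 2×2 max pool`, with the filter schedule F1(k) = 72·2^(k−1)
for the first convolution and F2(k) = 144·2^(k−1) for the second. All
convolutions are stride-1 with same-padding, so spatial size changes only at
pooling/upsampling; a 512×512 input contracts 512→256→128→64→32→16 and the
post-pool bottleneck holds 2304 channels. This two-width-per-block schedule
is the minimal one consistent with the published narration of the
architecture, whose prose attributes the channel growth (72 → 144 at the
first downsampling) to the pooling layer — an operation that cannot change
channel count; placing the growth in the second convolution of each block
reproduces every quoted width (72, 144, 2304) exactly. Decoder block *j* is
`2× nearest-neighbor upsample → concatenate with the pre-pool activation of
the mirror encoder block → 3×3 conv (ReLU)`, widths halving per level
(1152, 576, 288, 144); the topmost decoder convolution is itself the output
layer (1 channel, sigmoid) — the published total of 15 convolutions leaves
no room for a separate 1×1 head. The same constructor at depth 4 yields the
classic 12-convolution hourglass used as the unmodified baseline for
layer-count comparison.

Two knobs make the architecture testable at desk scale without changing its
shape: `width_scale` multiplies every filter count (rounded, clamped at 1)
and `tile_size` sets the input side (must be divisible by 2^depth). Layer
inventory and the feature-map trace are computed from the constructed graph,
not from the specification, so the tests verify what was actually built;
the inventory counts only the five structural kinds (activations are fused
into their convolutions).

## Network engine

No deep-learning framework is part of the dependency set; the package
carries a compact numpy engine implementing exactly the needed layer
vocabulary with hand-derived backward passes. Convolution is an im2col
matrix product (BLAS does the work); its input gradient applies the same
kernel machinery to the 180°-rotated, input/output-transposed filter bank,
which is the exact adjoint for stride-1 same-padding and avoids scatter-add.
Max pooling stores per-window argmaxes for exact gradient routing. Batch
normalization uses batch statistics in training (running averages, keep
fraction 0.9, ε = 1e−5, for inference) with the standard three-term input
gradient. The sigmoid output is fused with the binary cross-entropy loss, so
the entry gradient of backpropagation is (p − y)/n — numerically exact even
at saturated probabilities. The whole chain is verified against float64
central differences (agreement to ~1e−7 relative).

Weight init is He-normal for ReLU convolutions, Glorot-normal otherwise,
from a single seeded generator per network. Optimizers: Adam (lr 1e−3, β₁
0.9, β₂ 0.999), SGD (lr 0.01), RMSprop (lr 1e−3, ρ 0.9), Adadelta (lr 1.0,
ρ 0.95 — the classic formulation where the accumulated-update ratio sets the
step size). Learning rates are these per-optimizer standards unless
overridden, and are recorded in the run log.

## Training and evaluation

The loss is mean per-pixel binary cross-entropy — the standard choice for
sigmoid-output binary segmentation (the reference description of the
training setup does not name one). Each epoch shuffles with the run seed,
records training loss, validation loss (natural units; a ×100 column is
available since some reports print loss on a 0–100 scale) and validation
pixel accuracy in percent; the weights of the best validation-loss epoch are
restored at the end. Runs are deterministic under a fixed seed on fixed
hardware/thread settings.

Evaluation derives accuracy, precision, recall and F1 (percent) from
pixel-wise TP/FP/FN/TN. F1 is the harmonic mean of precision and recall and
coincides exactly with the Dice coefficient of the two masks; the tests
check this identity to 1e−12 on random pairs. Zero-denominator metrics
(e.g. no predicted positives) report 0 with a `RuntimeWarning` — note that
a tile whose ground truth and prediction are both empty therefore scores 0
precision/recall despite being a perfect prediction, so aggregate reports
over many background tiles should pool confusion counts (confusions are
additive) rather than average per-image metrics. The per-image-then-average
aggregation is nevertheless what `evaluate` reports, matching the per-image
reporting convention of the reference analysis; both views are available.
The sweep helper trains one fresh network per configuration and tabulates
`optimizer, batch_size, epochs, val_loss, val_accuracy`.

## Synthetic data

The generator emulates what the pipeline needs from a PAS-stained WSI and
nothing more: a pink-ish background with smoothed low-frequency noise plus
fine speckle, and non-overlapping elliptical structures with a darker
boundary ring (outer 30% of the normalized radius) and a mottled, more
saturated interior — the simplest appearance exhibiting the ring-like
glomerular morphology. Placement is rejection sampling on bounding circles
with a 4 px margin, capped at 100 retries per structure. The mask is the
union of ellipse interiors and the returned RLE is its encoding, which ties
the generator to the codec in tests. Defaults (1024×1024 slides, 8
structures, semi-axes 20–60 px, texture amplitude 10 intensity units) give
glomerulus-to-slide proportions loosely comparable to kidney cortex at the
tile scale the tests use.

What passing tests show — and do not show: the synthetic classes are
color-separable by construction, so end-to-end results (F1 ≈ 99% on held-out
synthetic tiles) demonstrate that the codec, tiling, augmentation, network
and training loop are wired correctly and that the network can learn a
segmentation, not that it would reach any particular score on real tissue,
which has stain variation, sclerotic subtypes, tubular look-alikes and
scanner artifacts the generator deliberately omits.

## Problem sizes

The test suite and the reference-quantity script run everything at desk
scale as the package's own configuration choices: architecture checks build
the canonical graph (depth 5, base 72, tile 512) but never run a 512×512
forward pass; training properties use the 1/8-width network on 64×64 tiles
(40 + 40 generated tiles, 3:1 split, balanced to 114 training images, Adam,
batch 8, 10 epochs); the augmentation arithmetic check runs the real
13,441-tile balancing at 64×64. The full-scale published performance values
require the external 20-WSI dataset and GPU-scale training and are out of
scope here.

## Known limitations

- The engine is CPU/numpy: a full-width 512×512 forward pass is memory- and
  time-prohibitive; the canonical network is built and introspected but
  trained only in scaled form.
- Batch normalization running statistics warm up over ~tens of batches;
  very short runs validate with partially stale statistics.
- Nearest-neighbor upsampling and the single decoder convolution per block
  follow the reference architecture; transposed convolutions, pretrained
  encoders and multi-class output are deliberately absent.
- Pyramidal WSI formats (SVS/NDPI) are not read; inputs are plain
  TIFF/PNG arrays.
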