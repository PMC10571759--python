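# Methods

## Problem and model

The package segments actinic-keratosis (AK) lesions in wide-field clinical
photographs: a binary per-pixel labelling task in which the foreground has
low contrast, diffuse boundaries, and is surrounded by visually similar
benign structures. The segmentation network is a four-level encoder-decoder
(U-Net) with three modifications that target exactly these difficulties:

1. **VGG16-style encoder.** Each of the four encoder blocks stacks 3×3
   convolutions + ReLU (widths `base_filters × 2^(l−1)`, capped at 512;
   default block depths 2, 2, 3, 3 as in VGG16) with 2×2 max pooling
   between blocks, so the four skip maps sit at full, 1/2, 1/4 and 1/8
   resolution. Encoder kernels can be initialised from a locally supplied
   VGG16 weight file; by default (and in every test) they are seeded-random.
   Nothing in the package downloads weights.
2. **convLSTM skip fusion.** At each of the three skip levels, the encoder
   map and the transposed-convolution-upsampled decoder map are channel
   concatenated, split into an `n × m` patch grid (`h_p = h_l/n`,
   `w_p = w_l/m`, exact division required and validated at configuration
   time), and a convolutional LSTM with peephole connections scans the
   patches in row-major order from an all-zero initial state. The output
   gate's peephole reads the **new** cell state `c_t` (not `c_{t−1}`); the
   implementation follows that equation literally and the test suite pins
   it against an independent scalar-loop oracle. The per-step hidden maps
   are reassembled at their grid positions into the fused skip feature.
3. **Batch-normalised decoder.** Every decoder convolution is followed by
   batch normalisation (before ReLU), concentrating the regularisation on
   the reconstruction path.

A 1×1 convolution with sigmoid produces per-pixel foreground
probabilities; binarisation uses threshold 0.5 by default (configurable).
Setting `skip_fusion="concat"` removes the recurrence entirely and yields
the plain-concatenation baseline U-Net with otherwise identical topology,
which is how the architectural comparison in the tests is made.

### Design choices where the design was open

- **Patch grid** (4, 4) by default: it divides every skip resolution of a
  256-px input and yields a 16-step scan, long enough for the recurrence
  to integrate context. Test-sized models use (2, 2).
- **Scan order**: single-direction row-major raster. The order is part of
  the model configuration so experiments are reproducible; no
  bidirectional pass.
- **Hidden width** `K`: half the concatenated width at each level (= the
  encoder width there), mirroring how a decoder stage halves channels.
- **Fusion output replaces concatenation**: the reassembled hidden maps
  feed the decoder convolutions directly, without re-concatenating the
  raw skip tensor. The recurrence already receives the full concatenation
  as input, so re-appending it would only restore the semantic gap the
  fusion is meant to close.
- **Initial state**: zeros. **Forget-gate bias** initialised to 1 so the
  cell starts by remembering — a standard stabilisation for short scans.
- **Upsampling**: transposed convolution, kernel 2, stride 2.

## Numerical core

No deep-learning framework is used: `akunet.nn` is a reverse-mode
automatic-differentiation engine on float32 NumPy arrays (NHWC layout).
Convolutions are stride-1/same-padding im2col + BLAS matmul; the input
gradient is a convolution with the spatially flipped, channel-transposed
kernel, and the im2col matrix from the forward pass is cached for the
weight gradient. Max pooling records argmax indices; batch normalisation
uses the standard closed-form batch-statistics gradient and running
moments (momentum 0.1, eps 1e-5) for inference. Backpropagation through
the patch scan falls out of the graph (truncation-free BPTT over the
n·m steps). Every operator is verified against central-difference
numerical gradients at 1e-3 tolerance in float32.

Training minimises pixel-averaged binary cross-entropy with probabilities
clipped to [1e-7, 1−1e-7] (clipped pixels get zero gradient). The
optimiser is Adam with *decoupled* weight decay (lr 1e-3, decay 1e-6,
betas 0.9/0.999) — the common reading of "weight decay" alongside Adam.
The epoch budget is configurable (default 100 epochs, batch 32); model
selection keeps the best validation-Dice epoch, with no early stopping.
Given a seed, data order, initialisation and therefore the entire run are
deterministic on a fixed BLAS.

## Crop pipeline and splits

Photographs are rescaled 0.5× (images bilinear with anti-aliasing, masks
nearest-neighbour so they stay binary, px/mm halved), one box per
connected annotated region is centred on the region centroid (nearest
region pixel when the centroid falls outside; boxes clamped into bounds
rather than padded — zero padding is reserved for inference), and
`n_offsets` translation boxes per lesion are drawn with seeded uniform
shifts in [−side/4, +side/4]², resampled (bounded retries) until the box
still intersects its source region. Crops are then rescaled 0.5× again to
the network input side. Defaults: 512-px boxes → 256-px inputs;
`n_offsets=8`, of the order implied by a ~29:1 crop-to-photograph ratio
in the reference workflow. Splits assign whole patients to
train/validation/test; the manifest is serialised and leakage (a patient
in two splits) is asserted at every use. Evaluation crops are
lesion-centred only, never translation-augmented.

## Wide-field inference

The full photograph is zero-padded (in normalised intensity space) to the
smallest frame that a grid of tile-side tiles with stride
`tile − overlap` covers exactly, with the padding split as evenly as
possible (odd pixel to bottom/right; the aggregated output is invariant
to that choice). Default overlap is 0 — pure mosaicking; a nonzero
overlap averages overlapping tile predictions uniformly, as standard seam
suppression. After aggregation the padding is removed, so output and
input sizes match exactly. An optional minimum-component-area filter
(default 0 px, i.e. off) removes speckle regions after thresholding.

## Evaluation metrics

Dice and IoU are pixel-exact overlap scores (both defined as 1.0 for two
empty masks, and related by the identity Dice = 2·IoU/(1+IoU), asserted
property-wise). The region-tolerant scores decompose the ground truth
into connected components (8-connectivity by default — annotation strokes
frequently touch diagonally): a component counts as detected if the
prediction shares ≥1 pixel with it; aRec is the detected fraction, aPrec
the fraction of predicted area inside annotated regions, aF1 their
harmonic mean (0 when both rates are 0). Undefined cases (aRec with no
annotated regions, aPrec with an empty prediction) are NaN and excluded
from aggregate means, whose exclusion counts are reported, so batch
averages never divide by zero. Aggregation over a test set is the
unweighted mean of per-item metrics where defined.

## Synthetic data

The generator emulates the features that make AK segmentation hard, at a
configurable scale (default 5 px/mm):

- background: per-patient base skin tone, multi-octave smooth noise,
  faint per-channel mottling, mild vignette;
- lesions: rotated super-ellipses (exponent 1.5–3, diameters 2–20 mm)
  whose reddish-brown colour shift has a luminance magnitude equal to the
  sampled contrast (default range 0.15–0.35) and whose edges are Gaussian
  blurred (1.5–4 px); the ground-truth mask is the *pre-blur* support,
  mirroring rough clinical annotations;
- distractors that must not be segmented: dark anti-aliased Bézier hair
  strokes and sharp high-contrast discs (benign-lesion confusers), both
  constructed to avoid lesion pixels.

What it does **not** model: specular highlights, perspective and pose
variation, anatomical structures (eyes, lips, nostrils), camera noise and
compression, or truly confluent plaque fields. Passing tests therefore
demonstrate that the implementation learns and evaluates correctly on a
low-contrast, distractor-rich task of the right geometry — not clinical
performance.

## Problem sizes used by the test suite

The behavioural tests run a scaled-down study chosen to keep the whole
suite practical on one CPU: 7 patients × 2 scenes of 256² px, patient
split 0.7/0.15/0.15, two-stage 0.5× crops to 64-px inputs (~230 training
crops), and a tiny model (base_filters 8, one convolution per encoder
block, grid 2×2) trained 20 epochs at batch 16. Under those conditions
the recurrent-skip model reaches held-out Dice ≈ 0.92 and the
plain-concatenation baseline ≈ 0.90 (ordering stable across seeds and
BLAS threading), and both comfortably exceed the best global intensity
threshold — the architectural ordering of the full-scale study, recovered
as a property.

## Known limitations

- Single-direction scan only; no bidirectional or multi-scale recurrence.
- Convolutions support stride 1 and odd kernels (1, 3) — all the model
  needs, but not a general framework.
- ImageNet-pretrained encoder initialisation is supported only from a
  local weight file; results shown here use random initialisation.
- No photometric augmentation (flips, colour jitter): the crop pipeline
  implements translation boxes only.
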