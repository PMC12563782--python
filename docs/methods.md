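# Methods

## Problem setting

Two vision tasks on RGB images of skinned fish fillets moving on a
conveyor: (i) partition the fillet into belly, loin and back — the
boundaries follow tissue texture and colour, not geometry — and
(ii) find and delineate small surface defects of two kinds, pale fat
deposits and dark-red bruises.  Defects are the hard part: they are a
few pixels across, randomly placed, and close in appearance to normal
tissue, so they defeat both coarse detectors and full-frame dense
segmentation run at practical resolutions.

## Models

### Segmentation: U-Net with convolutional block attention

The segmenter is a standard U-shaped encoder–decoder.  Each encoder
stage applies two 3×3 convolutions (batch-normalized, rectified) and a
2×2 max-pool; channels double and resolution halves per stage, so the
default (first stage 64 channels, depth 4) bottoms out at a 1024-channel
bottleneck at 1/16 resolution.  The decoder mirrors the encoder with
2×2 transposed convolutions, concatenating the same-resolution encoder
feature before each convolution pair; a 1×1 convolution maps to class
logits.  With same-padding convolutions the skip connection needs no
cropping; equal shapes are asserted instead.

The attention variant inserts a CBAM block after each encoder stage and
the bottleneck.  Channel attention pools the feature map globally by
mean and by max, passes both C-vectors through one shared two-layer
perceptron (C → C/r → C, r = 16), sums, and squashes with the logistic
function; spatial attention stacks the channel-wise mean and max maps
and applies a single 7×7 convolution, logistic-squashed.  The input is
multiplied by the channel gate, then by the spatial gate.  Placement is
encoder-side; a config flag can also enable decoder-side blocks, which
we leave off by default since the encoder is where features are
selected.  One network definition serves three heads: background
removal (2 classes), part segmentation (4), defect-crop segmentation (3).

Training uses Adam (learning rate 10⁻³, batch 16) with a loss of
pixel-wise cross-entropy plus soft Dice in equal weight — cross-entropy
alone under-weights thin boundary bands, Dice alone is unstable early.
Online augmentation redraws per sample and epoch: brightness and
contrast ±20 %, hue ±10 % and saturation ±20 % (in HSV, the conventional
reading of percentage jitter), rotation ±15°, scaling 80–120 %,
horizontal flip with probability ½; draws are uniform within the stated
ranges.  Geometry is applied identically to image (bilinear), mask
(nearest-neighbour — labels must never blend) and boxes (transform
corners, re-tighten, clip, drop below 1 px²).

### Detection: single-stage detector with a P2 head

The detector is CSP-style: a Focus stem (space-to-depth slicing of pixel
parities, 3→12 channels, then convolution), C3 cross-stage-partial
blocks, SPPF pooling at the bottom, and an FPN (top-down) plus PAN
(bottom-up) neck.  Beyond the usual P3/P4/P5 heads at strides 8/16/32,
the top-down path continues one level further: its upsampled output is
concatenated with the backbone's stride-4 map and, after a C3 block,
feeds a fourth head at stride 4 — 160×160 cells at 640-px input.  The
bottom-up path re-descends from there, so the P2 features also inform
the coarser heads.  Disabling P2 (config flag) reproduces the plain
three-head layout for ablations.

Decoding follows the v5-style parameterisation per anchor cell
(3 anchors per level): center = (cell + 2σ(t_xy) − 0.5)·stride,
size = anchor·(2σ(t_wh))², confidence = σ(obj)·σ(class), followed by
class-wise greedy NMS (IoU 0.45, confidence 0.25 by default, both
exposed).  Retention is strictly above threshold, so an all-zero
(bias-free) grid, which scores exactly σ(0)² = 0.25 everywhere, emits
nothing.

Anchors default to k-means over the training set's box sizes (12
clusters under an aligned-IoU distance, assigned to levels by ascending
area), with scaled v5-style defaults when no data is given.

**Target assignment.**  Ground-truth boxes match anchors by the usual
width/height-ratio rule (max ratio < 4) in the box's own cell plus the
two nearest neighbour cells — but only at pyramid levels whose stride
the box actually spans (box size ≥ 0.75 × stride).  Without the stride
condition, sub-stride objects train the coarse heads to fire confident
boxes they cannot localize; at evaluation those near-misses outrank
genuine fine-level detections and flood the precision–recall curve with
false positives (we measured ≈18 such false positives per image on
synthetic data before adding the condition).  Loss is complete-IoU for
matched boxes (weight 0.2 — heavier than the ecosystem's 0.05 because
tiny boxes are localization-limited), binary cross-entropy objectness
with the clipped CIoU as soft target (per-level balance 4/1/0.25/0.06),
and binary cross-entropy over classes (weight 0.5).

Training uses Adam at 3·10⁻³ with cosine decay to a 0.1 floor, batch 8.
Mosaic augmentation (four images spliced at a random centre, boxes
transformed and clipped) runs with probability 1 for the first 75 % of
epochs and is then switched off, the ecosystem's close-mosaic
convention: validation frames are never mosaic-distorted, and the final
epochs consolidate on native object scales.  Images enter the network
by plain (non-letterbox) resize; sources are square.

### Two-stage fusion

Detection boxes are padded by 15 % per side (the crop segmenter needs
context beyond the tight box to find the boundary), clipped, cropped,
resized bicubically to 64×64 (divisible by 2^depth for depth ≤ 6), and
segmented by the 3-class U-Net; crop masks return by nearest-neighbour
resize into a full-frame raster.  Where padded boxes overlap with
different nonzero labels the higher-confidence box wins; background
never overwrites a nonzero label.  Images with no detections yield an
all-zero mask.  Because defects cover a few percent of the frame, the
crops' total area — and hence the dense-segmentation cost — is far below
a full-frame pass; the suite asserts the throughput ordering, not a
hardware-dependent ratio.

## Evaluation

Detection: predictions ranked by confidence, matched greedily to the
same-class ground truth with highest IoU ≥ 0.5, one match per truth;
AP is the area under the monotone precision envelope over all recall
steps (an 11-point variant is available by flag); mAP averages classes
present in the ground truth, skipping (flagged NaN) classes absent from
both sides rather than rewarding silence.  Segmentation: per-class IoU
from the pixel confusion matrix with background included, mIoU the mean
over classes present; pixel accuracy the fraction of correctly labeled
pixels.  For segmentation models a dense analogue of mAP is reported as
per-class pixel precision at argmax decisions averaged over foreground
classes, since argmax masks carry no confidence ranking (the definition
is pluggable).  Throughput is N images / T seconds, reported both with
and without preprocessing time.  Model pairs are compared by a
two-sided paired t-test on per-sample metrics (df = n−1); zero-variance
differences return a flagged degenerate result.

The prose convention is the universal one: a false positive is a
predicted positive with no matching truth; a false negative a truth with
no matching prediction — the only reading under which TP/(TP+FP) is
precision.

## Synthetic data

The generator emulates the conveyor scene: an elongated ellipse (axis
ratio 2.6, random rotation ±15° and small translation — matching the
augmentation ranges the models must absorb) on a darker blue-grey
background; three longitudinal bands whose colours run pale pink
(belly) → orange (loin) → dark red-brown (back) with per-band
low-frequency sinusoidal luminance stripes standing in for myotome
texture (bands must differ in texture, not colour alone); sparse
irregular blobs per class (radius-modulated by low harmonics), pale for
fat, dark red for bruise, rejection-sampled to lie fully inside the
body; a linear illumination ramp and additive Gaussian pixel noise.

`band_fractions` are honoured as fractions of body *pixels*: the band
cuts invert the ellipse-area CDF, since equal height slices of an
ellipse are far from equal areas (a 0.30/0.40/0.30 height split yields
only ≈0.25 of pixels in the middle band).  Defect boxes are recomputed
from connected components of the rendered defect raster, so box/blob
agreement holds by construction even when blobs merge.  Everything is
deterministic per (spec, seed); per-sample seeds spawn from the master
seed so any prefix of a dataset is stable under changes of n.

Defaults are chosen for realism at 512 px (defect radii 2–12 px —
no pixel sizes are published for real defects, so this is an explicit
stand-in; blob/tissue colour separation well above the noise floor).
What the generator does **not** model: specular glare, wet-surface
reflections, partial fillets, occlusion, conveyor clutter, camera blur,
and inter-fish biological variation beyond colour/texture jitter.
Passing tests therefore demonstrate that the implementation learns and
measures what it claims on data with known ground truth — not
field-ready accuracy on real fillets.

## Numerical core

No GPU framework is assumed: `finseg.nn` is a compact reverse-mode
autodiff on numpy arrays with hand-written backward passes for the hot
kernels.  Convolutions are im2col views plus BLAS matmuls; the input
gradient of a strided convolution is computed as a stride-1 convolution
of the zero-dilated output gradient with the flipped kernel, so no
scatter-add sits on the hot path; transposed 2×2 stride-2 convolutions
reduce to einsums because windows never overlap.  Batch-norm runs as a
fused primitive with the standard three-term backward.  Every kernel is
checked against central finite differences in the suite.  Float32
throughout; the logistic function clips its argument at ±60; max-pool
gradients follow the argmax (first index on ties inside a window;
reduction ops split ties evenly).  Adam is the single optimizer used.

## Scale of the shipped experiments

The suite and the acceptance script train desk-scale models chosen as
the smallest configurations where the scientific effects are measurable:
part segmentation with a base-8/depth-3 U-Net on 200 synthetic 64-px
images for 30 epochs (held-out mIoU ≈ 0.97 with CBAM, ≈ 0.955 without),
and defect detection with a width-0.125 detector at 160-px input on 300
synthetic images for 60 epochs (held-out mAP@0.5 ≈ 0.76).  The P2
ablation uses 150 images with blob diameters ≤ 6 px for 30 epochs per
arm.  Splits are always at specimen level, 8:1:1 (train share rounded to
nearest, validation taking the odd remainder — the convention that
reproduces the published 489- and 1529-image splits exactly).

## Known limitations

- The synthetic domain is far easier than real fillet imagery; absolute
  metric values here do not transfer.
- Anchor k-means on a single-scale box population yields nearly
  degenerate anchors; the stride condition in target assignment, not
  anchor diversity, is what separates pyramid levels in that regime.
- The numpy core is single-threaded BLAS-bound; it is meant for
  correctness and desk-scale training, not production throughput.
- Checkpoints store raw arrays plus the config (npz); no cross-version
  migration is attempted.
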