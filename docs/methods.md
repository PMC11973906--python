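# Methods

## Problem and model

The task is binary semantic segmentation of thyroid nodules in B-mode
ultrasound: map a greyscale image to a per-pixel probability of
"nodule". The model is an encoder-decoder network in the DeepLabV3+
family, modified throughout for parameter economy; its components and
the reasoning behind every free choice are documented here.

### Encoder

A MobileNetV2 backbone (stem 3×3 stride-2 convolution, then the
standard inverted-residual plan t/c/n/s = 1/16/1/1, 6/24/2/2, 6/32/3/2,
6/64/4/2, 6/96/3/1, 6/160/3/2, 6/320/1/1) adapted to output stride 16:
when the cumulative stride reaches 16, further stride-2 blocks run at
stride 1 with dilation 2 (the usual DeepLab recipe), so no stride-32
feature map ever exists. We keep the last two block groups dilated
rather than truncating after the 96-channel stage: the 320-channel
stride-16 output lets the ASPP use branch widths near the conventional
256 while still meeting the parameter budgets below; a 96-channel
encoder would force implausibly wide (>1000-channel) decoder fusions to
reach the same totals. Convolutions carry no bias wherever a batch norm
follows (the norm owns the shift); batch-norm affine pairs count as
parameters, running statistics are buffers and do not. ReLU6 is used
inside the encoder, plain ReLU elsewhere; inverted-residual projections
are linear.

### Context: ASPP cascaded with PPM

The ASPP has five branches on the stride-16 map: 1×1, three 3×3 dilated
convolutions at rates 6/12/18 (the DeepLabV3+ convention at output
stride 16), and global average pooling; concatenation is fused by a 1×1
convolution. With `use_ds_aspp` the three dilated branches are
depthwise-separable (depthwise 3×3 dilated + 1×1 pointwise, each with
batch norm and ReLU); otherwise they are standard dilated convolutions.
Toggling the flag changes nothing else, so the parameter difference
between the two variants is exactly the three branches' difference.

The pyramid pooling module pools the ASPP output adaptively to
1×1, 2×2, 3×3 and 6×6 (PSPNet convention), processes each with a 1×1
convolution, upsamples back and concatenates with its input. There is
deliberately no post-concatenation fusion: removing the PPM changes the
context width by exactly the PPM branches' total width, which keeps the
ablation accounting transparent.

### Attention

CBAM-style gates. The channel gate pools max and average descriptors,
passes both through one shared two-layer MLP (hidden width ⌈C/r⌉,
r = 16, floor 1), sums and squashes with a sigmoid. Note that "shared"
refers to the two pooling paths using the same MLP — individual
channels are *not* interchangeable, since each output channel owns a
distinct second-layer row. The spatial gate concatenates channel-wise
max and mean maps and applies a 7×7 convolution + sigmoid. The channel
gate refines the deep (1/16) features, spatial gates the 1/8 and 1/4
skips. With attention disabled both gates are identities, so the
parameter delta of the toggle equals the gates' own counts.

### Decoder

Multi-skip (default): the attention-refined 1/16 map is upsampled ×2,
concatenated with the spatially-gated 1/8 skip and fused by a 3×3
depthwise-separable convolution; the result is upsampled ×2 and fused
the same way with a 1×1-projected, spatially-gated 1/4 skip (vertical
path). The ASPP+PPM context, upsampled to 1/4, is then concatenated and
fused (horizontal path). One extra 3×3 depthwise-separable fusion at
1/4 resolution implements the secondary fusion step before the final
upsampling — the placement of that step was ambiguous in the
architecture description; we chose the minimal reading (a single
stride-4 refinement before the head). The head is a biased 1×1
convolution to one channel, bilinear upsampling to full resolution
(half-pixel centres, corner alignment off, as everywhere) and a
sigmoid. With `use_multi_skip=False` the decoder is the original
DeepLabV3+ one: context upsampled ×4, one 1/4 skip via 1×1 projection,
two 3×3 depthwise-separable fusions.

### Calibrated widths

Three published budgets constrain the architecture: the full model
serializes to 12.4 MB, the DS-ASPP-only ablation (PPM/attention/
multi-skip off) to 14.7 MB, and the same variant with standard dilated
ASPP branches to 22.9 MB (ratio 64.2%). MB means decimal megabytes of
32-bit floats: `count × 4 / 10⁶` — the only convention under which the
ratios among these sizes are unit-free and mutually consistent. The
budgets pin totals, not widths, so the shipped defaults were fixed once
by a parameter-count-only grid search: ASPP branch width 268, ASPP
output 256, PPM branch width 96, decoder fusion widths 160 (1/8), 192
(1/4), shallow projection 48, horizontal fusion 252, single-skip
decoder width 887. The resulting counts are 3,099,859 (12.4 MB),
3,671,930 (14.7 MB) and 5,719,610 (22.9 MB); enhancements therefore
shrink the DS-only variant by 15.6%. A closed-form accountant
(`conv_math`) recomputes every component's count from layer shapes and
is tested against the constructed arrays, so these numbers are
arithmetic, not measurements.

## Losses

Binary cross-entropy (probabilities clipped to [1e-7, 1−1e-7]; mean
reduction for training, sum available) and the Tversky loss
`1 − (Σpg + s) / (Σpg + αΣp(1−g) + βΣ(1−p)g + s)` with α = 0.3,
β = 0.7 and smoothing s = 1. The loss-form (one minus the index) is the
standard choice where only the index is specified. The smoothing
constant makes an empty-mask image with an empty prediction score index
1/loss 0, which matters because a third of a realistic dataset has no
nodule. β > α penalizes false negatives more, which is what raises
sensitivity; α = β = 0.5 recovers soft Dice exactly (a tested
identity).

## Metrics

All metrics derive from pooled TP/FP/FN/TN at probability threshold 0.5
(the threshold is a convention, exposed as an argument): DSC, IoU
(= Jaccard), sensitivity, specificity, accuracy. Degenerate
denominators return 1 so correct rejection of empty images is not
penalized. Default dataset aggregation pools counts globally
("global_pool"); per-image averaging is available since the choice is
otherwise open, and the two differ whenever image difficulty varies.
`dsc_from_iou(iou) = 2·iou/(1+iou)` is exposed as a consistency oracle
for externally reported metric pairs.

## Preprocessing and augmentation

Standardization: any-size greyscale or RGB input to 512×512 (or a
configured size) 8-bit "mode L"; RGB collapses by Rec. 601 luminance;
masks resize nearest-neighbour and re-binarize. Denoising is Gaussian
(σ = 1.0 default); contrast enhancement is CLAHE with clip limit 2.0 in
the histogram-multiple convention (rescaled internally to scikit-image's
relative clip) on an 8×8 tile grid. Filter defaults are conventional
values, exposed in configuration. Augmentation quadruples the data:
original, horizontal mirror, vertical mirror, and one rotation drawn
uniformly from [−5°, +5°] (seeded; bilinear for images,
nearest-neighbour for masks, zero fill). The "random flip rotation"
phrasing in the source protocol is ambiguous; rotation-of-original is
the minimal reading that preserves the stated fourfold count.
Augmentation precedes the seeded 6:2:2 split — faithful to the stated
order even though it permits augment-siblings to straddle splits;
`split_grouped` provides the leak-free alternative.

## Phantoms

Each phantom is: smooth background (Gaussian-filtered noise, std 8 gray
levels around mean 120) + zero to two rotated elliptical nodules
(semi-axes 15–80 px at 512 scale, scaled with frame size; interior
darkened by 30–80 gray levels with a blurred rim; optional posterior
shadow with probability 0.15) × multiplicative speckle (Gaussian field,
unit mean, std 12/120; Rayleigh optional). Masks are the exact ellipse
interiors. Dataset prevalence is pinned exactly:
`round(n · prevalence)` images carry nodules (default 154/247).
What phantoms do not model: beam geometry, attenuation, tissue
interfaces, anisotropic speckle, annotation noise. Passing tests on
phantoms therefore demonstrates pipeline and optimization correctness,
not clinical performance.

## Training protocol and desk-scale experiment sizes

Adam (β₁ 0.9, β₂ 0.999), initial learning rate 1e-3 held constant
(cosine decay behind a flag), batch size 4, 60 epochs, Tversky loss by
default, best checkpoint by validation IoU, fully deterministic given
the seed. The numerical core is float32 NumPy; convolutions evaluate as
strided-window views contracted in BLAS, with input gradients via
transposed convolution on a stride-scattered canvas.

Tests and examples run width-reduced configurations (width multiplier
0.5, ASPP/decoder widths 64–96) on 128–160 px phantoms — chosen as the
package's desk-scale defaults so the full suite runs in minutes on one
CPU. Two behavioural experiments are part of the test suite: (i) an
overfit smoke test — 8 phantoms at 160×160 for the standard 60-epoch
protocol reaches training DSC above 0.9 with a monotonically trending
loss; (ii) a direction-of-effect experiment — on a tiny-nodule set
(≤1% foreground pixels) Tversky(β = 0.7) training attains sensitivity
at least that of BCE training at matched seed and epochs (in practice
BCE collapses to all-background on such imbalance while Tversky does
not). These reproduce orderings, not clinical magnitudes.

## Known limitations

- Phantom realism is deliberately bounded (see above); no claim about
  clinical accuracy follows from these tests.
- No pretrained encoder weights; training always starts from random
  initialization.
- CPU-only, single-process; full 512×512 training works but is slow.
- The width calibration fixes the parameter budgets exactly but the
  individual widths themselves are not identifiable from the budgets —
  other width vectors meeting the same totals exist.
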