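# Methods

## Problem and model

`cseanet` segments lung nodules on 2-D CT slices. Nodules are small, often
low-contrast, and their margins blur into surrounding parenchyma, so the
design concentrates on two things: preserving fine spatial detail across the
encoder-decoder bottleneck, and letting the network attend to *where* a
nodule is along each image axis.

The backbone is a nested encoder-decoder (U-Net++): encoder stages
X(i, 0) of two 3x3 conv + batch-norm + ReLU layers with 2x2 max-pool
downsampling, and a dense upper-triangular grid of decoder nodes

    X(i, j) = H( [ S_i, X(i, 1), ..., X(i, j-1), Up(X(i+1, j-1)) ] ),

where `Up` is bilinear x2 upsampling followed by a 3x3 convolution and
`S_i` is the skip transform of encoder output X(i, 0). The skip transform
is the model family's axis of variation (`skip_mode`):

* `plain` — identity (standard U-Net++);
* `dcse_only` — one dual-branch channel-spatial feature-enhancement module;
* `ca_only` — one coordinate-attention module;
* `csea` — the full block, DCSE -> coordinate attention -> DCSE.

A DCSE module runs two parallel branches over its C-channel input and fuses
them. The channel branch (CERM) applies a 3x3 trunk convolution and then
three parallel 3x3 convolutions with C/8, C/4 and 5C/8 filters; their
concatenation restores C channels and is added residually to the input.
The spatial branch (SFEM) applies a 1x1 entry convolution and three
parallel 3x3 dilated convolutions at rates 3, 5 and 7 (effective kernels
7, 11, 15), concatenated and fused 3C -> C by a 1x1 convolution. The two
branch outputs are concatenated (2C) and fused back to C by a 1x1
convolution. Coordinate attention pools the map along rows and columns,
squeezes the concatenated profiles to max(ceil(C/r), 8) channels
(1x1 conv + BN + hard-swish), expands each direction back to C channels,
and applies sigmoid gates as a per-channel outer product:
u_c(i,j) = y_c(i,j) * g^h_c(i) * g^w_c(j).

The head is a 1x1 convolution + sigmoid; training consumes pre-sigmoid
scores for numerical stability.

## Objective and metrics

Training minimizes L = 0.5 * L_Dice + L_BCE, where L_Dice is the smoothed
soft Dice loss 1 - (2|X∩Y| + λ)/(|X| + |Y| + λ) with λ = 1 by default
(λ rescues the empty-mask case and stabilizes gradients on tiny targets),
and L_BCE is mean binary cross-entropy evaluated with the log-sum-exp
stabilization in score space. Reduction is the mean over pixels and batch,
keeping the loss scale independent of batch size.

Evaluation uses hard masks at threshold 0.5: IoU = TP/(TP+FN+FP),
DSC = 2TP/(2TP+FN+FP), and Boundary IoU — the IoU of boundary bands, where
a mask's band is its foreground within Euclidean distance d of its contour
(foreground minus its d-erosion, computed via a distance transform on a
zero-padded mask so the image border counts as background). The band width
defaults to 2% of the image diagonal, minimum 1 px (6 px at 224x224); an
absolute override exists. Dataset-level scores are micro-aggregated from
summed confusion counts; per-image means are reported alongside. Both
empty-mask conventions (IoU/DSC and Boundary IoU = 1 when both sides are
empty) are logged when they fire so perfect negatives are visible but not
penalized.

## Training recipe

Adam (β = 0.9/0.999, ε = 1e-8) with classic L2 weight decay 1e-6, batch
size 4, 300 epochs by default, initial learning rate 1e-3 annealed per
epoch along a single half-cosine to η_min = 0 (no warm restarts —
the minimal reading of cosine annealing). Weight initialization is He
fan-in normal, threaded from a single seeded generator in construction
order. Model selection keeps the best-validation-DSC checkpoint; the last
checkpoint is also saved, and checkpoints carry a format-version string,
both configs and optimizer state, so runs resume exactly (the lr schedule
is closed-form in the epoch index). Data order and augmentation draws are
seeded per epoch; two runs with the same configs produce byte-identical
history CSVs.

## Numerical substrate

No GPU framework is used: the package carries a compact NumPy engine —
reverse-mode autodiff tensors, an im2col-GEMM convolution (stride 1,
arbitrary dilation), fused batch norm with the closed-form backward, 2x2
max-pooling, separable bilinear x2 upsampling, and Adam. Convolution is
verified against `scipy.signal.correlate2d` and finite differences in the
test suite; batch-norm, pooling and upsampling gradients are
finite-difference checked. Default compute dtype is float32; gradient
checks run in float64.

## Preprocessing

CT intensities are clipped to [-1000, 800] HU and mapped linearly onto
[0, 1] over that fixed window (not per image). The 2-D slice is replicated
into 3 channels (or stacked with its two axial neighbours in adjacent-slice
mode, edge-replicated at volume ends). Training images optionally receive
an HSV saturation/value jitter plus a luminance-contrast factor, each drawn
uniformly from ±20% with probability 0.5 — applied only after 3-channel
assembly and only to the training split. Patch extraction is restrictive:
windows of 224x224 are sampled so that each contains mask foreground when
any exists (jittered around a sampled foreground pixel), else restricted to
the body/lung field (pixels above -950 HU); undersized inputs are padded
with the air value. Splitting is 7:2:1 (train:test:val) by case — all
patches of one scan share a split — via a seeded shuffle with
largest-remainder allocation; per-case grouping is deliberately stricter
than a per-image split to rule out leakage between splits.

## Phantom generator

The phantom emulates the geometry of the segmentation task rather than CT
physics: a soft-tissue field (+40 HU) with two elliptical lung fields
(-800 HU) containing 1-3 star-convex nodules (radius 3-10 px, boundary
radius modulated by a 4-term random harmonic series with amplitude 25% of
the radius, per-nodule HU jitter ±30 around 0 HU), Gaussian blur σ = 1 px
for partial-volume edges and additive Gaussian noise σ = 20 HU. The mask
is the exact pre-blur nodule support — crisp ground truth over soft image
edges, as a human annotator would draw. Outputs stay inside the
[-1000, 800] HU window. Per-slice seeds are `seed + index`, and PNG
encoding is deterministic, so datasets regenerate byte-for-byte.

What passing on phantoms does show: the architecture, losses, metrics,
optimization and IO are wired correctly, and the model family can learn
small star-convex bright targets in a dark field. What it does not show:
performance on real CT, where vessels, ribs, scanner kernels, 3-D
continuity and genuinely ambiguous nodule margins dominate difficulty.

## Problem sizes used in tests and the acceptance script

The scaled-down benchmark trains on 200 phantom slices at 96x96
(7:2:1 split), depth 3 / base width 16, for 8 epochs with the standard
recipe, for both the full CSEA model and the plain-skip baseline; on this
high-contrast synthetic task both models exceed validation DSC 0.80 well
within those epochs, so the run doubles as a regression benchmark.
Unit-level checks use 48x48 phantoms, depth 3 / base width 8. These sizes
are the package's own desk-scale choices; the default configuration
(depth 5, base 32, 224x224, 300 epochs) is what one would use on real
datasets.

## Design choices where the design was open

* **Branch widths / fusions.** The dilated branches keep C channels each
  and every concatenation is followed by an explicit 1x1 fusion back to C,
  so each block is channel-preserving and the CSEA block is a drop-in skip
  replacement. Fusion convolutions use BN but no activation; all other
  convolutions are conv + BN + ReLU.
* **CERM branch topology.** The three channel-split convolutions are
  applied in parallel to the trunk output (the formulation consistent with
  the exact C/8 + C/4 + 5C/8 = C concatenation), not stacked sequentially.
* **Skip placement.** `per_level` (default) applies one skip module to each
  encoder output, shared by all nested nodes of that level; `per_edge`
  instantiates one per dense connection. Per-level bounds the parameter
  growth that the DCSE module otherwise causes across U-Net++'s dense grid.
* **Coordinate-attention internals.** δ = hard-swish, reduction r = 32 with
  an intermediate-channel floor of 8; both configurable.
* **Gating scope.** The row/column gates multiply the feature map
  per channel, exactly as the outer-product formula states, inside the CSEA
  block (between the two DCSE modules).
* **Channel divisibility.** Base widths must be multiples of 8 so the CERM
  split is integral; enforced at configuration time.
* **Upsampling.** Bilinear interpolation + 3x3 convolution rather than
  transposed convolution, avoiding checkerboard artifacts.
* **Deep supervision.** Available (averaged per-column heads) but off by
  default; the final nested node feeds the head.
* **Binarization threshold** 0.5, configurable; ε-clamp 1e-7 on
  probabilities in the BCE probability path.

## Known limitations

2-D only; single-class (nodule vs background); no test-time augmentation
or ensembling; the NumPy engine is single-threaded BLAS-bound and sized for
desk-scale experiments, not for 300-epoch full-resolution training; HSV
augmentation of replicated-grayscale CT mainly perturbs luminance/contrast
(hue is undefined on gray pixels); the phantom's difficulty is far below
real clinical data, so phantom DSC values are not comparable to DSC on real
datasets.
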