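# cseanet

Lung-nodule segmentation on 2-D CT slices with a nested encoder-decoder
(U-Net++) whose skip connections are replaced by **channel-spatial enhanced
attention (CSEA) blocks**. The package is aimed at medical-image-analysis
researchers who want a complete, desk-scale-testable reference
implementation of this model family: the architecture and its ablations,
the BCE-Dice objective, boundary-aware evaluation metrics, the CT
preprocessing pipeline, a seeded training loop, and a synthetic CT phantom
generator so that nothing requires an external dataset download.

## The model

Encoder stages X(i,0) (two 3x3 conv + BN + ReLU, 2x2 max-pool) feed the
dense U-Net++ decoder grid

    X(i,j) = H([ S_i, X(i,1), ..., X(i,j-1), Up(X(i+1,j-1)) ]),

where the skip transform S_i of each encoder output is the configurable
heart of the model (`skip_mode`): identity (plain U-Net++), DCSE only, CA
only, or the full CSEA block, `DCSE -> CA -> DCSE`.

A **DCSE** module fuses two parallel branches over a C-channel map:

* **CERM** — 3x3 trunk conv, then three parallel 3x3 convs with C/8, C/4
  and 5C/8 filters; their concatenation (exactly C channels) is added
  residually to the input.
* **SFEM** — 1x1 entry conv, then three parallel 3x3 dilated convs at
  rates 3/5/7 (effective kernels 7/11/15 px), fused 3C -> C by a 1x1 conv.

**Coordinate attention** pools the map along rows (z^h) and columns (z^w),
squeezes the concatenated profiles through a 1x1 conv + BN + hard-swish,
and emits per-row and per-column sigmoid gates applied as
u_c(i,j) = y_c(i,j) · g^h_c(i) · g^w_c(j).

Training minimizes `L = 0.5·L_Dice + L_BCE` (smoothed soft Dice, λ = 1);
evaluation reports IoU = TP/(TP+FN+FP), DSC = 2TP/(2TP+FN+FP) and Boundary
IoU (IoU of the masks' boundary bands, band width 2% of the image diagonal
by default). The recipe is Adam with weight decay 1e-6, batch 4, initial
lr 1e-3 with single-cycle cosine annealing.

Everything runs on a compact NumPy neural-network engine bundled with the
package (reverse-mode autodiff, im2col-GEMM convolution, fused batch norm,
bilinear upsampling, Adam) — no GPU framework required. See
`docs/methods.md` for assumptions, parameter defaults and design choices.

## Worked example

Generate a phantom dataset, train a small model, evaluate and predict:

```bash
cseanet synth --n 60 --size 96 --seed 7 --out work/phantom
python - << 'EOF'
from cseanet import ModelConfig, TrainConfig, train, evaluate
from cseanet.phantom import read_manifest
from cseanet.preprocess import split_dataset
from cseanet.phantom import write_manifest

records = split_dataset(read_manifest("work/phantom/manifest.csv"), seed=7)
write_manifest("work/phantom/manifest.csv", records)
result = train(ModelConfig(depth=3, base_channels=16, skip_mode="csea", seed=7),
               TrainConfig(epochs=8, seed=7), records, out_dir="work/run")
print(f"best val DSC {result['best_dsc']:.4f}")
report = evaluate("work/run/best.npz", records, split="test")
m = report.micro
print(f"test IoU {m['iou']:.4f}  DSC {m['dsc']:.4f}  BoundaryIoU {m['boundary_iou']:.4f}")
EOF
```

Output from this exact run (seeds fixed):

```
best val DSC 0.9487
test IoU 0.9043  DSC 0.9498  BoundaryIoU 0.7539
```

`best val DSC` is the micro-aggregated Dice coefficient on the validation
split at the best epoch — on these high-contrast phantoms even a small
model approaches 0.95 within a few epochs. The test-split row shows the
same metrics on held-out slices; Boundary IoU is lower than DSC because it
scores only the band of pixels within 3 px (2% of the 96x96 diagonal) of
each mask's contour, exactly where the discretized star-convex nodule
boundaries are hardest to match.

Then segment a single slice:

```bash
cseanet predict --ckpt work/run/best.npz --in work/phantom/slice_0000_img.png \
                --out work/slice_0000_pred.png
```

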