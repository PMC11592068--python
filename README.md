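# ucapsnet

Two-stage analysis of grayscale breast-ultrasound images: an **enhanced
U-Net** segments hypoechoic lesions into binary masks, and a **capsule
network** — dense-block feature extractor, primary capsules, dynamic
routing-by-agreement, margin loss — classifies each segmented lesion as
benign or malignant. A seeded speckle-phantom generator makes the whole
pipeline runnable, testable and reproducible without any clinical dataset;
real data in the BUSI directory layout (class folders `benign/`,
`malignant/`, `normal/` with `*_mask*.png` ground truth) is read directly.

The package is aimed at researchers studying lesion segmentation and
capsule-based classification who want a transparent, dependency-light
reference implementation: the entire numerical core (convolutions,
batch-norm, pooling, transpose convolutions, Adam, and the capsule
operations with their exact gradients) is hand-written numpy, validated
against finite differences and a scalar routing reference in the test
suite.

## The model

**Stage 1.** The segmenter is a U-Net with 4 encoder blocks (two 3×3
convolutions, batch-norm, ReLU, He-normal init, 2×2 max-pool), filters
doubling from 64 to a 1024-channel bottleneck, a mirrored decoder with
2×2-stride-2 transpose convolutions, skip concatenations and dropout, and a
1×1 sigmoid head. Training minimizes pixelwise binary cross-entropy; masks
are produced by thresholding at 0.5.

**Stage 2.** Predicted masks are downsampled to half resolution,
replicated to 3 channels, and passed through a padded 7×7/stride-2 stem
(9408 weights; 134×134×3 → 64×64×64 → 66×66×64 → 32×32×64 at the default
128-px input), a 4-layer DenseNet-style block (growth 32, 64 → 192
channels), and reshaped into 8-dimensional **capsules** whose norms encode
entity presence after the squash

&nbsp;&nbsp;&nbsp;&nbsp;squash(s) = ‖s‖²/(1+‖s‖²) · s/(‖s‖+ε).

Routing by agreement distributes each primary capsule's vote over the class
capsules through softmax coefficients refined for 3 iterations; class
scores are the class-capsule norms ‖v_k‖, calibrated by a small dense +
softmax head. Training minimizes the margin loss

&nbsp;&nbsp;&nbsp;&nbsp;L = Σ_k y_k·max(0, m⁺−ŷ_k)² + λ(1−y_k)·max(0, ŷ_k−m⁻)²

with m⁺ = 0.9, m⁻ = 0.1, λ = 0.5. Evaluation reports accuracy, precision,
recall, F1 and the confusion matrix; segmentation is scored by Dice, mean
IoU and pixel accuracy. See `docs/methods.md` for every design choice and
its rationale.

## Worked example

```python
import numpy as np
from ucapsnet import (PhantomConfig, SegConfig, CapsConfig, TrainConfig,
                      make_dataset, run_two_stage)

phantoms = make_dataset(50, PhantomConfig(size=128, seed=7))   # 150 images
manifest = run_two_stage(
    phantoms,
    seg_config=SegConfig(input_size=128, base_filters=8, depth=3),
    caps_config=CapsConfig(input_size=64, dense_layers=2, primary_caps_dim=4),
    tc_seg=TrainConfig(learning_rate=3e-3, epochs=8, batch_size=5),
    tc_cls=TrainConfig(learning_rate=5e-3, epochs=15, batch_size=5),
    seed=1,
)
print(manifest.segmentation)
print(manifest.classification["accuracy"])
```

Output from this exact run:

```
{'mean_dice': 0.9796336522353636, 'mean_iou': 0.9606371944804355, 'pixel_accuracy': 0.99437255859375}
0.8
```

i.e. the tiny segmenter recovers the phantom lesions at Dice ≈ 0.98 on the
held-out 20%, and the capsule classifier separates smooth (benign) from
spiculated (malignant) margins at 80% held-out accuracy (the 40-image test
set gives roughly ±0.07 sampling noise; the benchmarks in
`ucapsnet.experiments` therefore report 3-seed medians). Rerunning with
the same `seed` reproduces these numbers exactly.

The same pipeline runs from a shell:

```
ucapsnet synth --out data/ --n-per-class 50 --size 128 --seed 7
ucapsnet run --data data/ --out runs/demo --seed 1
ucapsnet inspect          # layer-by-layer shape/parameter table
```

`ucapsnet inspect` prints the classifier's architecture trace — the stem
pad/conv/pool shapes (134, 64, 66, 32) with 9408 stem-conv weights, and the
dense-block layers with 8192 / 512 / 36,864 parameters concatenating to
32×32×192 — which is how the printed architecture is verified.

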