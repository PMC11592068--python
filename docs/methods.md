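# Methods

`ucapsnet` implements a two-stage analysis of grayscale breast-ultrasound
images: lesion segmentation with an enhanced U-Net, followed by
benign/malignant classification of the segmentation masks with a capsule
network. This note records the models, the choices made where the design was
genuinely open, and what the synthetic benchmarks do and do not demonstrate.

## The numerical core

No deep-learning framework is used. The package carries its own compact
numpy layer library (`ucapsnet.nn`): 2-D convolution and transpose
convolution (im2col via stride tricks), batch normalization, max pooling,
dropout, dense layers, all with hand-written reverse-mode gradients, plus an
Adam optimizer. Every layer's backward pass is validated against central
finite differences in the test suite. Tensors are channels-last float32;
capsule arithmetic runs in float64 for headroom in the squash/routing
algebra.

Batch-norm moving statistics use momentum 0.9 (not the common 0.99):
the training runs this package targets take a few hundred optimizer steps,
and the inference-mode statistics must converge within them. Batch-norm
parameter counting includes the two moving statistics, i.e. 4 per channel,
matching the summary convention of the major frameworks.

## Stage 1 — enhanced U-Net

Encoder: `depth` blocks (default 4) of two same-padded 3×3 convolutions
with ReLU and He-normal init, batch-norm after the first convolution, then
2×2 max-pool. Filters start at `base_filters` (default 64) and double per
level, giving a `base_filters·2^depth`-channel bottleneck (1024 at the
defaults). Decoder: 2×2-stride-2 transpose convolutions, concatenation with
the matching encoder features, two 3×3 convolutions, and dropout (default
rate 0.3). Head: 1×1 convolution with a sigmoid, thresholded at 0.5 with
the `>=` convention so an exactly-0.5 probability maps to foreground.

The training loss is pixelwise binary cross-entropy — the natural choice
for a one-channel sigmoid head; the gradient is computed in the fused
`p − y` form for numerical stability. An optional soft-Dice term
(`dice_weight`) can be added: with sparse foreground (~5% of pixels here),
pure BCE has an all-background local optimum that short training runs
sometimes fail to escape, and the Dice term removes it. The recovery
benchmarks use weight 0.5; the full-scale default remains plain BCE. Dice
is tracked per epoch as a monitoring metric.

## Stage 2 — capsule network

The classifier consumes the predicted masks, downsampled to half the
segmentation resolution (nearest-neighbor, preserving binarity) and
replicated to three channels.

* **Stem** — zero-pad 3, 7×7/stride-2 convolution with 64 filters and no
  bias (9408 weights for 3-channel input), batch-norm, ReLU, zero-pad 1,
  3×3/stride-2 max-pool. At 128 px input the trace is
  134×134×3 → 64×64×64 → 66×66×64 → 32×32×64. The 66→32 step is a pooling
  operation: no reshape can map 66·66·64 onto 32·32·64 elements, and a
  stride-2 3×3 pool reproduces the shapes exactly.
* **Dense block** — 4 pre-activation composite layers
  (BN → ReLU → 1×1 conv to 4·growth → BN → ReLU → 3×3 conv to growth →
  channel concat) with growth rate 32: 64 → 192 channels, introducing
  8192-, 512- and 36 864-parameter layers in the first composite.
* **Primary capsules** — batch-norm, dropout (0.275), then the feature
  volume is reshaped into D=8-dimensional capsules and squashed
  (`‖s‖²/(1+‖s‖²) · s/(‖s‖+ε)`, ε = 1e-7), so each capsule norm lies in
  [0,1).
* **Dynamic routing** — one learned linear map per (primary, class) pair
  produces prediction vectors û; routing logits start at zero and for 3
  iterations the coefficients softmax over classes, votes aggregate,
  squash, and logits grow by the agreement û·v. The loop is differentiated
  exactly (reverse sweep through all iterations, softmax included), and a
  straight-line scalar reference implementation pins the forward pass to
  1e-9 in the tests.
* **Head** — class-capsule norms feed a K×K dense layer plus softmax. The
  margin loss `Σ_k y_k max(0, m⁺−ŷ_k)² + λ(1−y_k) max(0, ŷ_k−m⁻)²`
  (m⁺ = 0.9, m⁻ = 0.1, λ = 0.5) is applied to the *norms* — capsule
  semantics make each norm an independent class-presence probability, and
  the published hand example (ŷ = (0.3, 0.8), loss 0.605) only makes sense
  for scores that need not sum to one. The dense head is fit jointly by
  cross-entropy on detached norms: it calibrates the reported probability
  vector without feeding gradients back into the capsule body. It starts as
  a scaled identity (a monotone map of the norms) so its predictions agree
  with the capsule ordering from the first step.

Two optimization choices matter at this scale:

* The routing transform (N·K·16·D parameters) is updated by plain gradient
  descent at 10× the Adam rate rather than by Adam. Adam's scale-free
  per-parameter steps are coherent across all N primary capsules (they share
  the upstream gradient), so it moves the aggregated vote `s_j` by O(N·lr)
  per step and drives the squash into its saturated, vanishing-gradient
  regime. Plain SGD steps are proportional to the gradient and self-damp at
  saturation.
* The routing transform is initialized from N(0, (3/√N)²) so the initial
  agreement-weighted sum lands in the responsive range of the squash.

The classifier is binary (benign vs malignant); `normal` images carry no
lesion and are excluded from classification, matching how the two-stage
workflow reports results. A learning-rate discrepancy in the source design
(1e-5 stated for training overall, 5e-3 in the hyperparameter table) is
resolved by attaching 1e-5 to the segmenter and 5e-3 to the classifier as
full-scale defaults; both are configurable.

Training applies a random axis-aligned flip/rotation (the 8 dihedral
transforms) per image per epoch; lesion morphology is orientation-free, so
these are label-preserving.

## Synthetic phantoms

The generator emulates the three properties the pipeline needs from breast
ultrasound: multiplicative speckle (unit-mean gamma noise, shape 4, i.e.
std/mean = 0.5, the fully-developed-speckle approximation), hypoechoic
lesions (intensity multiplied by 1 − 0.45 inside the lesion on a 0.55
background), and class-dependent margin morphology — benign lesions are
rotated ellipses with axis ratio 0.65–0.95, malignant lesions are
spiculated regions `r(θ) = r₀(1 + a·|sin(kθ/2)|)` with k = 6–12 spicules
and amplitude a = 0.35–0.7. Lesion radii span 0.12–0.28 of the image side.
The exact rasterized interior is the ground-truth mask.

A threshold on the mask irregularity index (perimeter²/4π·area) separates
the classes with >80% accuracy by construction, so the classifier's
recovery task is well-posed. The phantoms deliberately omit attenuation,
posterior shadowing, heterogeneous tissue texture and operator variability;
passing the recovery benchmarks demonstrates that the implementation can
learn planted structure end to end, not that it reaches any particular
performance on clinical data.

## Benchmark problem sizes

The recovery experiments (`ucapsnet.experiments`) use reduced
configurations chosen so each stage trains in minutes on one CPU:

* Segmentation: 64-px phantoms, U-Net with base 8 filters and depth 3,
  50 train / 20 test, 10 epochs, Adam 3e-3, batch 5, BCE + 0.5·soft-Dice;
  summary is the median over 3 training seeds of the mean held-out Dice.
* Classification: 64-px masks, capsule net with 2 composite layers and
  D = 4, 100 balanced train / 40 balanced test, 15 epochs, Adam 5e-3,
  batch 5; 3-seed median held-out accuracy, plus a shuffled-label control
  that must stay at chance level. Accuracy on 40 held-out phantoms carries
  ±0.07–0.08 sampling noise (and the shuffled-label control spreads even
  wider, since a network trained on noise generalizes with a random sign),
  which is why every summary — control included — is a median over the
  three training seeds rather than a single run.
* End-to-end: 150 phantoms at 128 px, segmenter at 128, classifier at 64
  (preserving the workflow's 2:1 resolution ratio), segmenter trained 8
  epochs; the run is repeated under the same master seed to check that the
  manifest metrics reproduce exactly.

The short-run learning rates (3e-3 / 5e-3, batch 5) are the tiny-run
training configuration: the full-scale defaults (50 epochs, batch 25)
assume two orders of magnitude more optimizer steps.

## Numerical conventions and degenerate inputs

* Dice and IoU return 1.0 when both masks are empty (perfect agreement);
  they are related by `dice = 2·iou/(1+iou)`, verified numerically.
* "Segmentation accuracy" always means pixel accuracy and is labeled as
  such; mean IoU is the unweighted per-image mean of foreground IoU.
* Zero denominators in precision/recall yield 0.0 with an explicit flag in
  the report rather than NaN.
* Cross-validation is stratified by class; a class with fewer members than
  folds is a named error.
* The squash of the zero vector is the zero vector (ε guards the division).
* Masks are resized nearest-neighbor everywhere so they remain exactly
  binary; images are resized bilinearly.
* Multiple mask files for one image are OR-combined.

## Known limitations

* The numpy backend is single-threaded BLAS-bound; full-scale (256 px,
  64-filter) training is functional but slow — the package's tested domain
  is the reduced configurations above.
* Routing memory grows as B·N·K·16; very large feature volumes need small
  batches.
* The phantom generator's simplicity means benchmark numbers here say
  nothing quantitative about BUSI or any clinical dataset.
* Model serialization stores raw parameter arrays (`.npz`); no checkpoint
  format compatibility with other frameworks is attempted.
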