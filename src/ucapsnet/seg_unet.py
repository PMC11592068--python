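"""Enhanced U-Net for lesion segmentation.

Encoder–decoder with skip connections: ``depth`` encoder blocks (two 3×3
same-padded convolutions with ReLU, batch-norm after the first, He-normal
init) each followed by a 2×2 max-pool; a two-convolution bottleneck with
batch-norm; ``depth`` decoder blocks (2×2 stride-2 transpose-convolution
upsample, concatenation with the matching encoder features, two 3×3
convolutions, dropout); and a 1×1 sigmoid head producing a per-pixel lesion
probability.  Filters start at ``base_filters`` and double per encoder
level, so the bottleneck carries ``base_filters * 2**depth`` channels.

Training minimizes pixelwise binary cross-entropy with Adam and is fully
reproducible given the init and training seeds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from .data_io import LabeledImage
from .metrics import dice
from .nn import (
    Adam,
    BatchNorm2D,
    Conv2D,
    ConvTranspose2D,
    Dropout,
    LayerInfo,
    MaxPool2D,
    NetworkSpec,
    ReLU,
)

if TYPE_CHECKING:
    from .pipeline import TrainConfig


@dataclass(frozen=True)
class SegConfig:
    input_size: int = 256
    base_filters: int = 64
    depth: int = 4
    dropout_rate: float = 0.3
    weight_init: str = "he_normal"
    threshold: float = 0.5

    def __post_init__(self):
        if self.base_filters < 1:
            raise ValueError("base_filters must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0,1)")
        if self.input_size % (2**self.depth) != 0:
            raise ValueError(
                f"input_size {self.input_size} not divisible by 2**depth = {2**self.depth}"
            )
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0,1)")
        if self.weight_init != "he_normal":
            raise ValueError("only he_normal init is supported")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class EnhancedUNet:
    """The segmentation network; weights live in the layer objects."""

    def __init__(self, config: SegConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        bf, depth = config.base_filters, config.depth
        self.enc = []
        in_ch = 1
        for i in range(depth):
            f = bf * 2**i
            self.enc.append({
                "conv1": Conv2D(f"enc{i+1}_conv1", in_ch, f, 3, padding="same", rng=rng),
                "bn": BatchNorm2D(f"enc{i+1}_bn", f),
                "relu1": ReLU(f"enc{i+1}_relu1"),
                "conv2": Conv2D(f"enc{i+1}_conv2", f, f, 3, padding="same", rng=rng),
                "relu2": ReLU(f"enc{i+1}_relu2"),
                "pool": MaxPool2D(f"enc{i+1}_pool", 2),
            })
            in_ch = f
        fb = bf * 2**depth
        self.bottleneck = {
            "conv1": Conv2D("bottleneck_conv1", in_ch, fb, 3, padding="same", rng=rng),
            "relu1": ReLU("bottleneck_relu1"),
            "conv2": Conv2D("bottleneck_conv2", fb, fb, 3, padding="same", rng=rng),
            "relu2": ReLU("bottleneck_relu2"),
            "bn": BatchNorm2D("bottleneck_bn", fb),
        }
        self.dec = []
        drop_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
        in_ch = fb
        for j in range(depth):
            i = depth - 1 - j  # matching encoder level
            f = bf * 2**i
            self.dec.append({
                "up": ConvTranspose2D(f"dec{j+1}_up", in_ch, f, 2, rng=rng),
                "conv1": Conv2D(f"dec{j+1}_conv1", 2 * f, f, 3, padding="same", rng=rng),
                "relu1": ReLU(f"dec{j+1}_relu1"),
                "conv2": Conv2D(f"dec{j+1}_conv2", f, f, 3, padding="same", rng=rng),
                "relu2": ReLU(f"dec{j+1}_relu2"),
                "drop": Dropout(f"dec{j+1}_dropout", config.dropout_rate, rng=drop_rng),
            })
            in_ch = f
        self.head = Conv2D("output", in_ch, 1, 1, padding="same", rng=rng)

    def layers(self):
        out = []
        for blk in self.enc:
            out.extend(blk.values())
        out.extend(self.bottleneck.values())
        for blk in self.dec:
            out.extend(blk.values())
        out.append(self.head)
        return out

    # -- forward / backward ------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Map a (B,H,W,1) batch to per-pixel lesion probabilities."""
        h = x.astype(np.float32)
        self._skips = []
        for blk in self.enc:
            for key in ("conv1", "bn", "relu1", "conv2", "relu2"):
                h = blk[key].forward(h, train)
            self._skips.append(h)
            h = blk["pool"].forward(h, train)
        for key in ("conv1", "relu1", "conv2", "relu2", "bn"):
            h = self.bottleneck[key].forward(h, train)
        for blk, skip in zip(self.dec, reversed(self._skips)):
            h = blk["up"].forward(h, train)
            h = np.concatenate([h, skip], axis=-1)
            for key in ("conv1", "relu1", "conv2", "relu2", "drop"):
                h = blk[key].forward(h, train)
        logits = self.head.forward(h, train)
        self._probs = _sigmoid(logits)
        return self._probs

    def backward_bce(self, y: np.ndarray, dice_weight: float = 0.0) -> None:
        """Backprop the segmentation loss from the cached forward.

        The base loss is pixelwise binary cross-entropy (fused sigmoid
        gradient ``p - y``).  With ``dice_weight`` > 0 a soft-Dice term
        ``1 - (2Σpy+1)/(Σp+Σy+1)`` over the batch is added, which counters
        the all-background collapse BCE favors when foreground is rare.
        """
        p = self._probs
        g = (p - y) / p.size
        if dice_weight:
            num = 2.0 * float((p * y).sum()) + 1.0
            den = float(p.sum() + y.sum()) + 1.0
            ddice_dp = -(2.0 * y * den - num) / den**2
            g = g + dice_weight * ddice_dp * p * (1.0 - p)
        g = self.head.backward(g.astype(np.float32))
        skip_grads = []
        for blk in reversed(self.dec):
            for key in ("drop", "relu2", "conv2", "relu1", "conv1"):
                g = blk[key].backward(g)
            f = blk["up"].out_ch
            g_up, g_skip = g[..., :f], g[..., f:]
            skip_grads.append(np.ascontiguousarray(g_skip))
            g = blk["up"].backward(np.ascontiguousarray(g_up))
        for key in ("bn", "relu2", "conv2", "relu1", "conv1"):
            g = self.bottleneck[key].backward(g)
        # skip_grads was collected shallowest-first (reversed decoder order)
        for blk, gs in zip(reversed(self.enc), reversed(skip_grads)):
            g = blk["pool"].backward(g) + gs
            for key in ("relu2", "conv2", "relu1", "bn", "conv1"):
                g = blk[key].backward(g)

    # -- architecture trace ------------------------------------------------

    def network_spec(self) -> NetworkSpec:
        cfg = self.config
        infos: list[LayerInfo] = []
        shape = (cfg.input_size, cfg.input_size, 1)

        def add(layer, s):
            out = layer.out_shape(s)
            infos.append(LayerInfo(layer.name, layer.kind, out, layer.param_count))
            return out

        skips = []
        for blk in self.enc:
            for key in ("conv1", "bn", "relu1", "conv2", "relu2"):
                shape = add(blk[key], shape)
            skips.append(shape)
            shape = add(blk["pool"], shape)
        for key in ("conv1", "relu1", "conv2", "relu2", "bn"):
            shape = add(self.bottleneck[key], shape)
        for j, (blk, skip) in enumerate(zip(self.dec, reversed(skips))):
            shape = add(blk["up"], shape)
            shape = (shape[0], shape[1], shape[2] + skip[2])
            infos.append(LayerInfo(f"dec{j+1}_concat", "concatenate", shape, 0))
            for key in ("conv1", "relu1", "conv2", "relu2", "drop"):
                shape = add(blk[key], shape)
        shape = add(self.head, shape)
        infos.append(LayerInfo("sigmoid", "sigmoid", shape, 0))
        return NetworkSpec("enhanced_unet", infos)


def build_enhanced_unet(config: SegConfig | None = None, seed: int = 0) -> EnhancedUNet:
    """Construct the enhanced U-Net with He-normal-initialized weights."""
    return EnhancedUNet(config or SegConfig(), seed=seed)


def train_segmenter(model: EnhancedUNet, data: list[LabeledImage], tc: "TrainConfig",
                    dice_weight: float = 0.0):
    """Train on image/mask pairs; returns per-epoch history (loss, dice).

    Every record must carry a mask sized to the model input.  Batch order,
    dropout and parameter updates are all driven by ``tc.seed``.  The loss
    is pixelwise binary cross-entropy, optionally combined with a soft-Dice
    term weighted by ``dice_weight`` (see
    :meth:`EnhancedUNet.backward_bce`).
    """
    if not data:
        raise ValueError("empty training dataset")
    missing = [r.source_id for r in data if r.mask is None]
    if missing:
        raise ValueError(f"records without masks: {missing}")
    size = model.config.input_size
    bad = [r.source_id for r in data if r.pixels.shape != (size, size)]
    if bad:
        raise ValueError(f"records not sized to {size}x{size}: {bad[:5]}")

    x = np.stack([r.pixels for r in data])[..., None].astype(np.float32)
    y = np.stack([r.mask for r in data])[..., None].astype(np.float32)
    rng = np.random.default_rng(tc.seed)
    for blk in model.dec:  # re-seed dropout stream for reproducible training
        blk["drop"].rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
    opt = Adam(model.layers(), lr=tc.learning_rate)
    thr = model.config.threshold
    history = []
    for epoch in range(tc.epochs):
        order = rng.permutation(len(data))
        losses, dices = [], []
        for start in range(0, len(data), tc.batch_size):
            idx = order[start : start + tc.batch_size]
            p = model.forward(x[idx], train=True)
            pc = np.clip(p, 1e-7, 1 - 1e-7)
            losses.append(float(-np.mean(y[idx] * np.log(pc) + (1 - y[idx]) * np.log(1 - pc))))
            dices.append(float(np.mean([
                dice(p[b, :, :, 0] >= thr, y[idx][b, :, :, 0] >= 0.5)
                for b in range(len(idx))
            ])))
            model.backward_bce(y[idx], dice_weight=dice_weight)
            opt.step()
        history.append({"epoch": epoch + 1,
                        "loss": float(np.mean(losses)),
                        "dice": float(np.mean(dices))})
    return history


def predict_mask(model: EnhancedUNet, image: np.ndarray) -> np.ndarray:
    """Segment one grayscale image into a binary mask (prob >= threshold -> 1)."""
    image = np.asarray(image, dtype=np.float32)
    size = model.config.input_size
    if image.shape != (size, size):
        raise ValueError(f"expected a {size}x{size} image, got {image.shape}")
    p = model.forward(image[None, :, :, None], train=False)
    return (p[0, :, :, 0] >= model.config.threshold).astype(np.uint8)


def predict_masks(model: EnhancedUNet, images: list[np.ndarray],
                  batch_size: int = 8) -> list[np.ndarray]:
    """Batched :func:`predict_mask` over a list of same-sized images."""
    size = model.config.input_size
    out: list[np.ndarray] = []
    for start in range(0, len(images), batch_size):
        chunk = np.stack([np.asarray(im, dtype=np.float32)
                          for im in images[start : start + batch_size]])
        if chunk.shape[1:] != (size, size):
            raise ValueError(f"expected {size}x{size} images, got {chunk.shape[1:]}")
        p = model.forward(chunk[..., None], train=False)
        out.extend((p[i, :, :, 0] >= model.config.threshold).astype(np.uint8)
                   for i in range(len(chunk)))
    return out
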