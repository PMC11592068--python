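"""Capsule network for benign/malignant classification of lesion masks.

The classifier consumes 3-channel mask images (the segmentation stage's
output, see :func:`ucapsnet.data_io.prepare_for_classifier`) and proceeds
through four parts:

1. **Stem** — zero-pad 3, 7×7 stride-2 convolution (64 filters, no bias),
   batch-norm, ReLU, zero-pad 1, 3×3 stride-2 max-pool.  With a 128×128×3
   input the trace is 134×134×3 → 64×64×64 (9408 weights) → 66×66×64 →
   32×32×64.
2. **Dense block** — DenseNet-style composite layers
   (BN → ReLU → 1×1 conv to 4·growth → BN → ReLU → 3×3 conv to growth →
   channel concat), growing 64 → 64 + layers·growth channels.
3. **Primary capsules** — batch-norm, dropout, then the feature volume is
   reshaped into D-dimensional vectors and squashed so each capsule's norm
   lies in [0,1) and can be read as an entity-presence probability.
4. **Dynamic routing by agreement** — each primary capsule predicts every
   class capsule through a learned transform; routing coefficients
   (a softmax over classes of accumulated agreement logits) iteratively
   concentrate each capsule's vote on the class capsule it agrees with.
   Class-capsule norms feed a small dense + softmax head.

Training minimizes the margin loss: the true class is pushed above ``m+``
and the others below ``m-``, absent-class violations down-weighted by λ.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from .data_io import Label
from .nn import (
    Adam,
    BatchNorm2D,
    Conv2D,
    Dense,
    Dropout,
    LayerInfo,
    MaxPool2D,
    NetworkSpec,
    ReLU,
    ZeroPad2D,
    glorot_normal,
)

if TYPE_CHECKING:
    from .pipeline import TrainConfig

CLASS_ORDER = (Label.BENIGN, Label.MALIGNANT)

# step-size ratio between the plain-SGD routing-transform update and the
# Adam learning rate used for the convolutional body (see train_classifier)
ROUTING_LR_MULT = 10.0


@dataclass(frozen=True)
class CapsConfig:
    input_size: int = 128
    stem_filters: int = 64
    growth_rate: int = 32
    dense_layers: int = 4
    primary_caps_dim: int = 8
    class_caps_dim: int = 16
    n_classes: int = 2
    routing_iterations: int = 3
    m_plus: float = 0.9
    m_minus: float = 0.1
    lambda_down: float = 0.5
    epsilon: float = 1e-7
    dropout_rate: float = 0.275
    weight_init: str = "glorot_normal"

    def __post_init__(self):
        if not 0 < self.m_minus < self.m_plus < 1:
            raise ValueError("need 0 < m_minus < m_plus < 1")
        if self.lambda_down <= 0 or self.epsilon <= 0:
            raise ValueError("lambda_down and epsilon must be > 0")
        if self.routing_iterations < 1:
            raise ValueError("routing_iterations must be >= 1")
        if self.weight_init != "glorot_normal":
            raise ValueError("only glorot_normal init is supported")
        h = self.feature_side
        if (h * h * self.feature_channels) % self.primary_caps_dim != 0:
            raise ValueError(
                f"feature volume {h}x{h}x{self.feature_channels} not divisible "
                f"by primary_caps_dim={self.primary_caps_dim}"
            )

    @property
    def feature_side(self) -> int:
        """Spatial side after the stem (pad3 → conv s2 → pad1 → pool3 s2)."""
        after_conv = (self.input_size + 6 - 7) // 2 + 1
        return (after_conv + 2 - 3) // 2 + 1

    @property
    def feature_channels(self) -> int:
        return self.stem_filters + self.dense_layers * self.growth_rate

    @property
    def n_primary_capsules(self) -> int:
        h = self.feature_side
        return h * h * self.feature_channels // self.primary_caps_dim


@dataclass
class CapsuleTensor:
    """A set of capsule vectors; row norms are entity-presence probabilities."""

    values: np.ndarray  # (..., N, D)

    @property
    def norms(self) -> np.ndarray:
        return np.linalg.norm(self.values, axis=-1)


# ---------------------------------------------------------------------------
# Core capsule operations
# ---------------------------------------------------------------------------

def squash(s: np.ndarray, epsilon: float = 1e-7) -> np.ndarray:
    """Squash nonlinearity: (‖s‖²/(1+‖s‖²)) · s/(‖s‖+ε) along the last axis.

    Rescales the norm into [0,1) while preserving direction; the zero vector
    maps to itself.
    """
    s = np.asarray(s, dtype=np.float64)
    if not np.all(np.isfinite(s)):
        raise ValueError("squash input must be finite")
    norm = np.linalg.norm(s, axis=-1, keepdims=True)
    scale = norm**2 / (1.0 + norm**2) / (norm + epsilon)
    return scale * s


def _squash_backward(s: np.ndarray, g: np.ndarray, epsilon: float) -> np.ndarray:
    """Vector–Jacobian product of :func:`squash` at ``s`` applied to ``g``."""
    s = np.asarray(s, dtype=np.float64)
    r = np.linalg.norm(s, axis=-1, keepdims=True)
    r_safe = np.maximum(r, 1e-30)
    h = r**2 / (1.0 + r**2)
    a = h / (r + epsilon)
    b = 2.0 / ((1.0 + r**2) ** 2 * (r + epsilon)) - h / (r_safe * (r + epsilon) ** 2)
    sg = np.sum(s * g, axis=-1, keepdims=True)
    return a * g + b * sg * s


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax along ``axis``."""
    x = np.asarray(x, dtype=np.float64)
    if x.size == 0:
        raise ValueError("softmax of an empty vector")
    if not np.all(np.isfinite(x)):
        raise ValueError("softmax input must be finite")
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def margin_loss(y: np.ndarray, y_hat: np.ndarray, m_plus: float = 0.9,
                m_minus: float = 0.1, lambda_down: float = 0.5) -> float:
    """Margin loss Σ_k [y_k max(0, m+−ŷ_k)² + λ(1−y_k) max(0, ŷ_k−m−)²].

    For 2-D inputs (batch × classes) the per-sample losses are averaged.
    """
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y.shape != y_hat.shape:
        raise ValueError(f"shape mismatch: y {y.shape} vs y_hat {y_hat.shape}")
    pos = y * np.maximum(0.0, m_plus - y_hat) ** 2
    neg = lambda_down * (1.0 - y) * np.maximum(0.0, y_hat - m_minus) ** 2
    per_sample = (pos + neg).sum(axis=-1)
    return float(per_sample.mean())


def _margin_loss_grad(y, y_hat, m_plus, m_minus, lambda_down):
    n = y.shape[0] if y.ndim == 2 else 1
    pos = -2.0 * y * np.maximum(0.0, m_plus - y_hat)
    neg = 2.0 * lambda_down * (1.0 - y) * np.maximum(0.0, y_hat - m_minus)
    return (pos + neg) / n


def primary_capsules(features: np.ndarray, config: CapsConfig) -> CapsuleTensor:
    """Reshape a (H,W,C) or (B,H,W,C) feature map into squashed capsules."""
    features = np.asarray(features)
    volume = int(np.prod(features.shape[-3:]))
    d = config.primary_caps_dim
    if volume % d != 0:
        raise ValueError(f"feature volume {volume} not divisible by capsule dim {d}")
    lead = features.shape[:-3]
    u = features.reshape(*lead, volume // d, d)
    return CapsuleTensor(squash(u, config.epsilon))


def dynamic_routing(primaries: CapsuleTensor | np.ndarray, weights: np.ndarray,
                    routing_iterations: int = 3, epsilon: float = 1e-7,
                    return_all: bool = False):
    """Route primary capsules to class capsules by agreement.

    ``weights`` has shape (N, K, O, D): one linear transform per
    (primary, class) pair.  Logits start at zero; each round computes
    coefficients ``c = softmax(logits over classes)``, aggregates
    ``s_j = Σ_i c_ij û_j|i``, squashes to ``v_j`` and (between rounds)
    reinforces logits by the agreement ``û·v``.

    Returns class scores ``‖v_j‖`` (shape (..., K)); with ``return_all`` the
    class-capsule vectors and final coefficients are also returned.
    """
    if routing_iterations < 1:
        raise ValueError("routing_iterations must be >= 1")
    u = primaries.values if isinstance(primaries, CapsuleTensor) else np.asarray(primaries)
    squeeze = u.ndim == 2
    if squeeze:
        u = u[None]
    u_hat = np.einsum("nkod,bnd->bnko", weights, u, optimize=True)
    v, c = _route(u_hat, routing_iterations, epsilon)
    scores = np.linalg.norm(v, axis=-1)
    if squeeze:
        scores, v, c = scores[0], v[0], c[0]
    return (scores, v, c) if return_all else scores


def _route(u_hat: np.ndarray, iterations: int, epsilon: float, cache: list | None = None):
    """Forward routing loop on prediction vectors û (B,N,K,O).

    When ``cache`` is given, per-iteration (c, s, v) tuples are appended so
    :func:`_route_backward` can run the exact reverse-mode sweep.
    """
    b_log = np.zeros(u_hat.shape[:3], dtype=np.float64)
    for it in range(iterations):
        c = softmax(b_log, axis=2)
        s = np.einsum("bnk,bnko->bko", c, u_hat, optimize=True)
        v = squash(s, epsilon)
        if cache is not None:
            cache.append((c, s, v))
        if it < iterations - 1:
            b_log = b_log + np.einsum("bnko,bko->bnk", u_hat, v, optimize=True)
    return v, c


def _route_backward(u_hat: np.ndarray, cache: list, dv_final: np.ndarray,
                    epsilon: float) -> np.ndarray:
    """Exact vector–Jacobian product of the unrolled routing loop.

    Walks the iterations in reverse, propagating gradients through the
    squash, the agreement-weighted sums, the softmax and the logit
    accumulation; returns dL/dû.
    """
    iterations = len(cache)
    du_hat = np.zeros_like(u_hat)
    db_next = None  # dL/db_{t+1}
    dv = dv_final
    for t in range(iterations - 1, -1, -1):
        c, s, v = cache[t]
        if t < iterations - 1:
            # v_t entered b_{t+1} = b_t + û·v_t
            dv = np.einsum("bnk,bnko->bko", db_next, u_hat, optimize=True)
            du_hat += db_next[..., None] * v[:, None, :, :]
        ds = _squash_backward(s, dv, epsilon)
        dc = np.einsum("bko,bnko->bnk", ds, u_hat, optimize=True)
        du_hat += c[..., None] * ds[:, None, :, :]
        # softmax over the class axis
        db = c * (dc - np.sum(dc * c, axis=2, keepdims=True))
        if db_next is not None:
            db = db + db_next  # b_t also feeds b_{t+1} directly
        db_next = db
    return du_hat


# ---------------------------------------------------------------------------
# Network construction
# ---------------------------------------------------------------------------

def _make_stem_layers(cfg: CapsConfig, rng: np.random.Generator):
    return [
        ZeroPad2D("stem_pad1", 3),
        Conv2D("stem_conv", 3, cfg.stem_filters, 7, stride=2, use_bias=False,
               init="glorot", rng=rng),
        BatchNorm2D("stem_bn", cfg.stem_filters),
        ReLU("stem_relu"),
        ZeroPad2D("stem_pad2", 1),
        MaxPool2D("stem_pool", 3, stride=2),
    ]


def _make_dense_layers(cfg: CapsConfig, rng: np.random.Generator):
    """One list of composite layers; each entry is an ordered layer dict."""
    blocks = []
    ch = cfg.stem_filters
    for i in range(cfg.dense_layers):
        mid = 4 * cfg.growth_rate
        blocks.append({
            "bn1": BatchNorm2D(f"dense{i+1}_bn1", ch),
            "relu1": ReLU(f"dense{i+1}_relu1"),
            "conv1x1": Conv2D(f"dense{i+1}_conv1x1", ch, mid, 1, use_bias=False,
                              init="glorot", rng=rng),
            "bn2": BatchNorm2D(f"dense{i+1}_bn2", mid),
            "relu2": ReLU(f"dense{i+1}_relu2"),
            "conv3x3": Conv2D(f"dense{i+1}_conv3x3", mid, cfg.growth_rate, 3,
                              padding="same", use_bias=False, init="glorot", rng=rng),
        })
        ch += cfg.growth_rate
    return blocks


def build_stem(config: CapsConfig | None = None, seed: int = 0) -> NetworkSpec:
    """Architecture trace of the stem alone (shapes and parameter counts)."""
    cfg = config or CapsConfig()
    layers = _make_stem_layers(cfg, np.random.default_rng(seed))
    infos = []
    shape = (cfg.input_size, cfg.input_size, 3)
    for layer in layers:
        shape = layer.out_shape(shape)
        infos.append(LayerInfo(layer.name, layer.kind, shape, layer.param_count))
    return NetworkSpec("capsnet_stem", infos)


class CapsuleNetwork:
    """The full classifier; see the module docstring for the four parts."""

    def __init__(self, config: CapsConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.stem = _make_stem_layers(config, rng)
        self.dense_blocks = _make_dense_layers(config, rng)
        self.post_bn = BatchNorm2D("primary_bn", config.feature_channels)
        self.dropout = Dropout("primary_dropout", config.dropout_rate,
                               rng=np.random.default_rng(rng.integers(0, 2**31 - 1)))
        n, d = config.n_primary_capsules, config.primary_caps_dim
        k, o = config.n_classes, config.class_caps_dim
        # scale so the agreement-weighted sum over N primaries lands in the
        # responsive (non-saturated) range of squash
        std = 3.0 / np.sqrt(n)
        self.routing_w = rng.normal(0.0, std, size=(n, k, o, d))
        self._routing_w_grad = np.zeros_like(self.routing_w)
        self.head = Dense("head_dense", k, k, init="glorot", rng=rng)
        # start the calibration head as a monotone map of the class-capsule
        # norms; cross-entropy training refines it from there
        self.head.params["w"] = (4.0 * np.eye(k)).astype(np.float32)

    def layers(self):
        out = list(self.stem)
        for blk in self.dense_blocks:
            out.extend(blk.values())
        out.extend([self.post_bn, self.dropout, self.head])
        return out

    # -- forward / backward ------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Map (B,H,W,3) inputs to class probabilities (B,K)."""
        cfg = self.config
        h = x.astype(np.float32)
        for layer in self.stem:
            h = layer.forward(h, train)
        for blk in self.dense_blocks:
            z = h
            for key in ("bn1", "relu1", "conv1x1", "bn2", "relu2", "conv3x3"):
                z = blk[key].forward(z, train)
            h = np.concatenate([h, z], axis=-1)
        h = self.post_bn.forward(h, train)
        h = self.dropout.forward(h, train)
        self._feat_shape = h.shape
        u = h.reshape(h.shape[0], cfg.n_primary_capsules, cfg.primary_caps_dim)
        self._u = u.astype(np.float64)
        self._u_sq = squash(self._u, cfg.epsilon)
        self._u_hat = np.einsum("nkod,bnd->bnko", self.routing_w, self._u_sq,
                                optimize=True)
        self._route_cache: list = []
        v, c = _route(self._u_hat, cfg.routing_iterations, cfg.epsilon,
                      cache=self._route_cache)
        self._v, self._c = v, c
        self._norms = np.linalg.norm(v, axis=-1)
        logits = self.head.forward(self._norms, train)
        self._probs = softmax(logits, axis=-1)
        return self._probs

    def backward_margin(self, y_onehot: np.ndarray) -> None:
        """Backprop the training loss from the cached forward pass.

        The margin loss acts on the class-capsule norms (capsule semantics:
        a norm is the class-presence probability), pushing each class's norm
        toward m+/m− independently.  The dense+softmax head is fit jointly by
        cross-entropy on *detached* norms, so it calibrates the reported
        probabilities without feeding back into the capsule body.  The
        routing loop is differentiated exactly (reverse sweep through all
        iterations, including the softmax coefficients).
        """
        cfg = self.config
        # head: cross-entropy on its softmax output, input detached
        dlogits = (self._probs - y_onehot) / len(y_onehot)
        self.head.backward(dlogits.astype(np.float32))
        # body: margin loss on the class-capsule norms
        dnorms = _margin_loss_grad(y_onehot, self._norms, cfg.m_plus,
                                   cfg.m_minus, cfg.lambda_down)
        norm_safe = np.maximum(self._norms, 1e-30)[..., None]
        dv = dnorms[..., None] * self._v / norm_safe
        du_hat = _route_backward(self._u_hat, self._route_cache, dv, cfg.epsilon)
        self._routing_w_grad = np.einsum("bnko,bnd->nkod", du_hat, self._u_sq,
                                         optimize=True)
        du_sq = np.einsum("bnko,nkod->bnd", du_hat, self.routing_w, optimize=True)
        du = _squash_backward(self._u, du_sq, cfg.epsilon)
        g = du.reshape(self._feat_shape).astype(np.float32)
        g = self.dropout.backward(g)
        g = self.post_bn.backward(g)
        for blk in reversed(self.dense_blocks):
            c_in = blk["bn1"].ch
            g_in, g_new = g[..., :c_in], np.ascontiguousarray(g[..., c_in:])
            for key in ("conv3x3", "relu2", "bn2", "conv1x1", "relu1", "bn1"):
                g_new = blk[key].backward(g_new)
            g = np.ascontiguousarray(g_in) + g_new
        for layer in reversed(self.stem):
            g = layer.backward(g)

    # -- architecture trace ------------------------------------------------

    def network_spec(self) -> NetworkSpec:
        cfg = self.config
        infos = []
        shape = (cfg.input_size, cfg.input_size, 3)
        for layer in self.stem:
            shape = layer.out_shape(shape)
            infos.append(LayerInfo(layer.name, layer.kind, shape, layer.param_count))
        for i, blk in enumerate(self.dense_blocks):
            z = shape
            for key in ("bn1", "relu1", "conv1x1", "bn2", "relu2", "conv3x3"):
                z = blk[key].out_shape(z)
                infos.append(LayerInfo(blk[key].name, blk[key].kind, z,
                                       blk[key].param_count))
            shape = (shape[0], shape[1], shape[2] + cfg.growth_rate)
            infos.append(LayerInfo(f"dense{i+1}_concat", "concatenate", shape, 0))
        for layer in (self.post_bn, self.dropout):
            shape = layer.out_shape(shape)
            infos.append(LayerInfo(layer.name, layer.kind, shape, layer.param_count))
        n, d = cfg.n_primary_capsules, cfg.primary_caps_dim
        infos.append(LayerInfo("primary_caps", "primary_capsules", (n, d), 0))
        infos.append(LayerInfo("routing", "dynamic_routing",
                               (cfg.n_classes, cfg.class_caps_dim),
                               self.routing_w.size))
        infos.append(LayerInfo("head_dense", "dense", (cfg.n_classes,),
                               self.head.param_count))
        infos.append(LayerInfo("head_softmax", "softmax", (cfg.n_classes,), 0))
        return NetworkSpec("capsnet", infos)


def build_capsnet(config: CapsConfig | None = None, seed: int = 0) -> CapsuleNetwork:
    """Construct the capsule classifier with Glorot-normal-initialized weights."""
    return CapsuleNetwork(config or CapsConfig(), seed=seed)


# ---------------------------------------------------------------------------
# Training / inference
# ---------------------------------------------------------------------------

def _one_hot(labels: list[Label], k: int) -> np.ndarray:
    idx = [CLASS_ORDER.index(Label(l)) for l in labels]
    y = np.zeros((len(idx), k))
    y[np.arange(len(idx)), idx] = 1.0
    return y


def _dihedral(batch: np.ndarray, ops: np.ndarray) -> np.ndarray:
    """Apply one of the 8 axis-aligned flips/rotations to each image."""
    out = np.empty_like(batch)
    for i, op in enumerate(ops):
        img = batch[i]
        if op >= 4:
            img = img[:, ::-1]
        out[i] = np.rot90(img, k=op % 4, axes=(0, 1))
    return out


def train_classifier(model: CapsuleNetwork, data: list[tuple[np.ndarray, Label]],
                     tc: "TrainConfig", augment: bool = True):
    """Train on (3-channel image, benign/malignant label) pairs with Adam.

    Returns per-epoch history (margin loss, training accuracy).  ``normal``
    labels are rejected: the classifier is binary.  With ``augment``, half
    of each batch (in expectation) is passed through a random axis-aligned
    flip/rotation (lesion morphology is orientation-free, so the 8 dihedral
    transforms are label-preserving); the other half stays untransformed,
    which keeps short training runs easy to fit while still regularizing.
    """
    if not data:
        raise ValueError("empty training dataset")
    labels = [Label(l) for _, l in data]
    bad = [l for l in labels if l not in CLASS_ORDER]
    if bad:
        raise ValueError(f"classifier is binary (benign/malignant); got {bad[0].value!r}")
    cfg = model.config
    size = cfg.input_size
    x = np.stack([np.asarray(img, dtype=np.float32) for img, _ in data])
    if x.shape[1:] != (size, size, 3):
        raise ValueError(f"inputs must be {size}x{size}x3, got {x.shape[1:]}")
    y = _one_hot(labels, cfg.n_classes)
    rng = np.random.default_rng(tc.seed)
    model.dropout.rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
    opt = Adam(model.layers(), lr=tc.learning_rate)
    history = []
    for epoch in range(tc.epochs):
        order = rng.permutation(len(data))
        losses, hits, seen = [], 0, 0
        for start in range(0, len(data), tc.batch_size):
            idx = order[start : start + tc.batch_size]
            xb = x[idx]
            if augment:
                ops = rng.integers(0, 8, size=len(idx))
                ops = np.where(rng.random(len(idx)) < 0.5, ops, 0)
                xb = _dihedral(xb, ops)
            p = model.forward(xb, train=True)
            losses.append(margin_loss(y[idx], model._norms, cfg.m_plus,
                                      cfg.m_minus, cfg.lambda_down))
            hits += int((p.argmax(axis=1) == y[idx].argmax(axis=1)).sum())
            seen += len(idx)
            model.backward_margin(y[idx])
            opt.step()
            # plain gradient descent for the routing transform: Adam's
            # scale-free per-parameter steps move the aggregated s_j by
            # O(N * lr) when the per-capsule gradients are coherent, which
            # drives the squash into saturation
            model.routing_w -= ROUTING_LR_MULT * tc.learning_rate * model._routing_w_grad
        history.append({"epoch": epoch + 1, "loss": float(np.mean(losses)),
                        "accuracy": hits / seen})
    return history


def predict_class(model: CapsuleNetwork, image: np.ndarray) -> tuple[Label, np.ndarray]:
    """Classify one 3-channel input; returns (label, class probabilities)."""
    image = np.asarray(image, dtype=np.float32)
    size = model.config.input_size
    if image.shape != (size, size, 3):
        raise ValueError(f"expected a {size}x{size}x3 input, got {image.shape}")
    p = model.forward(image[None], train=False)[0]
    return CLASS_ORDER[int(p.argmax())], p
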