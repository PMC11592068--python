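"""Minimal numpy neural-network layers with explicit backprop.

All tensors are channels-last ``(batch, height, width, channels)`` float32.
Each layer caches what its backward pass needs during ``forward`` and exposes
``params`` / ``grads`` dicts of same-shaped arrays so an optimizer can update
in place.  ``param_count`` includes non-trainable state (batch-norm moving
statistics), matching framework summary conventions.

The library implements exactly what the segmentation and capsule models here
need; it is not a general autodiff system.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


def glorot_normal(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / (fan_in + fan_out)), size=shape).astype(np.float32)


class Layer:
    kind = "layer"

    def __init__(self, name: str):
        self.name = name
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        # parameters that exist but receive no gradient (e.g. BN moving stats)
        self.n_untrained = 0

    @property
    def param_count(self) -> int:
        return sum(p.size for p in self.params.values()) + self.n_untrained

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class ZeroPad2D(Layer):
    kind = "zero_padding"

    def __init__(self, name: str, pad: int):
        super().__init__(name)
        self.pad = pad

    def out_shape(self, s):
        return (s[0] + 2 * self.pad, s[1] + 2 * self.pad, s[2])

    def forward(self, x, train=False):
        p = self.pad
        return np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))

    def backward(self, g):
        p = self.pad
        return g[:, p:-p, p:-p, :]


class Conv2D(Layer):
    """2-D convolution via sliding windows + tensordot.

    ``padding`` is 'same' (stride-1 size-preserving) or 'valid'.
    """

    kind = "conv2d"

    def __init__(self, name, in_ch, out_ch, kernel, stride=1, padding="valid",
                 use_bias=True, init="he", rng=None):
        super().__init__(name)
        self.in_ch, self.out_ch = in_ch, out_ch
        self.k, self.stride, self.padding = kernel, stride, padding
        fan_in = kernel * kernel * in_ch
        fan_out = kernel * kernel * out_ch
        rng = rng or np.random.default_rng(0)
        shape = (kernel, kernel, in_ch, out_ch)
        if init == "he":
            w = he_normal(rng, shape, fan_in)
        elif init == "glorot":
            w = glorot_normal(rng, shape, fan_in, fan_out)
        elif init == "zeros":
            w = np.zeros(shape, dtype=np.float32)
        else:
            raise ValueError(f"unknown init {init!r}")
        self.params["w"] = w
        if use_bias:
            self.params["b"] = np.zeros(out_ch, dtype=np.float32)

    def _pad_width(self):
        if self.padding == "same":
            if self.stride != 1:
                raise ValueError("'same' padding implemented for stride 1 only")
            return self.k // 2
        return 0

    def out_shape(self, s):
        p = self._pad_width()
        h = (s[0] + 2 * p - self.k) // self.stride + 1
        w = (s[1] + 2 * p - self.k) // self.stride + 1
        return (h, w, self.out_ch)

    def forward(self, x, train=False):
        p = self._pad_width()
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        self._in_shape = xp.shape
        k = self.k
        win = sliding_window_view(xp, (k, k), axis=(1, 2))
        win = win[:, :: self.stride, :: self.stride]  # (B,Ho,Wo,C,k,k)
        # materialize the im2col columns once, in the (k,k,C) order of the
        # weight layout; the same buffer serves the weight gradient
        self._out_hw = win.shape[1:3]
        cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3))
        self._cols = cols.reshape(-1, k * k * self.in_ch)
        out = self._cols @ self.params["w"].reshape(-1, self.out_ch)
        out = out.reshape(len(x), *self._out_hw, self.out_ch)
        if "b" in self.params:
            out += self.params["b"]
        return out

    def backward(self, g):
        w = self.params["w"]
        k = self.k
        g2d = g.reshape(-1, self.out_ch)
        dw = self._cols.T @ g2d  # (k*k*C, F)
        self.grads["w"] = dw.reshape(k, k, self.in_ch, self.out_ch)
        if "b" in self.params:
            self.grads["b"] = g2d.sum(axis=0)
        B, Ho, Wo, _ = g.shape
        s = self.stride
        dxp = np.zeros(self._in_shape, dtype=np.float32)
        for i in range(k):
            for j in range(k):
                # out[b,h,w,f] consumed xp[b, h*s+i, w*s+j, c] * w[i,j,c,f]
                dxp[:, i : i + Ho * s : s, j : j + Wo * s : s, :] += g @ w[i, j].T
        p = self._pad_width()
        self._cols = None
        return dxp[:, p : dxp.shape[1] - p, p : dxp.shape[2] - p, :] if p else dxp


class ConvTranspose2D(Layer):
    """Transpose convolution with kernel == stride (exact integer upsample)."""

    kind = "conv2d_transpose"

    def __init__(self, name, in_ch, out_ch, kernel=2, init="he", rng=None):
        super().__init__(name)
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, kernel
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch  # each output pixel sees one input pixel per channel
        shape = (kernel, kernel, in_ch, out_ch)
        self.params["w"] = he_normal(rng, shape, fan_in) if init == "he" else glorot_normal(
            rng, shape, fan_in, kernel * kernel * out_ch
        )
        self.params["b"] = np.zeros(out_ch, dtype=np.float32)

    def out_shape(self, s):
        return (s[0] * self.k, s[1] * self.k, self.out_ch)

    def forward(self, x, train=False):
        self._x = x
        B, H, W, _ = x.shape
        k = self.k
        y = np.einsum("bhwc,ijcf->bhiwjf", x, self.params["w"], optimize=True)
        y = y.reshape(B, H * k, W * k, self.out_ch) + self.params["b"]
        return y.astype(np.float32)

    def backward(self, g):
        B, Hk, Wk, F = g.shape
        k = self.k
        g6 = g.reshape(B, Hk // k, k, Wk // k, k, F)
        self.grads["w"] = np.einsum("bhwc,bhiwjf->ijcf", self._x, g6, optimize=True)
        self.grads["b"] = g.sum(axis=(0, 1, 2))
        dx = np.einsum("bhiwjf,ijcf->bhwc", g6, self.params["w"], optimize=True)
        self._x = None
        return dx.astype(np.float32)


class BatchNorm2D(Layer):
    """Batch normalization over (B,H,W) per channel.

    Stores gamma/beta (trained) plus moving mean/variance (untrained), so
    ``param_count`` is 4 per channel.
    """

    kind = "batch_norm"

    # momentum 0.9: moving stats must converge within the short training
    # runs this library targets (~10^2 steps)
    def __init__(self, name, ch, momentum=0.9, eps=1e-3):
        super().__init__(name)
        self.ch, self.momentum, self.eps = ch, momentum, eps
        self.params["gamma"] = np.ones(ch, dtype=np.float32)
        self.params["beta"] = np.zeros(ch, dtype=np.float32)
        self.moving_mean = np.zeros(ch, dtype=np.float32)
        self.moving_var = np.ones(ch, dtype=np.float32)
        self.n_untrained = 2 * ch

    def out_shape(self, s):
        return tuple(s)

    def forward(self, x, train=False):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.moving_mean = (m * self.moving_mean + (1 - m) * mean).astype(np.float32)
            self.moving_var = (m * self.moving_var + (1 - m) * var).astype(np.float32)
        else:
            mean, var = self.moving_mean, self.moving_var
        self._inv = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        self._xhat = ((x - mean) * self._inv).astype(np.float32)
        self._n = int(np.prod([x.shape[a] for a in axes])) if train else 0
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, g):
        axes = tuple(range(g.ndim - 1))
        xhat, inv = self._xhat, self._inv
        self.grads["gamma"] = (g * xhat).sum(axis=axes)
        self.grads["beta"] = g.sum(axis=axes)
        gg = g * self.params["gamma"]
        if self._n:
            n = self._n
            dx = (gg - gg.mean(axis=axes) - xhat * (gg * xhat).sum(axis=axes) / n) * inv
        else:  # inference-mode stats are constants
            dx = gg * inv
        self._xhat = None
        return dx.astype(np.float32)


class ReLU(Layer):
    kind = "relu"

    def out_shape(self, s):
        return tuple(s)

    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, g):
        out = np.where(self._mask, g, 0.0).astype(np.float32)
        self._mask = None
        return out


class MaxPool2D(Layer):
    kind = "max_pool"

    def __init__(self, name, pool, stride=None):
        super().__init__(name)
        self.k = pool
        self.stride = stride or pool

    def out_shape(self, s):
        h = (s[0] - self.k) // self.stride + 1
        w = (s[1] - self.k) // self.stride + 1
        return (h, w, s[2])

    def forward(self, x, train=False):
        win = sliding_window_view(x, (self.k, self.k), axis=(1, 2))
        win = win[:, :: self.stride, :: self.stride]  # (B,Ho,Wo,C,k,k)
        B, Ho, Wo, C = win.shape[:4]
        flat = win.reshape(B, Ho, Wo, C, self.k * self.k)
        self._arg = flat.argmax(axis=-1)
        self._in_shape = x.shape
        return flat.max(axis=-1)

    def backward(self, g):
        B, Ho, Wo, C = g.shape
        dx = np.zeros(self._in_shape, dtype=np.float32)
        bb, hh, ww, cc = np.indices((B, Ho, Wo, C), sparse=False)
        di, dj = self._arg // self.k, self._arg % self.k
        np.add.at(dx, (bb, hh * self.stride + di, ww * self.stride + dj, cc), g)
        self._arg = None
        return dx


class Dropout(Layer):
    kind = "dropout"

    def __init__(self, name, rate, rng=None):
        super().__init__(name)
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0,1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)

    def out_shape(self, s):
        return tuple(s)

    def forward(self, x, train=False):
        if not train or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return (x * self._mask).astype(np.float32)

    def backward(self, g):
        if self._mask is None:
            return g
        out = (g * self._mask).astype(np.float32)
        self._mask = None
        return out


class Dense(Layer):
    kind = "dense"

    def __init__(self, name, n_in, n_out, init="glorot", rng=None):
        super().__init__(name)
        rng = rng or np.random.default_rng(0)
        if init == "glorot":
            self.params["w"] = glorot_normal(rng, (n_in, n_out), n_in, n_out)
        elif init == "he":
            self.params["w"] = he_normal(rng, (n_in, n_out), n_in)
        else:
            raise ValueError(f"unknown init {init!r}")
        self.params["b"] = np.zeros(n_out, dtype=np.float32)

    def out_shape(self, s):
        return (self.params["w"].shape[1],)

    def forward(self, x, train=False):
        self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, g):
        self.grads["w"] = self._x.T @ g
        self.grads["b"] = g.sum(axis=0)
        dx = g @ self.params["w"].T
        self._x = None
        return dx.astype(np.float32)
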