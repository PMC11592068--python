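"""Adam optimizer over the layer library's in-place parameter dicts."""

from __future__ import annotations

import numpy as np

from .layers import Layer


class Adam:
    def __init__(self, layers: list[Layer], lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.layers = [l for l in layers if l.params]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]
        self._v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        corr = self.lr * np.sqrt(1 - b2 ** self.t) / (1 - b1 ** self.t)
        for l, m, v in zip(self.layers, self._m, self._v):
            for k, p in l.params.items():
                g = l.grads.get(k)
                if g is None:
                    continue
                m[k] = b1 * m[k] + (1 - b1) * g
                v[k] = b2 * v[k] + (1 - b2) * g * g
                p -= corr * m[k] / (np.sqrt(v[k]) + self.eps)
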