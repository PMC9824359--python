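"""Adam optimizer."""

from __future__ import annotations

import numpy as np


class Adam:
    """Adam with bias correction (beta1 0.9, beta2 0.999, eps 1e-7)."""

    def __init__(self, learning_rate: float = 0.0001, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        self.lr = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m: dict[int, dict[str, np.ndarray]] = {}
        self._v: dict[int, dict[str, np.ndarray]] = {}

    def step(self, layers) -> None:
        """Apply one update to every parameter of every layer with gradients."""
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for layer in layers:
            if not layer.params:
                continue
            key = id(layer)
            m = self._m.setdefault(key, {})
            v = self._v.setdefault(key, {})
            for name, p in layer.params.items():
                g = layer.grads.get(name)
                if g is None:
                    continue
                if name not in m:
                    m[name] = np.zeros_like(p)
                    v[name] = np.zeros_like(p)
                m[name] = self.beta1 * m[name] + (1.0 - self.beta1) * g
                v[name] = self.beta2 * v[name] + (1.0 - self.beta2) * (g * g)
                mhat = m[name] / b1t
                vhat = v[name] / b2t
                p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
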