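"""Masked LSTM layer with full backpropagation through time.

Gate order follows the common i, f, g (cell candidate), o convention with
tanh cell activation and sigmoid gate activation.  Masked time steps are
skipped: state (h, c) is carried through unchanged, so the output at the
last step equals the hidden state after the last valid step regardless of
how many trailing padding windows follow.
"""

from __future__ import annotations

import numpy as np

from repscore.nn.init import glorot_uniform
from repscore.nn.layers import Layer


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class MaskedLSTM(Layer):
    """LSTM over (N, T, D) inputs with a per-step boolean mask (N, T).

    Returns the full output sequence (N, T, units); at masked steps the
    previous hidden state is repeated.  All weights use Glorot uniform
    initialization; the forget-gate bias starts at 1.
    """

    def __init__(self, input_dim: int, units: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.input_dim = input_dim
        self.units = units
        self.dtype = dtype
        u = units
        self.params["W"] = glorot_uniform(rng, (input_dim, 4 * u), input_dim, 4 * u, dtype)
        self.params["R"] = glorot_uniform(rng, (u, 4 * u), u, 4 * u, dtype)
        b = np.zeros(4 * u, dtype=dtype)
        b[u : 2 * u] = 1.0  # forget-gate bias
        self.params["b"] = b

    def forward(self, x: np.ndarray, mask: np.ndarray | None = None, training: bool = False) -> np.ndarray:
        n, t, d = x.shape
        u = self.units
        if mask is None:
            mask = np.ones((n, t), dtype=bool)
        W, R, b = self.params["W"], self.params["R"], self.params["b"]
        h = np.zeros((n, u), dtype=self.dtype)
        c = np.zeros((n, u), dtype=self.dtype)
        outputs = np.zeros((n, t, u), dtype=self.dtype)
        cache = []
        for step in range(t):
            m = mask[:, step].astype(self.dtype)[:, None]
            z = x[:, step, :] @ W + h @ R + b
            i = _sigmoid(z[:, :u])
            f = _sigmoid(z[:, u : 2 * u])
            g = np.tanh(z[:, 2 * u : 3 * u])
            o = _sigmoid(z[:, 3 * u :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            cache.append((x[:, step, :], h, c, i, f, g, o, tc, m))
            h = m * h_new + (1.0 - m) * h
            c = m * c_new + (1.0 - m) * c
            outputs[:, step, :] = h
        self._cache = cache
        self._mask = mask
        return outputs

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, t, u = grad.shape
        W, R = self.params["W"], self.params["R"]
        dW = np.zeros_like(W)
        dR = np.zeros_like(R)
        db = np.zeros_like(self.params["b"])
        dx = np.zeros((n, t, self.input_dim), dtype=self.dtype)
        dh = np.zeros((n, u), dtype=self.dtype)
        dc = np.zeros((n, u), dtype=self.dtype)
        for step in reversed(range(t)):
            x_t, h_prev, c_prev, i, f, g, o, tc, m = self._cache[step]
            dh = dh + grad[:, step, :]
            # gradients through the (unmasked) LSTM cell
            do = dh * tc * o * (1.0 - o)
            dct = dh * o * (1.0 - tc * tc) + dc
            di = dct * g * i * (1.0 - i)
            df = dct * c_prev * f * (1.0 - f)
            dg = dct * i * (1.0 - g * g)
            dz = np.concatenate([di, df, dg, do], axis=1) * m
            dW += x_t.T @ dz
            dR += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, step, :] = dz @ W.T
            dh_cell = dz @ R.T
            dc_cell = dct * f
            # masked samples pass state gradients straight through
            dh = m * dh_cell + (1.0 - m) * dh
            dc = m * dc_cell + (1.0 - m) * dc
        self.grads["W"] = dW
        self.grads["R"] = dR
        self.grads["b"] = db
        return dx
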