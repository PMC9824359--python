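"""Feed-forward layers with hand-derived backward passes.

Every layer exposes ``forward(x, training)`` and ``backward(grad)``;
trainable arrays live in ``params`` with matching entries in ``grads``.
Inputs to convolution/pooling layers have shape (N, C, H, W).
"""

from __future__ import annotations

import numpy as np

from repscore.nn.init import glorot_uniform


class Layer:
    """Base layer: parameter/gradient registry plus no-op passes."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))


def _activation_forward(name: str, z: np.ndarray) -> np.ndarray:
    if name == "linear":
        return z
    if name == "relu":
        return np.maximum(z, 0.0)
    if name == "elu":
        return np.where(z > 0, z, np.expm1(np.minimum(z, 0.0)))
    if name == "lrelu":
        return np.where(z > 0, z, 0.3 * z)
    raise ValueError(f"unknown activation {name!r}")


def _activation_backward(name: str, z: np.ndarray, out: np.ndarray, grad: np.ndarray) -> np.ndarray:
    if name == "linear":
        return grad
    if name == "relu":
        return grad * (z > 0)
    if name == "elu":
        # d/dz elu = 1 for z > 0, exp(z) = out + 1 otherwise
        return grad * np.where(z > 0, 1.0, out + 1.0)
    if name == "lrelu":
        return grad * np.where(z > 0, 1.0, 0.3)
    raise ValueError(f"unknown activation {name!r}")


class Activation(Layer):
    def __init__(self, name: str):
        super().__init__()
        self.name = name

    def forward(self, x, training=False):
        self._z = x
        self._out = _activation_forward(self.name, x)
        return self._out

    def backward(self, grad):
        return _activation_backward(self.name, self._z, self._out, grad)


class Conv2D(Layer):
    """2-D convolution with "same" spatial padding (odd kernels only).

    Weight shape (F, C, kh, kw).  Implemented as a sum of kernel-offset
    GEMMs, which keeps memory bounded for the wide channel-row inputs used
    here.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: tuple[int, int],
                 rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        kh, kw = kernel
        if kh % 2 == 0 or kw % 2 == 0:
            raise ValueError("same padding requires odd kernel dimensions")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = (kh, kw)
        self.dtype = dtype
        fan_in = in_channels * kh * kw
        fan_out = out_channels * kh * kw
        self.params["W"] = glorot_uniform(rng, (out_channels, in_channels, kh, kw), fan_in, fan_out, dtype)
        self.params["b"] = np.zeros(out_channels, dtype=dtype)

    def forward(self, x, training=False):
        kh, kw = self.kernel
        ph, pw = kh // 2, kw // 2
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
        self._xp = xp
        self._in_shape = x.shape
        out = np.zeros((n, self.out_channels, h, w), dtype=self.dtype)
        W = self.params["W"]
        for i in range(kh):
            for j in range(kw):
                patch = xp[:, :, i : i + h, j : j + w]
                out += np.einsum("nchw,fc->nfhw", patch, W[:, :, i, j], optimize=True)
        out += self.params["b"][None, :, None, None]
        return out

    def backward(self, grad):
        kh, kw = self.kernel
        n, c, h, w = self._in_shape
        W = self.params["W"]
        dW = np.zeros_like(W)
        dxp = np.zeros_like(self._xp)
        for i in range(kh):
            for j in range(kw):
                patch = self._xp[:, :, i : i + h, j : j + w]
                dW[:, :, i, j] = np.einsum("nfhw,nchw->fc", grad, patch, optimize=True)
                dxp[:, :, i : i + h, j : j + w] += np.einsum(
                    "nfhw,fc->nchw", grad, W[:, :, i, j], optimize=True
                )
        self.grads["W"] = dW
        self.grads["b"] = grad.sum(axis=(0, 2, 3))
        ph, pw = kh // 2, kw // 2
        return dxp[:, :, ph : ph + h, pw : pw + w]


class MaxPool2D(Layer):
    """(2, 2) max pooling with per-axis clipping.

    An axis shorter than 2 is not pooled; otherwise stride-2 pooling with the
    trailing remainder dropped (floor semantics), so 6 -> 3 -> 1 over two
    blocks.
    """

    def __init__(self, pool: tuple[int, int] = (2, 2)):
        super().__init__()
        self.pool = pool

    @staticmethod
    def output_size(h: int, w: int, pool: tuple[int, int] = (2, 2)) -> tuple[int, int]:
        ph = pool[0] if h >= pool[0] else 1
        pw = pool[1] if w >= pool[1] else 1
        return h // ph, w // pw

    def forward(self, x, training=False):
        n, c, h, w = x.shape
        ph = self.pool[0] if h >= self.pool[0] else 1
        pw = self.pool[1] if w >= self.pool[1] else 1
        h2, w2 = h // ph, w // pw
        self._geom = (x.shape, ph, pw, h2, w2)
        crop = x[:, :, : h2 * ph, : w2 * pw]
        blocks = crop.reshape(n, c, h2, ph, w2, pw).transpose(0, 1, 2, 4, 3, 5)
        flat = blocks.reshape(n, c, h2, w2, ph * pw)
        self._argmax = flat.argmax(axis=-1)
        return flat.max(axis=-1)

    def backward(self, grad):
        (in_shape, ph, pw, h2, w2) = self._geom
        n, c, h, w = in_shape
        flat = np.zeros((n, c, h2, w2, ph * pw), dtype=grad.dtype)
        np.put_along_axis(flat, self._argmax[..., None], grad[..., None], axis=-1)
        blocks = flat.reshape(n, c, h2, w2, ph, pw).transpose(0, 1, 2, 4, 3, 5)
        dx = np.zeros(in_shape, dtype=grad.dtype)
        dx[:, :, : h2 * ph, : w2 * pw] = blocks.reshape(n, c, h2 * ph, w2 * pw)
        return dx


class Dropout(Layer):
    """Inverted dropout; identity outside training."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class BatchNorm(Layer):
    """Per-channel batch normalization over (N, H, W) for (N, C, H, W) inputs."""

    def __init__(self, channels: int, momentum: float = 0.99, eps: float = 1e-3, dtype=np.float32):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.params["gamma"] = np.ones(channels, dtype=dtype)
        self.params["beta"] = np.zeros(channels, dtype=dtype)
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)

    def forward(self, x, training=False):
        axes = (0, 2, 3)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean = self.running_mean.astype(x.dtype)
            var = self.running_var.astype(x.dtype)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, training, x.shape)
        return self.params["gamma"][None, :, None, None] * xhat + self.params["beta"][None, :, None, None]

    def backward(self, grad):
        xhat, inv, training, shape = self._cache
        axes = (0, 2, 3)
        self.grads["gamma"] = (grad * xhat).sum(axis=axes)
        self.grads["beta"] = grad.sum(axis=axes)
        g = self.params["gamma"][None, :, None, None]
        if not training:
            return grad * g * inv[None, :, None, None]
        m = shape[0] * shape[2] * shape[3]
        dxhat = grad * g
        dx = (
            dxhat
            - dxhat.mean(axis=axes, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=axes, keepdims=True)
        ) * inv[None, :, None, None]
        return dx


class Dense(Layer):
    """Fully connected layer with optional built-in activation."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 activation: str = "linear", dtype=np.float32):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        self.activation = activation
        self.params["W"] = glorot_uniform(rng, (in_features, out_features), in_features, out_features, dtype)
        self.params["b"] = np.zeros(out_features, dtype=dtype)

    def forward(self, x, training=False):
        self._x = x
        self._z = x @ self.params["W"] + self.params["b"]
        self._out = _activation_forward(self.activation, self._z)
        return self._out

    def backward(self, grad):
        dz = _activation_backward(self.activation, self._z, self._out, grad)
        self.grads["W"] = self._x.T @ dz
        self.grads["b"] = dz.sum(axis=0)
        return dz @ self.params["W"].T
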