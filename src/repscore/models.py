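"""CNN-LSTM architecture variants.

Three variants share one skeleton: a stack of CNN-blocks (convolution +
(2, 2) max-pooling + dropout-0.2 or batch normalization) applied identically
to every temporal window of a repetition (shared weights), a masked
recurrent stage of one or two 256-unit LSTM layers, and a 512 -> 128 -> 3
dense head with softmax output.

- ``baseline``: one stream over the full channel-row matrix, square kernels
  ((5,5)x3 for the fixed scheme, (9,9)/(5,5)/(3,3) for the decreasing one).
- ``imu_centric``: one convolutional branch per IMU over its 6 channel rows,
  kernels (1,5); per-window branch outputs are concatenated before the LSTM.
- ``channel_centric``: like baseline but convolving along time only with
  (1,5) kernels shared across all channel rows.

Filter counts are the first ``n_blocks`` of [16, 32, 64].  Convolutions use
"same" spatial padding; pooling clips to size 1 on axes shorter than 2.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict

import numpy as np

from repscore.nn.layers import Activation, BatchNorm, Conv2D, Dense, Dropout, Layer, MaxPool2D
from repscore.nn.losses import softmax
from repscore.nn.lstm import MaskedLSTM

__all__ = [
    "CnnBlockSpec",
    "ArchitectureConfig",
    "resolve_blocks",
    "build_model",
    "describe_model",
    "ModelHandle",
]

VARIANTS = ("baseline", "imu_centric", "channel_centric")
SCHEMES = ("fixed_kernel", "decreasing_kernel")
ACTIVATIONS = ("relu", "elu", "lrelu")
REGULARIZERS = ("dropout_0.2", "batch_norm")

FILTER_PROGRESSION = (16, 32, 64)
FIXED_KERNELS = ((5, 5), (5, 5), (5, 5))
DECREASING_KERNELS = ((9, 9), (5, 5), (3, 3))
TIME_ONLY_KERNEL = (1, 5)

_ACTIVATION_ALIASES = {"relu": "relu", "elu": "elu", "lrelu": "lrelu", "leakyrelu": "lrelu"}


def canonical_activation(name: str) -> str:
    key = name.lower().replace("_", "")
    if key not in _ACTIVATION_ALIASES:
        raise ValueError(f"unknown activation {name!r}; expected one of {ACTIVATIONS}")
    return _ACTIVATION_ALIASES[key]


@dataclass(frozen=True)
class CnnBlockSpec:
    """One CNN-block: convolution, (2, 2) max-pooling (clipped), regularizer."""

    n_filters: int
    kernel: tuple[int, int]
    pool: tuple[int, int] = (2, 2)
    regularizer: str = "dropout_0.2"

    def __post_init__(self) -> None:
        if self.n_filters <= 0:
            raise ValueError("n_filters must be positive")
        if self.kernel[0] < 1 or self.kernel[1] < 1:
            raise ValueError("kernel dimensions must be >= 1")
        if self.regularizer not in REGULARIZERS:
            raise ValueError(f"regularizer must be one of {REGULARIZERS}")


@dataclass
class ArchitectureConfig:
    """Full architecture + training-setting description of one model.

    Fixed constants (LSTM units 256, dense 512/128/3, softmax output, tanh /
    sigmoid LSTM activations, Glorot uniform initialization, learning rate
    0.0001, categorical cross-entropy) are fields so they are recorded in
    serialized configs, but changing them steps outside the studied design.
    """

    variant: str = "baseline"
    n_blocks: int = 3
    scheme: str = "fixed_kernel"
    activation: str = "elu"
    regularizer: str = "dropout_0.2"
    n_lstm_layers: int = 2
    lstm_units: int = 256
    dense_units: tuple[int, ...] = (512, 128, 3)
    output_activation: str = "softmax"
    lstm_activation: str = "tanh"
    lstm_recurrent_activation: str = "sigmoid"
    weight_init: str = "glorot_uniform"
    batch_size: int = 32
    learning_rate: float = 0.0001
    loss: str = "categorical_cross_entropy"

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.n_blocks not in (1, 2, 3):
            raise ValueError("n_blocks must be 1, 2 or 3")
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}")
        self.activation = canonical_activation(self.activation)
        if self.regularizer not in REGULARIZERS:
            raise ValueError(f"regularizer must be one of {REGULARIZERS}")
        if self.n_lstm_layers not in (1, 2):
            raise ValueError("n_lstm_layers must be 1 or 2")
        if self.batch_size not in (4, 8, 16, 32):
            raise ValueError("batch_size must be one of 4, 8, 16, 32")
        if tuple(self.dense_units)[-1] != 3:
            raise ValueError("output layer must have 3 units (one per class)")
        self.dense_units = tuple(self.dense_units)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["dense_units"] = list(self.dense_units)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureConfig":
        d = dict(d)
        if "dense_units" in d:
            d["dense_units"] = tuple(d["dense_units"])
        return cls(**d)


def resolve_blocks(scheme: str, n_blocks: int, variant: str,
                   regularizer: str = "dropout_0.2") -> list[CnnBlockSpec]:
    """Expand (scheme, n_blocks, variant) into concrete CNN-block specs.

    Baseline uses square kernels per the scheme; the IMU-centric and
    channel-centric variants always convolve along time only with (1, 5)
    kernels, regardless of scheme.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be one of {SCHEMES}")
    if n_blocks not in (1, 2, 3):
        raise ValueError("n_blocks must be in 1..3")
    filters = FILTER_PROGRESSION[:n_blocks]
    if variant in ("imu_centric", "channel_centric"):
        kernels = (TIME_ONLY_KERNEL,) * n_blocks
    elif scheme == "fixed_kernel":
        kernels = FIXED_KERNELS[:n_blocks]
    else:
        kernels = DECREASING_KERNELS[:n_blocks]
    return [
        CnnBlockSpec(n_filters=f, kernel=k, regularizer=regularizer)
        for f, k in zip(filters, kernels)
    ]


class _ConvBranch:
    """A window-shared CNN-block stack over one input stream."""

    def __init__(self, blocks: list[CnnBlockSpec], in_shape: tuple[int, int],
                 activation: str, rng: np.random.Generator, dropout_rng: np.random.Generator,
                 dtype=np.float32, name: str = "branch"):
        self.name = name
        self.layers: list[Layer] = []
        self.inventory: list[dict] = []
        h, w = in_shape
        in_ch = 1
        for bi, spec in enumerate(blocks):
            conv = Conv2D(in_ch, spec.n_filters, spec.kernel, rng, dtype)
            self.layers.append(conv)
            self.layers.append(Activation(activation))
            self.inventory.append(
                {
                    "name": f"{name}_conv{bi + 1}",
                    "type": "Conv2D",
                    "filters": spec.n_filters,
                    "kernel": list(spec.kernel),
                    "activation": activation,
                    "output_shape": [spec.n_filters, h, w],
                    "n_params": conv.n_params(),
                }
            )
            h, w = MaxPool2D.output_size(h, w, spec.pool)
            self.layers.append(MaxPool2D(spec.pool))
            self.inventory.append(
                {
                    "name": f"{name}_pool{bi + 1}",
                    "type": "MaxPool2D",
                    "pool": list(spec.pool),
                    "output_shape": [spec.n_filters, h, w],
                    "n_params": 0,
                }
            )
            if spec.regularizer == "dropout_0.2":
                self.layers.append(Dropout(0.2, dropout_rng))
                self.inventory.append(
                    {"name": f"{name}_dropout{bi + 1}", "type": "Dropout", "rate": 0.2,
                     "output_shape": [spec.n_filters, h, w], "n_params": 0}
                )
            else:
                bn = BatchNorm(spec.n_filters, dtype=dtype)
                self.layers.append(bn)
                self.inventory.append(
                    {"name": f"{name}_batchnorm{bi + 1}", "type": "BatchNorm",
                     "output_shape": [spec.n_filters, h, w], "n_params": bn.n_params()}
                )
            in_ch = spec.n_filters
        self.out_shape = (in_ch, h, w)
        self.n_features = in_ch * h * w

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        out = x
        for layer in self.layers:
            out = layer.forward(out, training=training)
        self._out_full = out.shape
        return out.reshape(out.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = grad.reshape(self._out_full)
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g


class ModelHandle:
    """A built, trainable CNN-LSTM model.

    Inputs to :meth:`forward` are the full windowed arrays of shape
    (B, X, C, W) plus a boolean mask (B, X); the IMU-centric variant slices
    its per-IMU streams internally (6 channel rows per IMU).
    """

    def __init__(self, config: ArchitectureConfig, input_shape: tuple[int, int, int],
                 seed: int = 0, dtype=np.float32):
        x_windows, c_rows, w_len = input_shape
        self.config = config
        self.input_shape = tuple(input_shape)
        self.dtype = dtype
        self.seed = seed
        min_w = 2 ** config.n_blocks
        if w_len < min_w:
            raise ValueError(
                f"window length {w_len} too small for {config.n_blocks} pooling stages; "
                f"minimal admissible window length is {min_w}"
            )
        rng = np.random.default_rng(seed)
        self.dropout_rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
        blocks = resolve_blocks(config.scheme, config.n_blocks, config.variant, config.regularizer)
        self.branches: list[_ConvBranch] = []
        if config.variant == "imu_centric":
            if c_rows % 6 != 0:
                raise ValueError("imu_centric variant needs a multiple of 6 channel rows")
            self.n_imus = c_rows // 6
            for k in range(self.n_imus):
                self.branches.append(
                    _ConvBranch(blocks, (6, w_len), config.activation, rng,
                                self.dropout_rng, dtype, name=f"imu{k}")
                )
        else:
            self.n_imus = None
            self.branches.append(
                _ConvBranch(blocks, (c_rows, w_len), config.activation, rng,
                            self.dropout_rng, dtype, name="cnn")
            )
        feat = sum(b.n_features for b in self.branches)
        self.lstms: list[MaskedLSTM] = []
        in_dim = feat
        for _ in range(config.n_lstm_layers):
            self.lstms.append(MaskedLSTM(in_dim, config.lstm_units, rng, dtype))
            in_dim = config.lstm_units
        self.dense: list[Dense] = []
        for ui, units in enumerate(config.dense_units):
            act = "linear" if ui == len(config.dense_units) - 1 else config.activation
            self.dense.append(Dense(in_dim, units, rng, activation=act, dtype=dtype))
            in_dim = units
        self._feat = feat

    # -- plumbing -----------------------------------------------------------

    def layers(self) -> list[Layer]:
        out: list[Layer] = []
        for b in self.branches:
            out.extend(b.layers)
        out.extend(self.lstms)
        out.extend(self.dense)
        return out

    def get_weights(self) -> list:
        state = []
        for layer in self.layers():
            entry = {name: p.copy() for name, p in layer.params.items()}
            if isinstance(layer, BatchNorm):
                entry["_running_mean"] = layer.running_mean.copy()
                entry["_running_var"] = layer.running_var.copy()
            state.append(entry)
        return state

    def set_weights(self, state: list) -> None:
        for layer, entry in zip(self.layers(), state):
            for name in layer.params:
                layer.params[name][...] = entry[name]
            if isinstance(layer, BatchNorm):
                layer.running_mean[...] = entry["_running_mean"]
                layer.running_var[...] = entry["_running_var"]

    # -- forward / backward -------------------------------------------------

    def _branch_input(self, x: np.ndarray, k: int) -> np.ndarray:
        if self.n_imus is None:
            return x
        return x[:, :, 6 * k : 6 * (k + 1), :]

    def forward(self, x: np.ndarray, mask: np.ndarray, training: bool = False) -> np.ndarray:
        """Class logits for a batch of windowed inputs (B, X, C, W)."""
        b, xw, c, w = x.shape
        feats = []
        for k, branch in enumerate(self.branches):
            xin = self._branch_input(x, k).reshape(b * xw, 1, -1, w).astype(self.dtype)
            feats.append(branch.forward(xin, training))
        self._feat_sizes = [f.shape[1] for f in feats]
        seq = np.concatenate(feats, axis=1).reshape(b, xw, self._feat)
        for lstm in self.lstms:
            seq = lstm.forward(seq, mask=mask, training=training)
        out = seq[:, -1, :]
        self._seq_shape = seq.shape
        for dense in self.dense:
            out = dense.forward(out, training=training)
        return out

    def backward(self, dlogits: np.ndarray) -> None:
        g = dlogits
        for dense in reversed(self.dense):
            g = dense.backward(g)
        gseq = np.zeros(self._seq_shape, dtype=self.dtype)
        gseq[:, -1, :] = g
        for lstm in reversed(self.lstms):
            gseq = lstm.backward(gseq)
        b, xw, feat = gseq.shape
        flat = gseq.reshape(b * xw, feat)
        offset = 0
        for k, branch in enumerate(self.branches):
            size = self._feat_sizes[k]
            branch.backward(flat[:, offset : offset + size])
            offset += size

    def predict_proba(self, x: np.ndarray, mask: np.ndarray) -> np.ndarray:
        """Class probabilities (rows sum to 1)."""
        return softmax(self.forward(x, mask, training=False))

    def predict(self, x: np.ndarray, mask: np.ndarray) -> np.ndarray:
        """Predicted score values in {1, 2, 3}."""
        return self.predict_proba(x, mask).argmax(axis=1) + 1

    # -- inspection ---------------------------------------------------------

    def describe(self) -> list[dict]:
        """Deterministic layer inventory (names, shapes, parameter counts)."""
        inv: list[dict] = []
        for branch in self.branches:
            inv.extend(copy.deepcopy(branch.inventory))
        in_dim = self._feat
        for li, lstm in enumerate(self.lstms):
            inv.append(
                {
                    "name": f"lstm{li + 1}",
                    "type": "MaskedLSTM",
                    "units": self.config.lstm_units,
                    "activation": self.config.lstm_activation,
                    "recurrent_activation": self.config.lstm_recurrent_activation,
                    "output_shape": [self.input_shape[0], self.config.lstm_units],
                    "n_params": lstm.n_params(),
                }
            )
            in_dim = self.config.lstm_units
        for di, dense in enumerate(self.dense):
            last = di == len(self.dense) - 1
            inv.append(
                {
                    "name": f"dense{di + 1}" if not last else "output",
                    "type": "Dense",
                    "units": dense.out_features,
                    "activation": self.config.output_activation if last else self.config.activation,
                    "output_shape": [dense.out_features],
                    "n_params": dense.n_params(),
                }
            )
        return inv

    @property
    def n_branches(self) -> int:
        return len(self.branches)


def build_model(config: ArchitectureConfig, input_shape: tuple[int, int, int],
                seed: int = 0, dtype=np.float32) -> ModelHandle:
    """Instantiate a trainable model for windowed inputs of shape (X, C, W)."""
    return ModelHandle(config, input_shape, seed=seed, dtype=dtype)


def describe_model(handle: ModelHandle) -> list[dict]:
    """Layer inventory of a built model (see :meth:`ModelHandle.describe`)."""
    return handle.describe()
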