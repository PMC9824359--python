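"""Network input representation.

Pipeline per repetition: stack channels into a 2-D matrix, standardize
(separately for accelerometer and gyroscope channels, parameters fitted on
training repetitions only), zero-pad to a common length, slice into X
equal-width non-overlapping windows, and record a per-window validity mask.
Padding happens after standardization so padded entries are exact zeros and
the all-zero-window mask is well defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from repscore.core import ChannelLayout, Repetition

__all__ = [
    "StandardizationParams",
    "WindowingConfig",
    "WindowedInput",
    "stack_channels",
    "fit_standardization",
    "apply_standardization",
    "pad_and_window",
    "build_per_imu_inputs",
    "Preprocessor",
]

MIN_WINDOW_LENGTH = 8


@dataclass(frozen=True)
class StandardizationParams:
    """Pooled mean/sd per modality, fitted on the training set only."""

    accel_mean: float
    accel_sd: float
    gyro_mean: float
    gyro_sd: float

    def __post_init__(self) -> None:
        if self.accel_sd <= 0 or self.gyro_sd <= 0:
            raise ValueError("standard deviations must be positive")

    def to_dict(self) -> dict:
        return {
            "accel_mean": self.accel_mean,
            "accel_sd": self.accel_sd,
            "gyro_mean": self.gyro_mean,
            "gyro_sd": self.gyro_sd,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StandardizationParams":
        return cls(**{k: float(v) for k, v in d.items()})


@dataclass(frozen=True)
class WindowingConfig:
    """Equal-width non-overlapping windowing of the padded matrix.

    ``pad_length`` must be a multiple of ``n_windows`` and each window must be
    at least :data:`MIN_WINDOW_LENGTH` samples wide.
    """

    n_windows: int = 10
    pad_length: int = 0

    def __post_init__(self) -> None:
        if self.n_windows < 1:
            raise ValueError("n_windows must be >= 1")
        if self.pad_length % self.n_windows != 0:
            raise ValueError(
                f"pad_length {self.pad_length} not divisible by n_windows {self.n_windows}"
            )
        if self.window_length < MIN_WINDOW_LENGTH:
            raise ValueError(
                f"window length {self.window_length} below minimum {MIN_WINDOW_LENGTH}"
            )

    @property
    def window_length(self) -> int:
        return self.pad_length // self.n_windows

    @classmethod
    def from_training_lengths(cls, lengths: Iterable[int], n_windows: int = 10) -> "WindowingConfig":
        """Pad length = max training repetition length, rounded up to a multiple of X."""
        max_len = max(lengths)
        pad = -(-max_len // n_windows) * n_windows
        pad = max(pad, MIN_WINDOW_LENGTH * n_windows)
        return cls(n_windows=n_windows, pad_length=pad)

    def to_dict(self) -> dict:
        return {"n_windows": self.n_windows, "pad_length": self.pad_length}


@dataclass
class WindowedInput:
    """Windowed representation of one repetition.

    ``data`` has shape (X, C, W); ``mask[i]`` is True iff window ``i`` overlaps
    the recorded samples (False windows are all zero padding).  ``n_samples``
    is the original length T, kept so the padded matrix can be reconstructed
    exactly.
    """

    data: np.ndarray
    mask: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("windowed data must have shape (X, C, W)")
        if self.mask.shape != (self.data.shape[0],):
            raise ValueError("mask length must equal number of windows")

    def reconstruct_padded(self) -> np.ndarray:
        """Concatenate windows along time, reproducing the padded matrix."""
        return np.concatenate(list(self.data), axis=1)

    def reconstruct(self) -> np.ndarray:
        """Recover the original (unpadded) matrix."""
        return self.reconstruct_padded()[:, : self.n_samples]


def stack_channels(rep: Repetition, layout: ChannelLayout) -> np.ndarray:
    """Return the C x T channel matrix in layout order (validates row count)."""
    if rep.data.shape[0] != layout.n_channels:
        raise ValueError(
            f"repetition {rep.repetition_id}: {rep.data.shape[0]} rows, "
            f"layout requires {layout.n_channels}"
        )
    return rep.data


def fit_standardization(
    training_reps: Sequence[Repetition], layout: ChannelLayout
) -> StandardizationParams:
    """Pooled mean/sd over all accelerometer (resp. gyroscope) channels and
    time steps of the training repetitions.

    Raises on an empty collection or a constant pool.
    """
    if len(training_reps) == 0:
        raise ValueError("cannot fit standardization on an empty collection")
    accel_rows = layout.accel_rows()
    gyro_rows = layout.gyro_rows()
    accel_pool = np.concatenate([stack_channels(r, layout)[accel_rows].ravel() for r in training_reps])
    gyro_pool = np.concatenate([stack_channels(r, layout)[gyro_rows].ravel() for r in training_reps])
    a_sd = float(accel_pool.std())
    g_sd = float(gyro_pool.std())
    if a_sd == 0.0:
        raise ValueError("accelerometer pool is constant; cannot standardize")
    if g_sd == 0.0:
        raise ValueError("gyroscope pool is constant; cannot standardize")
    return StandardizationParams(
        accel_mean=float(accel_pool.mean()),
        accel_sd=a_sd,
        gyro_mean=float(gyro_pool.mean()),
        gyro_sd=g_sd,
    )


def apply_standardization(
    matrix: np.ndarray, params: StandardizationParams, layout: ChannelLayout
) -> np.ndarray:
    """Standardize accel and gyro rows with their respective pooled statistics."""
    out = np.array(matrix, dtype=np.float64, copy=True)
    out[layout.accel_rows()] = (out[layout.accel_rows()] - params.accel_mean) / params.accel_sd
    out[layout.gyro_rows()] = (out[layout.gyro_rows()] - params.gyro_mean) / params.gyro_sd
    return out


def pad_and_window(matrix: np.ndarray, config: WindowingConfig) -> WindowedInput:
    """Zero-pad a C x T matrix to the configured length and slice into windows.

    Window i covers samples [i*W, (i+1)*W); its mask is True iff it overlaps
    the recorded range [0, T).  Raises if T exceeds the pad length.
    """
    c, t = matrix.shape
    if t > config.pad_length:
        raise ValueError(
            f"repetition exceeds pad length: T={t} > L={config.pad_length}"
        )
    padded = np.zeros((c, config.pad_length), dtype=np.float64)
    padded[:, :t] = matrix
    w = config.window_length
    data = padded.reshape(c, config.n_windows, w).transpose(1, 0, 2).copy()
    starts = np.arange(config.n_windows) * w
    mask = starts < t
    return WindowedInput(data=data, mask=mask, n_samples=t)


def build_per_imu_inputs(
    rep: Repetition,
    params: StandardizationParams,
    config: WindowingConfig,
    layout: ChannelLayout,
) -> list[WindowedInput]:
    """Per-IMU windowed inputs (one (X, 6, W) block per IMU, shared mask).

    Stacking the outputs along the channel axis reproduces the full windowed
    representation exactly.
    """
    std = apply_standardization(stack_channels(rep, layout), params, layout)
    full = pad_and_window(std, config)
    per_imu = []
    cpi = layout.channels_per_imu
    for k in range(layout.n_imus):
        block = full.data[:, cpi * k : cpi * (k + 1), :].copy()
        per_imu.append(WindowedInput(data=block, mask=full.mask.copy(), n_samples=full.n_samples))
    return per_imu


class Preprocessor:
    """Fitted preprocessing state: standardization parameters + windowing config.

    Fit on training repetitions only; transforming a repetition longer than
    the fitted pad length raises rather than truncating.
    """

    def __init__(self, layout: ChannelLayout, n_windows: int = 10, pad_length: int | None = None):
        self.layout = layout
        self.n_windows = n_windows
        self._requested_pad_length = pad_length
        self.params: StandardizationParams | None = None
        self.config: WindowingConfig | None = None

    def fit(self, training_reps: Sequence[Repetition]) -> "Preprocessor":
        self.params = fit_standardization(training_reps, self.layout)
        if self._requested_pad_length is not None:
            self.config = WindowingConfig(self.n_windows, self._requested_pad_length)
        else:
            self.config = WindowingConfig.from_training_lengths(
                [r.n_samples for r in training_reps], self.n_windows
            )
        return self

    def _check_fitted(self) -> None:
        if self.params is None or self.config is None:
            raise RuntimeError("preprocessor is not fitted")

    def transform(self, rep: Repetition) -> WindowedInput:
        self._check_fitted()
        std = apply_standardization(stack_channels(rep, self.layout), self.params, self.layout)
        return pad_and_window(std, self.config)

    def transform_per_imu(self, rep: Repetition) -> list[WindowedInput]:
        self._check_fitted()
        return build_per_imu_inputs(rep, self.params, self.config, self.layout)

    def to_dict(self) -> dict:
        self._check_fitted()
        return {
            "n_windows": self.n_windows,
            "params": self.params.to_dict(),
            "config": self.config.to_dict(),
        }
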