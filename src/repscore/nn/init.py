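"""Weight initialization."""

from __future__ import annotations

import numpy as np


def glorot_uniform(
    rng: np.random.Generator,
    shape: tuple[int, ...],
    fan_in: int,
    fan_out: int,
    dtype=np.float32,
) -> np.ndarray:
    """Glorot (Xavier) uniform initialization: U(-limit, limit), limit = sqrt(6 / (fan_in + fan_out))."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)
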