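"""Softmax and categorical cross-entropy."""

from __future__ import annotations

import numpy as np


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, onehot: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Mean categorical cross-entropy of softmax(logits) against one-hot targets.

    Returns (loss, probabilities, gradient w.r.t. logits).
    """
    probs = softmax(logits)
    n = logits.shape[0]
    eps = np.finfo(probs.dtype).tiny
    loss = float(-(onehot * np.log(probs + eps)).sum() / n)
    grad = (probs - onehot) / n
    return loss, probs, grad.astype(logits.dtype)
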