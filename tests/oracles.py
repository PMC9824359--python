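"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the package's own code paths: the reliability
oracle enumerates within-item pairs explicitly, and the F1 oracle works from
a hand-built confusion matrix via per-class precision/recall.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def alpha_pair_enumeration(values, metric: str = "ordinal") -> float:
    """Krippendorff's alpha by explicit enumeration of within-item pairs.

    ``values`` is an items x raters array with NaN for missing.  Observed
    disagreement averages the difference function over all within-item pairs,
    each weighted by 1/(m_u - 1); expected disagreement runs over all
    cross-item value pairs.
    """
    values = np.asarray(values, dtype=float)
    cats = sorted({v for row in values for v in row if not np.isnan(v)})
    margins = {c: 0.0 for c in cats}
    units = []
    for row in values:
        vals = [v for v in row if not np.isnan(v)]
        if len(vals) >= 2:
            units.append(vals)
            for v in vals:
                margins[v] += 1.0
    if len(units) < 2:
        raise ValueError("fewer than 2 pairable items")
    n = sum(margins.values())

    def delta2(c, k):
        if metric == "nominal":
            return 0.0 if c == k else 1.0
        if metric == "interval":
            return (c - k) ** 2
        lo, hi = (c, k) if c <= k else (k, c)
        i0, i1 = cats.index(lo), cats.index(hi)
        s = sum(margins[cats[g]] for g in range(i0, i1 + 1)) - (margins[lo] + margins[hi]) / 2.0
        return s * s

    num = 0.0
    for vals in units:
        m = len(vals)
        for a, b in combinations(range(m), 2):
            num += 2.0 * delta2(vals[a], vals[b]) / (m - 1)
    d_o = num / n
    den = 0.0
    for c in cats:
        for k in cats:
            den += margins[c] * margins[k] * delta2(c, k)
    d_e = den / (n * (n - 1.0))
    if d_e == 0.0:
        raise ValueError("zero expected disagreement")
    return 1.0 - d_o / d_e


def f1_confusion_oracle(true_labels, predicted_labels, label_set=(1, 2, 3)) -> dict:
    """Per-class/macro/weighted F1 from an explicitly built confusion matrix."""
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    per_class = {}
    supports = {}
    for c in label_set:
        tp = int(np.sum((true_labels == c) & (predicted_labels == c)))
        fp = int(np.sum((true_labels != c) & (predicted_labels == c)))
        fn = int(np.sum((true_labels == c) & (predicted_labels != c)))
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        per_class[c] = (
            2 * precision * recall / (precision + recall) if precision + recall else 0.0
        )
        supports[c] = int(np.sum(true_labels == c))
    macro = sum(per_class.values()) / len(label_set)
    total = sum(supports.values())
    weighted = sum(per_class[c] * supports[c] for c in label_set) / total
    return {"per_class": per_class, "macro": macro, "weighted": weighted}
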