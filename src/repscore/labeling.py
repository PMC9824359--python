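"""Multi-rater label resolution and interrater reliability.

Reliability is quantified with Krippendorff's alpha computed from the
coincidence matrix over pairable values, which handles missing ratings by
construction.  Label resolution is a three-rater majority vote; triples with
three distinct scores carry no majority and are excluded.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from repscore.core import VALID_SCORES, Dataset

__all__ = [
    "AgreementCategory",
    "RatingTable",
    "ResolvedLabel",
    "krippendorff_alpha",
    "majority_vote",
    "summarize_agreement",
    "resolve_dataset_labels",
]


class AgreementCategory(str, enum.Enum):
    """Degree of agreement among three raters on one item."""

    UNANIMOUS = "unanimous"
    MAJORITY_MINOR = "majority_minor"  # discrepant score differs by one point
    MAJORITY_MAJOR = "majority_major"  # discrepant score differs by more than one point
    NO_MAJORITY = "no_majority"  # all three scores distinct; item excluded


@dataclass(frozen=True)
class ResolvedLabel:
    """Outcome of the majority vote for one item."""

    label: int | None
    agreement: AgreementCategory

    def __post_init__(self) -> None:
        if (self.label is None) != (self.agreement is AgreementCategory.NO_MAJORITY):
            raise ValueError("label must be absent exactly when there is no majority")


class RatingTable:
    """Items x raters matrix of ordinal scores with missing values.

    Missing entries are NaN.  Scores must lie in the declared ordinal domain
    (default {1, 2, 3}).
    """

    def __init__(self, values: np.ndarray | Sequence, domain: Sequence[int] = VALID_SCORES):
        arr = np.asarray(values, dtype=np.float64)
        if arr.ndim != 2:
            raise ValueError("rating table must be 2-D (items x raters)")
        self.values = arr
        self.domain = tuple(sorted(domain))
        present = arr[~np.isnan(arr)]
        bad = set(present.tolist()) - set(float(d) for d in self.domain)
        if bad:
            raise ValueError(f"scores outside ordinal domain {self.domain}: {sorted(bad)}")

    @property
    def n_items(self) -> int:
        return self.values.shape[0]

    @property
    def n_raters(self) -> int:
        return self.values.shape[1]


def _coincidence_matrix(table: RatingTable) -> tuple[np.ndarray, np.ndarray]:
    """Coincidence matrix over pairable values and the category list.

    Each item with m >= 2 ratings contributes, for every ordered pair of its
    ratings, weight 1/(m - 1) to the corresponding cell.  Items with fewer
    than 2 ratings are not pairable and are skipped.
    """
    cats = np.asarray(table.domain, dtype=np.float64)
    idx = {c: i for i, c in enumerate(cats.tolist())}
    K = len(cats)
    coin = np.zeros((K, K))
    for row in table.values:
        vals = row[~np.isnan(row)]
        m = len(vals)
        if m < 2:
            continue
        w = 1.0 / (m - 1)
        for a in range(m):
            for b in range(m):
                if a != b:
                    coin[idx[vals[a]], idx[vals[b]]] += w
    return coin, cats


def _ordinal_delta_sq(margins: np.ndarray) -> np.ndarray:
    """Ordinal squared difference from coincidence-matrix margins.

    delta^2(c, k) = (sum_{g=c..k} n_g - (n_c + n_k) / 2)^2 over category
    positions c <= k, symmetric.
    """
    K = len(margins)
    delta = np.zeros((K, K))
    for c in range(K):
        for k in range(c + 1, K):
            cum = margins[c : k + 1].sum() - (margins[c] + margins[k]) / 2.0
            delta[c, k] = delta[k, c] = cum * cum
    return delta


def _nominal_delta_sq(K: int) -> np.ndarray:
    return 1.0 - np.eye(K)


def _interval_delta_sq(cats: np.ndarray) -> np.ndarray:
    d = cats[:, None] - cats[None, :]
    return d * d


def krippendorff_alpha(table: RatingTable, metric: str = "ordinal") -> float:
    """Krippendorff's alpha for a ratings table.

    Parameters
    ----------
    table
        Items x raters ordinal scores, NaN for missing.
    metric
        ``"ordinal"``, ``"nominal"`` or ``"interval"`` difference function.

    Returns
    -------
    float
        alpha = 1 - D_o / D_e in (-1, 1].

    Raises
    ------
    ValueError
        If fewer than 2 items are pairable, or expected disagreement is zero
        (all pairable values identical) so alpha is undefined.
    """
    if metric not in ("ordinal", "nominal", "interval"):
        raise ValueError(f"unknown metric {metric!r}")
    pairable_items = sum(1 for row in table.values if (~np.isnan(row)).sum() >= 2)
    if pairable_items < 2:
        raise ValueError("need at least 2 items with >= 2 ratings each")

    coin, cats = _coincidence_matrix(table)
    margins = coin.sum(axis=1)
    n = margins.sum()

    if metric == "ordinal":
        delta = _ordinal_delta_sq(margins)
    elif metric == "nominal":
        delta = _nominal_delta_sq(len(cats))
    else:
        delta = _interval_delta_sq(cats)

    d_o = (coin * delta).sum() / n
    d_e = (np.outer(margins, margins) * delta).sum() / (n * (n - 1.0))
    if d_e == 0.0:
        raise ValueError("alpha undefined: zero expected disagreement (all pairable values identical)")
    return float(1.0 - d_o / d_e)


def majority_vote(scores: Sequence[int]) -> ResolvedLabel:
    """Resolve exactly three ordinal scores into a final label.

    All equal -> unanimous; two equal -> their value, with minor/major
    agreement depending on whether the discrepant score differs by one point
    or more; all distinct -> no majority, item excluded.
    """
    scores = tuple(int(s) for s in scores)
    if len(scores) != 3:
        raise ValueError(f"majority vote requires exactly 3 scores, got {len(scores)}")
    for s in scores:
        if s not in VALID_SCORES:
            raise ValueError(f"score {s} outside {{1,2,3}}")
    if scores[0] == scores[1] == scores[2]:
        return ResolvedLabel(scores[0], AgreementCategory.UNANIMOUS)
    if len(set(scores)) == 3:
        return ResolvedLabel(None, AgreementCategory.NO_MAJORITY)
    counts = {s: scores.count(s) for s in set(scores)}
    majority = next(s for s, c in counts.items() if c == 2)
    discrepant = next(s for s, c in counts.items() if c == 1)
    if abs(discrepant - majority) == 1:
        return ResolvedLabel(majority, AgreementCategory.MAJORITY_MINOR)
    return ResolvedLabel(majority, AgreementCategory.MAJORITY_MAJOR)


def summarize_agreement(score_triples: Iterable[Sequence[int]]) -> dict:
    """Agreement-category proportions and usable-item count over 3-rater items.

    Returns a dict with ``proportions`` (by category value, summing to 1 over
    nonempty input), ``counts``, ``n_items`` and ``n_usable`` (items with a
    majority).
    """
    counts = {cat: 0 for cat in AgreementCategory}
    n_items = 0
    for triple in score_triples:
        counts[majority_vote(triple).agreement] += 1
        n_items += 1
    proportions = {
        cat.value: (counts[cat] / n_items if n_items else 0.0) for cat in AgreementCategory
    }
    n_usable = n_items - counts[AgreementCategory.NO_MAJORITY]
    return {
        "proportions": proportions,
        "counts": {cat.value: counts[cat] for cat in AgreementCategory},
        "n_items": n_items,
        "n_usable": n_usable,
    }


def resolve_dataset_labels(dataset: Dataset) -> dict:
    """Apply the majority vote to every repetition's rater scores in place.

    Repetitions without a majority get ``resolved_label = None``.  Returns the
    :func:`summarize_agreement` report for the dataset.
    """
    triples = []
    for rep in dataset.repetitions:
        if len(rep.rater_scores) != 3:
            raise ValueError(
                f"repetition {rep.repetition_id} has {len(rep.rater_scores)} rater scores, need 3"
            )
        resolved = majority_vote(rep.rater_scores)
        rep.resolved_label = resolved.label
        triples.append(rep.rater_scores)
    return summarize_agreement(triples)


def rating_table_from_dataset(dataset: Dataset) -> RatingTable:
    """Build a RatingTable from the rater scores stored in a dataset."""
    n_raters = max((len(r.rater_scores) for r in dataset.repetitions), default=0)
    values = np.full((len(dataset.repetitions), n_raters), np.nan)
    for i, rep in enumerate(dataset.repetitions):
        for j, s in enumerate(rep.rater_scores):
            values[i, j] = s
    return RatingTable(values)
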