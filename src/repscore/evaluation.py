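"""Data splitting and classification metrics.

Splits: stratified shuffle (test 20% of all, validation 16% of all — i.e.
20% of the remaining 80% — training 64%), Monte-Carlo cross-validation
(independent redraws per fold), and leave-one-subject-out folds.  Metrics:
3x3 confusion matrix, per-class / macro / weighted F1 over the fixed label
set {1, 2, 3} with the zero convention for undefined precision or recall.
All splitters are pure functions of their inputs and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

LABEL_SET = (1, 2, 3)

__all__ = [
    "SplitSpec",
    "Fold",
    "MetricReport",
    "stratified_shuffle_split",
    "monte_carlo_cv",
    "loso_folds",
    "f1_metrics",
]


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test fractions of the whole dataset (sum to 1)."""

    test_fraction: float = 0.20
    val_fraction: float = 0.16
    train_fraction: float = 0.64
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.test_fraction + self.val_fraction + self.train_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {total}")
        if min(self.test_fraction, self.val_fraction, self.train_fraction) <= 0:
            raise ValueError("all fractions must be positive")


@dataclass(frozen=True)
class Fold:
    """Disjoint train/validation/test index sets for one evaluation fold."""

    train: np.ndarray
    val: np.ndarray
    test: np.ndarray
    held_out_subject: str | None = None

    def __post_init__(self) -> None:
        sets = [set(self.train.tolist()), set(self.val.tolist()), set(self.test.tolist())]
        if sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2]:
            raise ValueError("fold splits overlap")


@dataclass
class MetricReport:
    """Confusion matrix (rows = true label) and F1 summary for one split."""

    confusion: np.ndarray
    per_class_f1: dict[int, float]
    macro_f1: float
    weighted_f1: float
    n: int

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "per_class_f1": {str(k): v for k, v in self.per_class_f1.items()},
            "macro_f1": self.macro_f1,
            "weighted_f1": self.weighted_f1,
            "n": self.n,
        }


def _proportional_counts(n_per_class: dict, fraction: float) -> dict:
    """Largest-remainder rounding of per-class take counts for one split."""
    raw = {c: n * fraction for c, n in n_per_class.items()}
    base = {c: int(np.floor(v)) for c, v in raw.items()}
    want = int(round(sum(raw.values())))
    remainders = sorted(raw, key=lambda c: raw[c] - base[c], reverse=True)
    short = want - sum(base.values())
    for c in remainders[:short]:
        base[c] += 1
    return base


def stratified_shuffle_split(labels: np.ndarray, spec: SplitSpec) -> Fold:
    """One stratified train/val/test partition of ``range(len(labels))``.

    Per-class proportions in each split match the overall proportions within
    rounding; deterministic per seed.  Raises if any class is too small to
    appear in every split.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(spec.seed)
    classes = np.unique(labels)
    n_per_class = {c: int((labels == c).sum()) for c in classes}
    test_counts = _proportional_counts(n_per_class, spec.test_fraction)
    val_counts = _proportional_counts(n_per_class, spec.val_fraction)
    for c in classes:
        n_train = n_per_class[c] - test_counts[c] - val_counts[c]
        if min(test_counts[c], val_counts[c], n_train) < 1:
            raise ValueError(
                f"class {c} has {n_per_class[c]} members; too small to stratify across splits"
            )
    train_idx, val_idx, test_idx = [], [], []
    for c in classes:
        members = np.flatnonzero(labels == c)
        perm = rng.permutation(members)
        t, v = test_counts[c], val_counts[c]
        test_idx.append(perm[:t])
        val_idx.append(perm[t : t + v])
        train_idx.append(perm[t + v :])
    return Fold(
        train=np.sort(np.concatenate(train_idx)),
        val=np.sort(np.concatenate(val_idx)),
        test=np.sort(np.concatenate(test_idx)),
    )


def monte_carlo_cv(labels: np.ndarray, spec: SplitSpec, n_folds: int = 5) -> list[Fold]:
    """``n_folds`` independent stratified shuffle splits with derived per-fold seeds."""
    seeds = np.random.SeedSequence(spec.seed).generate_state(n_folds)
    return [
        stratified_shuffle_split(
            labels,
            SplitSpec(spec.test_fraction, spec.val_fraction, spec.train_fraction, seed=int(s)),
        )
        for s in seeds
    ]


def loso_folds(
    subject_ids: np.ndarray,
    labels: np.ndarray,
    n_folds: int,
    inner_val_fraction: float = 0.2,
    seed: int = 0,
) -> list[Fold]:
    """Leave-one-subject-out folds.

    Each fold's test set is exactly all repetitions of one held-out subject;
    the remaining data are split 80/20 (stratified) into train and
    validation.  When ``n_folds`` is smaller than the number of subjects, the
    held-out subjects are sampled without replacement using ``seed``.
    """
    subject_ids = np.asarray(subject_ids)
    labels = np.asarray(labels)
    subjects = list(dict.fromkeys(subject_ids.tolist()))
    if n_folds > len(subjects):
        raise ValueError(f"n_folds={n_folds} exceeds number of subjects ({len(subjects)})")
    rng = np.random.default_rng(seed)
    if n_folds < len(subjects):
        held_out = list(rng.choice(subjects, size=n_folds, replace=False))
    else:
        held_out = subjects
    inner_seeds = np.random.SeedSequence(seed).generate_state(len(held_out))
    folds = []
    for subject, inner_seed in zip(held_out, inner_seeds):
        test_idx = np.flatnonzero(subject_ids == subject)
        rest_idx = np.flatnonzero(subject_ids != subject)
        rest_labels = labels[rest_idx]
        inner_rng = np.random.default_rng(int(inner_seed))
        train_parts, val_parts = [], []
        for c in np.unique(rest_labels):
            members = rest_idx[rest_labels == c]
            perm = inner_rng.permutation(members)
            n_val = max(1, int(round(len(members) * inner_val_fraction)))
            if n_val >= len(members):
                raise ValueError(f"class {c} too small to stratify inner train/val split")
            val_parts.append(perm[:n_val])
            train_parts.append(perm[n_val:])
        folds.append(
            Fold(
                train=np.sort(np.concatenate(train_parts)),
                val=np.sort(np.concatenate(val_parts)),
                test=np.sort(test_idx),
                held_out_subject=str(subject),
            )
        )
    return folds


def f1_metrics(
    true_labels: np.ndarray, predicted_labels: np.ndarray, label_set=LABEL_SET
) -> MetricReport:
    """Confusion matrix and per-class / macro / weighted F1.

    Macro F1 averages over the full fixed label set; a class absent from both
    truth and prediction contributes F1 = 0.  Weighted F1 weights per-class
    F1 by true-label support.
    """
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    if true_labels.shape != predicted_labels.shape or true_labels.ndim != 1:
        raise ValueError("label vectors must be 1-D and of equal length")
    if len(true_labels) == 0:
        raise ValueError("empty input")
    label_set = tuple(label_set)
    for arr, name in ((true_labels, "true"), (predicted_labels, "predicted")):
        bad = set(arr.tolist()) - set(label_set)
        if bad:
            raise ValueError(f"{name} labels outside {label_set}: {sorted(bad)}")
    k = len(label_set)
    index = {c: i for i, c in enumerate(label_set)}
    confusion = np.zeros((k, k), dtype=np.int64)
    for t, p in zip(true_labels, predicted_labels):
        confusion[index[t], index[p]] += 1
    per_class = {}
    supports = confusion.sum(axis=1)
    for c in label_set:
        i = index[c]
        tp = confusion[i, i]
        fp = confusion[:, i].sum() - tp
        fn = confusion[i, :].sum() - tp
        denom = 2 * tp + fp + fn
        per_class[c] = float(2 * tp / denom) if denom > 0 else 0.0
    macro = float(np.mean([per_class[c] for c in label_set]))
    total = supports.sum()
    weighted = float(
        sum(per_class[c] * supports[index[c]] for c in label_set) / total
    )
    return MetricReport(
        confusion=confusion,
        per_class_f1=per_class,
        macro_f1=macro,
        weighted_f1=weighted,
        n=int(total),
    )
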