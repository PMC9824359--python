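"""Training loop, cross-validation / LOSO runners, and random hyperparameter search.

Per fold, standardization parameters and the pad length are fitted on that
fold's training split only (no leakage).  Training minimizes categorical
cross-entropy with Adam, stops on an early-stopping patience over the
validation loss, and restores the best-validation weights.  The epoch budget
and stopping rule are fixed here (max 300 epochs, patience 30 by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from repscore.core import Dataset, Repetition
from repscore.evaluation import (
    Fold,
    MetricReport,
    SplitSpec,
    f1_metrics,
    loso_folds,
    monte_carlo_cv,
)
from repscore.models import ArchitectureConfig, ModelHandle, build_model
from repscore.nn.losses import softmax_cross_entropy
from repscore.nn.optim import Adam
from repscore.preprocess import Preprocessor

__all__ = [
    "TrainingConfig",
    "HyperparameterGrid",
    "RunResult",
    "headline_config",
    "train",
    "run_cv",
    "run_losocv",
    "sample_configs",
    "random_search",
]

_EVAL_BATCH = 64


@dataclass
class TrainingConfig:
    """Epoch budget, early stopping, and the training seed."""

    max_epochs: int = 300
    patience: int = 30
    seed: int = 0
    verbose: bool = False

    def __post_init__(self) -> None:
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be positive")
        if self.patience < 0:
            raise ValueError("patience must be >= 0")


@dataclass(frozen=True)
class HyperparameterGrid:
    """The searched hyperparameter domains."""

    activation: tuple[str, ...] = ("relu", "elu", "lrelu")
    n_blocks: tuple[int, ...] = (1, 2, 3)
    scheme: tuple[str, ...] = ("fixed_kernel", "decreasing_kernel")
    regularizer: tuple[str, ...] = ("dropout_0.2", "batch_norm")
    n_lstm_layers: tuple[int, ...] = (1, 2)
    batch_size: tuple[int, ...] = (4, 8, 16, 32)

    def sample(self, rng: np.random.Generator) -> ArchitectureConfig:
        """Draw one configuration, each parameter independently and uniformly."""
        return ArchitectureConfig(
            variant="baseline",
            activation=str(rng.choice(self.activation)),
            n_blocks=int(rng.choice(self.n_blocks)),
            scheme=str(rng.choice(self.scheme)),
            regularizer=str(rng.choice(self.regularizer)),
            n_lstm_layers=int(rng.choice(self.n_lstm_layers)),
            batch_size=int(rng.choice(self.batch_size)),
        )


def headline_config() -> ArchitectureConfig:
    """The best searched combination, used for all per-exercise and LOSO runs:
    baseline variant, 3 CNN-blocks with the fixed-kernel scheme, ELU,
    dropout 0.2, 2 LSTM layers, batch size 32."""
    return ArchitectureConfig(
        variant="baseline",
        n_blocks=3,
        scheme="fixed_kernel",
        activation="elu",
        regularizer="dropout_0.2",
        n_lstm_layers=2,
        batch_size=32,
    )


@dataclass
class RunResult:
    """Per-fold metric reports plus aggregate mean/sd per split."""

    config: ArchitectureConfig
    fold_reports: list[dict[str, MetricReport]]
    histories: list[dict]
    aggregate: dict
    seeds: dict
    run_index: int | None = None

    def mean(self, split: str, metric: str = "macro_f1") -> float:
        return self.aggregate[split][f"{metric}_mean"]


def _one_hot(labels: np.ndarray) -> np.ndarray:
    out = np.zeros((len(labels), 3), dtype=np.float32)
    out[np.arange(len(labels)), np.asarray(labels) - 1] = 1.0
    return out


def assemble(reps: list[Repetition], pre: Preprocessor) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Windowed arrays (N, X, C, W), masks (N, X) and labels (N,) for a rep list."""
    xs, masks, ys = [], [], []
    for rep in reps:
        wi = pre.transform(rep)
        xs.append(wi.data.astype(np.float32))
        masks.append(wi.mask)
        ys.append(rep.resolved_label)
    return np.stack(xs), np.stack(masks), np.asarray(ys, dtype=np.int64)


def _evaluate(model: ModelHandle, x: np.ndarray, mask: np.ndarray, y: np.ndarray) -> tuple[float, MetricReport]:
    """Loss and metric report on one split, batched to bound memory."""
    onehot = _one_hot(y)
    losses, preds = [], []
    for start in range(0, len(x), _EVAL_BATCH):
        sl = slice(start, start + _EVAL_BATCH)
        logits = model.forward(x[sl], mask[sl], training=False)
        loss, probs, _ = softmax_cross_entropy(logits, onehot[sl])
        losses.append(loss * len(x[sl]))
        preds.append(probs.argmax(axis=1) + 1)
    loss = float(np.sum(losses) / len(x))
    report = f1_metrics(y, np.concatenate(preds))
    return loss, report


def train(
    model: ModelHandle,
    train_data: tuple[np.ndarray, np.ndarray, np.ndarray],
    val_data: tuple[np.ndarray, np.ndarray, np.ndarray],
    config: TrainingConfig,
) -> dict:
    """Train a model in place; returns the per-epoch history.

    Stops at ``max_epochs`` or when the validation loss has not improved for
    more than ``patience`` consecutive epochs; the best-validation weights
    are restored before returning.
    """
    x_tr, m_tr, y_tr = train_data
    x_va, m_va, y_va = val_data
    if len(x_tr) == 0:
        raise ValueError("empty training set")
    missing = set((1, 2, 3)) - set(np.unique(y_tr).tolist())
    if missing:
        warnings.warn(f"classes {sorted(missing)} missing from the training set", stacklevel=2)
    onehot_tr = _one_hot(y_tr)
    rng = np.random.default_rng(config.seed)
    optimizer = Adam(learning_rate=model.config.learning_rate)
    batch = model.config.batch_size
    layers = model.layers()

    history: dict = {"train_loss": [], "val_loss": [], "train_macro_f1": [], "val_macro_f1": []}
    best_val = np.inf
    best_weights = model.get_weights()
    stale = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(x_tr))
        for start in range(0, len(order), batch):
            idx = order[start : start + batch]
            logits = model.forward(x_tr[idx], m_tr[idx], training=True)
            _, _, grad = softmax_cross_entropy(logits, onehot_tr[idx])
            model.backward(grad)
            optimizer.step(layers)
        train_loss, train_report = _evaluate(model, x_tr, m_tr, y_tr)
        val_loss, val_report = _evaluate(model, x_va, m_va, y_va)
        history["train_loss"].append(train_loss)
        history["val_loss"].append(val_loss)
        history["train_macro_f1"].append(train_report.macro_f1)
        history["val_macro_f1"].append(val_report.macro_f1)
        if config.verbose:
            print(
                f"epoch {epoch + 1:3d}  loss {train_loss:.4f}/{val_loss:.4f}  "
                f"macro-F1 {train_report.macro_f1:.3f}/{val_report.macro_f1:.3f}"
            )
        if val_loss < best_val:
            best_val = val_loss
            best_weights = model.get_weights()
            stale = 0
        else:
            stale += 1
            if stale > config.patience:
                break
    model.set_weights(best_weights)
    history["stopped_epoch"] = len(history["train_loss"])
    return history


def _usable_reps(dataset: Dataset) -> list[Repetition]:
    reps = [r for r in dataset.repetitions if r.resolved_label is not None]
    if not reps:
        raise ValueError("dataset has no repetitions with resolved labels")
    return reps


def _aggregate(fold_reports: list[dict[str, MetricReport]]) -> dict:
    out: dict = {}
    for split in ("train", "val", "test"):
        macros = [fr[split].macro_f1 for fr in fold_reports]
        weighteds = [fr[split].weighted_f1 for fr in fold_reports]
        out[split] = {
            "macro_f1_mean": float(np.mean(macros)),
            "macro_f1_sd": float(np.std(macros)),
            "weighted_f1_mean": float(np.mean(weighteds)),
            "weighted_f1_sd": float(np.std(weighteds)),
        }
    return out


def _run_folds(
    dataset: Dataset,
    arch_config: ArchitectureConfig,
    folds: list[Fold],
    training_config: TrainingConfig,
    n_windows: int,
    pad_length: int | None,
    seed: int,
) -> RunResult:
    reps = _usable_reps(dataset)
    fold_seeds = np.random.SeedSequence(seed).generate_state(len(folds))
    fold_reports: list[dict[str, MetricReport]] = []
    histories = []
    for fold, fold_seed in zip(folds, fold_seeds):
        train_reps = [reps[i] for i in fold.train]
        val_reps = [reps[i] for i in fold.val]
        test_reps = [reps[i] for i in fold.test]
        pre = Preprocessor(dataset.layout, n_windows=n_windows, pad_length=pad_length)
        pre.fit(train_reps)
        tr = assemble(train_reps, pre)
        va = assemble(val_reps, pre)
        te = assemble(test_reps, pre)
        input_shape = tr[0].shape[1:]
        model = build_model(arch_config, input_shape, seed=int(fold_seed))
        tc = TrainingConfig(
            max_epochs=training_config.max_epochs,
            patience=training_config.patience,
            seed=int(fold_seed),
            verbose=training_config.verbose,
        )
        history = train(model, tr, va, tc)
        reports = {}
        for split, (x, m, y) in zip(("train", "val", "test"), (tr, va, te)):
            _, reports[split] = _evaluate(model, x, m, y)
        fold_reports.append(reports)
        histories.append(history)
    return RunResult(
        config=arch_config,
        fold_reports=fold_reports,
        histories=histories,
        aggregate=_aggregate(fold_reports),
        seeds={"run_seed": seed, "fold_seeds": [int(s) for s in fold_seeds]},
    )


def run_cv(
    dataset: Dataset,
    arch_config: ArchitectureConfig,
    n_folds: int = 5,
    training_config: TrainingConfig | None = None,
    split_spec: SplitSpec | None = None,
    n_windows: int = 10,
    pad_length: int | None = None,
    seed: int = 0,
) -> RunResult:
    """Monte-Carlo cross-validation with stratified shuffle splits per fold."""
    training_config = training_config or TrainingConfig(seed=seed)
    reps = _usable_reps(dataset)
    labels = np.asarray([r.resolved_label for r in reps])
    spec = split_spec or SplitSpec(seed=seed)
    folds = monte_carlo_cv(labels, spec, n_folds=n_folds)
    return _run_folds(dataset, arch_config, folds, training_config, n_windows, pad_length, seed)


def run_losocv(
    dataset: Dataset,
    arch_config: ArchitectureConfig,
    n_folds: int = 10,
    training_config: TrainingConfig | None = None,
    inner_val_fraction: float = 0.2,
    n_windows: int = 10,
    pad_length: int | None = None,
    seed: int = 0,
) -> RunResult:
    """Leave-one-subject-out cross-validation; headline metric is weighted F1."""
    training_config = training_config or TrainingConfig(seed=seed)
    reps = _usable_reps(dataset)
    labels = np.asarray([r.resolved_label for r in reps])
    subjects = np.asarray([r.subject_id for r in reps])
    folds = loso_folds(subjects, labels, n_folds, inner_val_fraction=inner_val_fraction, seed=seed)
    result = _run_folds(dataset, arch_config, folds, training_config, n_windows, pad_length, seed)
    result.seeds["held_out_subjects"] = [f.held_out_subject for f in folds]
    return result


def sample_configs(
    grid: HyperparameterGrid, n_runs: int = 90, base_seed: int = 0, dedupe: bool = False
) -> list[ArchitectureConfig]:
    """Draw the search's configuration list; reproducible from ``base_seed``.

    Draws are independent, so duplicates can occur; ``dedupe=True`` redraws
    until the list is duplicate-free (the full grid has 288 cells).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rng = np.random.default_rng(base_seed)
    configs: list[ArchitectureConfig] = []
    seen: set[tuple] = set()
    while len(configs) < n_runs:
        cfg = grid.sample(rng)
        key = (cfg.activation, cfg.n_blocks, cfg.scheme, cfg.regularizer,
               cfg.n_lstm_layers, cfg.batch_size)
        if dedupe:
            if key in seen:
                continue
            seen.add(key)
        configs.append(cfg)
    return configs


def random_search(
    grid: HyperparameterGrid,
    evaluate,
    n_runs: int = 90,
    base_seed: int = 0,
    dedupe: bool = False,
) -> list[RunResult]:
    """Random hyperparameter search, ranked by mean validation macro F1.

    ``evaluate(config, run_index)`` must return a :class:`RunResult` (e.g., a
    closure over :func:`run_cv`, or a stub for sweep-plumbing tests).  Ties
    are broken by run index (earlier run wins).
    """
    configs = sample_configs(grid, n_runs=n_runs, base_seed=base_seed, dedupe=dedupe)
    results: list[RunResult] = []
    for i, cfg in enumerate(configs):
        result = evaluate(cfg, i)
        result.run_index = i
        results.append(result)
    return sorted(results, key=lambda r: (-r.mean("val", "macro_f1"), r.run_index))
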