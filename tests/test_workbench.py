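import numpy as np
import pytest

from repscore.evaluation import MetricReport
from repscore.models import ArchitectureConfig, build_model
from repscore.preprocess import Preprocessor
from repscore.synthetic import SyntheticConfig, generate_dataset
from repscore.workbench import (
    HyperparameterGrid,
    RunResult,
    TrainingConfig,
    assemble,
    headline_config,
    random_search,
    run_cv,
    run_losocv,
    sample_configs,
    train,
)


def tiny_arch(**overrides):
    base = dict(
        variant="baseline", n_blocks=1, scheme="fixed_kernel", activation="elu",
        regularizer="dropout_0.2", n_lstm_layers=1, batch_size=8,
    )
    base.update(overrides)
    cfg = ArchitectureConfig(**base)
    cfg.lstm_units = 16
    cfg.dense_units = (16, 8, 3)
    return cfg


def prepared(dataset, pad_length=80):
    reps = dataset.repetitions
    pre = Preprocessor(dataset.layout, n_windows=10, pad_length=pad_length).fit(reps)
    return assemble(reps, pre)


class TestHeadlineConfig:
    def test_matches_best_searched_combination(self):
        cfg = headline_config()
        assert cfg.variant == "baseline"
        assert cfg.n_blocks == 3
        assert cfg.scheme == "fixed_kernel"
        assert cfg.activation == "elu"
        assert cfg.regularizer == "dropout_0.2"
        assert cfg.n_lstm_layers == 2
        assert cfg.batch_size == 32
        assert cfg.learning_rate == 0.0001


class TestTrain:
    def test_empty_training_set_raises(self, small_synthetic):
        x, m, y = prepared(small_synthetic)
        model = build_model(tiny_arch(), x.shape[1:], seed=0)
        with pytest.raises(ValueError, match="empty"):
            train(model, (x[:0], m[:0], y[:0]), (x, m, y), TrainingConfig(max_epochs=1))

    def test_missing_class_warns(self, small_synthetic):
        x, m, y = prepared(small_synthetic)
        keep = y != 1
        model = build_model(tiny_arch(), x.shape[1:], seed=0)
        with pytest.warns(UserWarning, match="missing"):
            train(model, (x[keep], m[keep], y[keep]), (x, m, y),
                  TrainingConfig(max_epochs=1, patience=0))

    def test_history_structure(self, small_synthetic):
        x, m, y = prepared(small_synthetic)
        model = build_model(tiny_arch(), x.shape[1:], seed=0)
        hist = train(model, (x, m, y), (x, m, y), TrainingConfig(max_epochs=2, patience=5))
        assert len(hist["train_loss"]) == 2
        assert len(hist["val_macro_f1"]) == 2
        assert hist["stopped_epoch"] == 2

    def test_patience_zero_stops_at_first_non_improvement(self, small_synthetic):
        x, m, y = prepared(small_synthetic)
        model = build_model(tiny_arch(), x.shape[1:], seed=1)
        hist = train(model, (x, m, y), (x, m, y), TrainingConfig(max_epochs=60, patience=0))
        losses = hist["val_loss"]
        # every epoch except the last must have improved on the running best
        best = np.inf
        for loss in losses[:-1]:
            assert loss < best
            best = min(best, loss)
        if len(losses) < 60:
            assert losses[-1] >= best

    def test_overfits_separable_synthetic_set(self):
        # 60 repetitions with strong class effects: capacity suffices by design
        cfg = SyntheticConfig(
            n_subjects=5, reps_per_subject=12, n_imus=2, duration_range=(1.5, 2.5),
            sampling_rate=25.0, deviation_amplitude=3.0, restriction_factor=0.5,
            subject_effect_scale=0.05, noise_sd=0.05, affected_segments=2, seed=21,
        )
        ds = generate_dataset(cfg)
        x, m, y = prepared(ds)
        model = build_model(tiny_arch(batch_size=8, n_blocks=2), x.shape[1:], seed=2)
        model.config.learning_rate = 0.002  # small net, plain overfitting check
        hist = train(model, (x, m, y), (x, m, y), TrainingConfig(max_epochs=40, patience=40))
        assert max(hist["train_macro_f1"]) >= 0.95

    def test_reproducible_history(self, small_synthetic):
        x, m, y = prepared(small_synthetic)
        hists = []
        for _ in range(2):
            model = build_model(tiny_arch(), x.shape[1:], seed=3)
            hists.append(train(model, (x, m, y), (x, m, y),
                               TrainingConfig(max_epochs=2, patience=5, seed=3)))
        assert hists[0]["train_loss"] == hists[1]["train_loss"]


class TestRunCV:
    def test_five_folds_and_aggregate(self, small_synthetic):
        result = run_cv(small_synthetic, tiny_arch(), n_folds=5,
                        training_config=TrainingConfig(max_epochs=1, patience=0),
                        pad_length=80, seed=5)
        assert len(result.fold_reports) == 5
        macros = [fr["test"].macro_f1 for fr in result.fold_reports]
        assert result.aggregate["test"]["macro_f1_mean"] == pytest.approx(np.mean(macros))
        assert result.aggregate["test"]["macro_f1_sd"] == pytest.approx(np.std(macros))

    def test_reproducible(self, small_synthetic):
        kwargs = dict(n_folds=2, training_config=TrainingConfig(max_epochs=1, patience=0),
                      pad_length=80, seed=6)
        a = run_cv(small_synthetic, tiny_arch(), **kwargs)
        b = run_cv(small_synthetic, tiny_arch(), **kwargs)
        assert a.aggregate == b.aggregate
        for fa, fb in zip(a.fold_reports, b.fold_reports):
            assert np.array_equal(fa["test"].confusion, fb["test"].confusion)

    def test_reports_have_all_splits(self, small_synthetic):
        result = run_cv(small_synthetic, tiny_arch(), n_folds=2,
                        training_config=TrainingConfig(max_epochs=1, patience=0),
                        pad_length=80, seed=7)
        for fr in result.fold_reports:
            assert set(fr) == {"train", "val", "test"}
            assert all(isinstance(r, MetricReport) for r in fr.values())


class TestRunLosocv:
    def test_holds_out_subjects(self, small_synthetic):
        result = run_losocv(small_synthetic, tiny_arch(), n_folds=2,
                            training_config=TrainingConfig(max_epochs=1, patience=0),
                            pad_length=80, seed=8)
        held = result.seeds["held_out_subjects"]
        assert len(held) == 2 and len(set(held)) == 2
        # test-set sizes equal the held-out subjects' repetition counts
        for fr, subject in zip(result.fold_reports, held):
            n_subject = sum(1 for r in small_synthetic if r.subject_id == subject)
            assert fr["test"].n == n_subject


class TestRandomSearch:
    def test_sample_configs_reproducible(self):
        grid = HyperparameterGrid()
        a = sample_configs(grid, n_runs=90, base_seed=11)
        b = sample_configs(grid, n_runs=90, base_seed=11)
        assert a == b
        assert len(a) == 90

    def test_sampled_values_in_domains(self):
        grid = HyperparameterGrid()
        for cfg in sample_configs(grid, n_runs=90, base_seed=12):
            assert cfg.activation in grid.activation
            assert cfg.n_blocks in grid.n_blocks
            assert cfg.scheme in grid.scheme
            assert cfg.regularizer in grid.regularizer
            assert cfg.n_lstm_layers in grid.n_lstm_layers
            assert cfg.batch_size in grid.batch_size

    def test_dedupe_removes_duplicates(self):
        grid = HyperparameterGrid()
        configs = sample_configs(grid, n_runs=60, base_seed=13, dedupe=True)
        keys = {(c.activation, c.n_blocks, c.scheme, c.regularizer, c.n_lstm_layers, c.batch_size)
                for c in configs}
        assert len(keys) == 60

    @staticmethod
    def _stub_result(cfg, val_macro):
        report = MetricReport(np.zeros((3, 3), int), {1: 0, 2: 0, 3: 0}, val_macro, val_macro, 0)
        return RunResult(
            config=cfg,
            fold_reports=[{"train": report, "val": report, "test": report}],
            histories=[],
            aggregate={s: {"macro_f1_mean": val_macro, "macro_f1_sd": 0.0,
                           "weighted_f1_mean": val_macro, "weighted_f1_sd": 0.0}
                       for s in ("train", "val", "test")},
            seeds={},
        )

    def test_ranking_by_validation_macro_f1(self):
        grid = HyperparameterGrid()
        scores = {}

        def evaluate(cfg, run_index):
            rng = np.random.default_rng(run_index)
            score = float(rng.random())
            scores[run_index] = score
            return self._stub_result(cfg, score)

        results = random_search(grid, evaluate, n_runs=20, base_seed=14)
        assert sorted(r.run_index for r in results) == list(range(20))
        ranked = [scores[r.run_index] for r in results]
        assert ranked == sorted(ranked, reverse=True)

    def test_ties_broken_by_run_index(self):
        grid = HyperparameterGrid()

        def evaluate(cfg, run_index):
            return self._stub_result(cfg, 0.5)

        results = random_search(grid, evaluate, n_runs=10, base_seed=15)
        assert [r.run_index for r in results] == list(range(10))
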