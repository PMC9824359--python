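import numpy as np
import pytest

from repscore.core import ChannelLayout, Dataset
from repscore.preprocess import (
    Preprocessor,
    StandardizationParams,
    WindowingConfig,
    apply_standardization,
    build_per_imu_inputs,
    fit_standardization,
    pad_and_window,
    stack_channels,
)

from conftest import make_repetition


class TestStackChannels:
    def test_default_layout_gives_102_rows(self):
        layout = ChannelLayout()
        rep = make_repetition(layout, 7)
        assert stack_channels(rep, layout).shape == (102, 7)

    def test_two_imu_layout_gives_12_rows(self, tiny_layout):
        rep = make_repetition(tiny_layout, 5)
        assert stack_channels(rep, tiny_layout).shape == (12, 5)

    def test_gyro_y_of_imu_3_is_row_22(self):
        layout = ChannelLayout()
        assert layout.channel_row(3, 4) == 22
        assert layout.channel_names()[22] == layout.imu_order[3] + "_gyro_y"

    def test_layout_mismatch(self, tiny_layout):
        rep = make_repetition(ChannelLayout(imu_order=("a", "b", "c")), 5)
        with pytest.raises(ValueError, match="rows"):
            stack_channels(rep, tiny_layout)


class TestStandardization:
    def test_symmetric_pool(self, tiny_layout):
        rep = make_repetition(tiny_layout, 4)
        rep.data[tiny_layout.accel_rows()] = np.tile([-1.0, 1.0], (6, 2))
        rep.data[tiny_layout.gyro_rows()] = np.tile([-2.0, 2.0], (6, 2))
        params = fit_standardization([rep], tiny_layout)
        assert params.accel_mean == pytest.approx(0.0)
        assert params.accel_sd == pytest.approx(1.0)
        assert params.gyro_sd == pytest.approx(2.0)

    def test_fitting_set_standardizes_to_unit_moments(self, tiny_layout, rng):
        reps = [make_repetition(tiny_layout, t, f"r{t}", seed=t) for t in (11, 17, 23)]
        params = fit_standardization(reps, tiny_layout)
        accel_pool, gyro_pool = [], []
        for rep in reps:
            std = apply_standardization(rep.data, params, tiny_layout)
            accel_pool.append(std[tiny_layout.accel_rows()].ravel())
            gyro_pool.append(std[tiny_layout.gyro_rows()].ravel())
        for pool in (np.concatenate(accel_pool), np.concatenate(gyro_pool)):
            assert pool.mean() == pytest.approx(0.0, abs=1e-9)
            assert pool.std() == pytest.approx(1.0, abs=1e-9)

    def test_two_rep_pooled_oracle(self, tiny_layout):
        # hand-enumerated pooled statistics over both reps jointly
        r1 = make_repetition(tiny_layout, 3, "a", seed=1)
        r2 = make_repetition(tiny_layout, 5, "b", seed=2)
        params = fit_standardization([r1, r2], tiny_layout)
        accel_vals = []
        for rep in (r1, r2):
            for row in (0, 1, 2, 6, 7, 8):
                accel_vals.extend(rep.data[row].tolist())
        accel_vals = np.array(accel_vals)
        assert params.accel_mean == pytest.approx(accel_vals.mean(), abs=1e-12)
        assert params.accel_sd == pytest.approx(accel_vals.std(), abs=1e-12)

    def test_identity_params(self, tiny_layout):
        rep = make_repetition(tiny_layout, 6)
        params = StandardizationParams(0.0, 1.0, 0.0, 1.0)
        assert np.allclose(apply_standardization(rep.data, params, tiny_layout), rep.data)

    def test_constant_shift(self, tiny_layout):
        rep = make_repetition(tiny_layout, 6)
        params = StandardizationParams(5.0, 1.0, 0.0, 1.0)
        out = apply_standardization(rep.data, params, tiny_layout)
        assert np.allclose(out[tiny_layout.accel_rows()], rep.data[tiny_layout.accel_rows()] - 5.0)
        assert np.allclose(out[tiny_layout.gyro_rows()], rep.data[tiny_layout.gyro_rows()])

    def test_constant_pool_errors(self, tiny_layout):
        rep = make_repetition(tiny_layout, 4)
        rep.data[tiny_layout.accel_rows()] = 1.0
        with pytest.raises(ValueError, match="constant"):
            fit_standardization([rep], tiny_layout)

    def test_empty_collection_errors(self, tiny_layout):
        with pytest.raises(ValueError, match="empty"):
            fit_standardization([], tiny_layout)

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            StandardizationParams(0.0, 0.0, 0.0, 1.0)

    def test_refit_ignores_removed_test_rep(self, tiny_layout):
        reps = [make_repetition(tiny_layout, t, f"r{t}", seed=t) for t in (10, 12, 14, 16)]
        train = reps[:3]
        assert fit_standardization(train, tiny_layout) == fit_standardization(train, tiny_layout)


class TestWindowingConfig:
    def test_divisibility_enforced(self):
        with pytest.raises(ValueError, match="divisible"):
            WindowingConfig(n_windows=10, pad_length=105)

    def test_min_window_length_enforced(self):
        with pytest.raises(ValueError, match="minimum"):
            WindowingConfig(n_windows=10, pad_length=50)

    def test_from_training_lengths_rounds_up(self):
        config = WindowingConfig.from_training_lengths([95, 101], n_windows=10)
        assert config.pad_length == 110
        assert config.window_length == 11


class TestPadAndWindow:
    def test_exact_fit_all_masked_true(self):
        config = WindowingConfig(n_windows=10, pad_length=100)
        out = pad_and_window(np.ones((6, 100)), config)
        assert out.data.shape == (10, 6, 10)
        assert out.mask.all()

    def test_partial_fill_mask_boundaries(self, rng):
        config = WindowingConfig(n_windows=10, pad_length=100)
        out = pad_and_window(rng.standard_normal((6, 73)), config)
        assert out.mask.tolist() == [True] * 8 + [False, False]
        # window 8 (0-based 7) covers samples 70..79 and contains data up to 72
        assert np.any(out.data[7] != 0.0)
        assert np.all(out.data[8:] == 0.0)

    def test_padding_entries_exact_zeros(self, rng):
        config = WindowingConfig(n_windows=5, pad_length=50)
        matrix = rng.standard_normal((4, 37))
        out = pad_and_window(matrix, config)
        padded = out.reconstruct_padded()
        assert np.all(padded[:, 37:] == 0.0)

    def test_concatenation_reconstructs_padded_matrix(self, rng):
        config = WindowingConfig(n_windows=4, pad_length=48)
        matrix = rng.standard_normal((5, 31))
        out = pad_and_window(matrix, config)
        padded = np.zeros((5, 48))
        padded[:, :31] = matrix
        assert np.array_equal(out.reconstruct_padded(), padded)

    def test_injective_with_recorded_length(self, rng):
        config = WindowingConfig(n_windows=4, pad_length=48)
        matrix = rng.standard_normal((5, 31))
        out = pad_and_window(matrix, config)
        assert np.array_equal(out.reconstruct(), matrix)

    def test_too_long_repetition_errors(self):
        config = WindowingConfig(n_windows=4, pad_length=40)
        with pytest.raises(ValueError, match="exceeds pad length"):
            pad_and_window(np.ones((3, 41)), config)


class TestPerImuInputs:
    def _setup(self, n_imus=3, t=45):
        layout = ChannelLayout(imu_order=tuple(f"seg{k}" for k in range(n_imus)))
        rep = make_repetition(layout, t)
        params = fit_standardization([rep], layout)
        config = WindowingConfig(n_windows=5, pad_length=50)
        return layout, rep, params, config

    def test_one_entry_per_imu(self):
        layout, rep, params, config = self._setup()
        out = build_per_imu_inputs(rep, params, config, layout)
        assert len(out) == 3
        assert all(o.data.shape == (5, 6, 10) for o in out)

    def test_default_layout_gives_17_entries(self):
        layout, rep, params, config = self._setup(n_imus=17)
        out = build_per_imu_inputs(rep, params, config, layout)
        assert len(out) == 17

    def test_stacking_reproduces_baseline(self):
        layout, rep, params, config = self._setup()
        per_imu = build_per_imu_inputs(rep, params, config, layout)
        std = apply_standardization(rep.data, params, layout)
        baseline = pad_and_window(std, config)
        stacked = np.concatenate([o.data for o in per_imu], axis=1)
        assert np.array_equal(stacked, baseline.data)

    def test_masks_identical_to_baseline(self):
        layout, rep, params, config = self._setup()
        per_imu = build_per_imu_inputs(rep, params, config, layout)
        std = apply_standardization(rep.data, params, layout)
        baseline = pad_and_window(std, config)
        for o in per_imu:
            assert np.array_equal(o.mask, baseline.mask)


class TestPreprocessor:
    def test_fit_transform(self, tiny_layout):
        train = [make_repetition(tiny_layout, t, f"r{t}", seed=t) for t in (80, 95)]
        pre = Preprocessor(tiny_layout, n_windows=10).fit(train)
        assert pre.config.pad_length == 100
        out = pre.transform(train[0])
        assert out.data.shape == (10, 12, 10)

    def test_standardize_then_pad_gives_exact_zero_padding(self, tiny_layout):
        train = [make_repetition(tiny_layout, 90, "a", seed=3)]
        pre = Preprocessor(tiny_layout, n_windows=10, pad_length=120).fit(train)
        out = pre.transform(train[0])
        assert np.all(out.reconstruct_padded()[:, 90:] == 0.0)

    def test_unfitted_raises(self, tiny_layout):
        with pytest.raises(RuntimeError):
            Preprocessor(tiny_layout).transform(make_repetition(tiny_layout, 10))

    def test_longer_test_rep_raises(self, tiny_layout):
        pre = Preprocessor(tiny_layout, n_windows=10).fit(
            [make_repetition(tiny_layout, 90, "a")]
        )
        with pytest.raises(ValueError, match="exceeds"):
            pre.transform(make_repetition(tiny_layout, 150, "b"))
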