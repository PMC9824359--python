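import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from repscore.core import ChannelLayout, Dataset, Exercise, Repetition, Side
from repscore.synthetic import RaterConfig, SyntheticConfig, generate_dataset, simulate_raters


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_layout():
    return ChannelLayout(imu_order=("pelvis", "sternum"))


def make_repetition(layout, t, rep_id="r0", subject="S0", seed=0, label=None, scores=()):
    rng = np.random.default_rng(seed)
    return Repetition(
        repetition_id=rep_id,
        subject_id=subject,
        exercise=Exercise.DS,
        side=Side.NONE,
        data=rng.standard_normal((layout.n_channels, t)),
        rater_scores=scores,
        resolved_label=label,
    )


@pytest.fixture
def tiny_dataset(tiny_layout):
    reps = [
        make_repetition(tiny_layout, 10, "r0", "S0", seed=1, label=3, scores=(3, 3, 3)),
        make_repetition(tiny_layout, 20, "r1", "S1", seed=2, label=2, scores=(2, 2, 1)),
    ]
    return Dataset(repetitions=reps, layout=tiny_layout, manifest={"origin": "fixture"})


@pytest.fixture(scope="session")
def small_synthetic():
    """A small but learnable synthetic dataset shared across tests."""
    cfg = SyntheticConfig(
        n_subjects=4,
        reps_per_subject=12,
        n_imus=2,
        duration_range=(1.5, 2.5),
        sampling_rate=25.0,
        deviation_amplitude=3.0,
        restriction_factor=0.5,
        subject_effect_scale=0.05,
        noise_sd=0.05,
        affected_segments=2,
        seed=99,
    )
    ds = generate_dataset(cfg)
    simulate_raters(ds, RaterConfig(p_off_by_one=0.0, p_off_by_two=0.0, seed=100))
    return ds
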