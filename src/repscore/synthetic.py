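"""Synthetic dataset generation.

Produces datasets with the statistical structure the scoring method assumes:
variable-length repetitions, class-dependent movement deviations localized
in time and in a subset of body segments, subject-specific amplitude and
timing idiosyncrasies, additive sensor noise, and noisy three-rater scoring.

Construction of one repetition:

1. a smooth per-segment motion template — a sum of Gaussian-windowed
   sinusoids over normalized repetition time, drawn once per dataset;
2. per-subject multiplicative amplitude and global time-warp factors, drawn
   once per subject with spread ``subject_effect_scale``;
3. the class effect: score 3 leaves the template unchanged; score 2 adds one
   localized deviation burst on ``affected_segments`` IMUs at a random
   phase; score 1 additionally shrinks all amplitudes by
   ``restriction_factor``;
4. additive white Gaussian noise with standard deviation ``noise_sd`` (in
   units of each modality's base amplitude).

Movement and rater randomness use two independent streams so rater noise can
be varied at fixed kinematics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from repscore.core import ChannelLayout, Dataset, Exercise, Repetition, Side

__all__ = ["SyntheticConfig", "RaterConfig", "generate_dataset", "simulate_raters"]

_N_HARMONICS = 3


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic movement generator."""

    n_subjects: int = 17
    reps_per_subject: int = 36
    class_probabilities: tuple[float, float, float] = (0.25, 0.35, 0.40)
    duration_range: tuple[float, float] = (2.0, 6.0)
    sampling_rate: float = 120.0
    n_imus: int = 17
    accel_base_amplitude: float = 1.0  # g
    gyro_base_amplitude: float = 60.0  # deg/s
    deviation_amplitude: float = 1.0
    restriction_factor: float = 0.6
    subject_effect_scale: float = 0.10
    noise_sd: float = 0.05
    affected_segments: int = 4
    exercise: Exercise = Exercise.DS
    side: Side = Side.NONE
    seed: int = 0

    def __post_init__(self) -> None:
        probs = np.asarray(self.class_probabilities, dtype=float)
        if probs.shape != (3,) or np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("class_probabilities must be a 3-simplex")
        lo, hi = self.duration_range
        if not (0 < lo <= hi):
            raise ValueError("duration_range must be positive and ordered")
        if not 0.0 < self.restriction_factor <= 1.0:
            raise ValueError("restriction_factor must lie in (0, 1]")
        if not 1 <= self.affected_segments <= self.n_imus:
            raise ValueError("affected_segments must lie in 1..n_imus")
        if self.n_subjects < 1 or self.reps_per_subject < 1:
            raise ValueError("need at least one subject and one repetition")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        self.exercise = Exercise(self.exercise)
        self.side = Side(self.side)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["exercise"] = self.exercise.value
        d["side"] = self.side.value
        d["class_probabilities"] = list(self.class_probabilities)
        d["duration_range"] = list(self.duration_range)
        return d


@dataclass
class RaterConfig:
    """Noisy-rater model: each of ``n_raters`` independently reports the true
    label, an off-by-one error, or a two-point error."""

    n_raters: int = 3
    p_off_by_one: float = 0.1
    p_off_by_two: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_raters < 1:
            raise ValueError("need at least one rater")
        if min(self.p_off_by_one, self.p_off_by_two) < 0 or self.p_off_by_one + self.p_off_by_two > 1:
            raise ValueError("error probabilities must be nonnegative and sum to <= 1")


def _template_params(rng: np.random.Generator, n_imus: int) -> dict:
    """Per-dataset motion template: Gaussian-windowed sinusoid banks per channel."""
    shape = (n_imus, 6, _N_HARMONICS)
    return {
        "amp": rng.uniform(0.3, 1.0, size=shape),
        "freq": rng.uniform(0.5, 3.0, size=shape),
        "phase": rng.uniform(0.0, 2 * np.pi, size=shape),
        "center": rng.uniform(0.15, 0.85, size=shape),
        "width": rng.uniform(0.08, 0.30, size=shape),
    }


def _eval_template(params: dict, tau: np.ndarray) -> np.ndarray:
    """Evaluate the template on normalized time tau; returns (n_imus, 6, T)."""
    amp = params["amp"][..., None]
    freq = params["freq"][..., None]
    phase = params["phase"][..., None]
    center = params["center"][..., None]
    width = params["width"][..., None]
    t = tau[None, None, None, :]
    envelope = np.exp(-((t - center) ** 2) / (2.0 * width**2))
    waves = amp * envelope * np.sin(2 * np.pi * freq * t + phase)
    return waves.sum(axis=2)


def generate_dataset(config: SyntheticConfig) -> Dataset:
    """Generate ``n_subjects * reps_per_subject`` labeled repetitions.

    Fully reproducible from ``config.seed``; the true label is stored as
    ``resolved_label`` (rater scores are added separately by
    :func:`simulate_raters`).
    """
    rng = np.random.default_rng(config.seed)
    layout = ChannelLayout(imu_order=tuple(f"segment_{k:02d}" for k in range(config.n_imus)))
    template = _template_params(rng, config.n_imus)
    affected = rng.choice(config.n_imus, size=config.affected_segments, replace=False)
    modality_scale = np.empty((config.n_imus, 6, 1))
    modality_scale[:, :3, 0] = config.accel_base_amplitude
    modality_scale[:, 3:, 0] = config.gyro_base_amplitude

    reps: list[Repetition] = []
    for s in range(config.n_subjects):
        subject_id = f"S{s:02d}"
        amp_factor = max(0.1, 1.0 + config.subject_effect_scale * rng.standard_normal())
        warp = float(np.clip(1.0 + config.subject_effect_scale * rng.standard_normal(), 0.5, 2.0))
        for r in range(config.reps_per_subject):
            duration = rng.uniform(*config.duration_range) * warp
            t_steps = max(1, int(round(duration * config.sampling_rate)))
            label = int(rng.choice((1, 2, 3), p=config.class_probabilities))
            tau = np.linspace(0.0, 1.0, t_steps)
            motion = _eval_template(template, tau) * modality_scale

            if label in (1, 2):
                burst_center = rng.uniform(0.2, 0.8)
                burst_freq = rng.uniform(3.0, 6.0)
                burst_phase = rng.uniform(0.0, 2 * np.pi)
                envelope = np.exp(-((tau - burst_center) ** 2) / (2.0 * 0.05**2))
                burst = (
                    config.deviation_amplitude
                    * envelope
                    * np.sin(2 * np.pi * burst_freq * tau + burst_phase)
                )
                motion[affected] += burst[None, None, :] * modality_scale[affected]
            if label == 1:
                motion *= config.restriction_factor
            # subject idiosyncrasy scales the whole movement, class effect
            # included, so absolute amplitude is confounded across subjects
            motion *= amp_factor

            noise = rng.standard_normal(motion.shape) * (config.noise_sd * modality_scale)
            motion = motion + noise
            reps.append(
                Repetition(
                    repetition_id=f"{subject_id}_r{r:03d}",
                    subject_id=subject_id,
                    exercise=config.exercise,
                    side=config.side,
                    data=motion.reshape(layout.n_channels, t_steps),
                    sampling_rate=config.sampling_rate,
                    resolved_label=label,
                )
            )
    manifest = {
        "generator": "repscore.synthetic",
        "config": config.to_dict(),
        "affected_segments": sorted(int(a) for a in affected),
    }
    return Dataset(repetitions=reps, layout=layout, manifest=manifest)


def _rate_once(true: int, rng: np.random.Generator, config: RaterConfig) -> int:
    u = rng.random()
    if u < config.p_off_by_two:
        # two-point errors exist only at the extremes; from the middle score
        # the farthest reachable report is one point away
        if true == 1:
            return 3
        if true == 3:
            return 1
        return int(rng.choice((1, 3)))
    if u < config.p_off_by_two + config.p_off_by_one:
        if true == 1:
            return 2
        if true == 3:
            return 2
        return int(rng.choice((1, 3)))
    return true


def simulate_raters(dataset: Dataset, config: RaterConfig) -> Dataset:
    """Fill ``rater_scores`` for every repetition from its true label (in place).

    Raters are independent; reproducible from ``config.seed``.  Raises if any
    repetition lacks a true label.
    """
    rng = np.random.default_rng(config.seed)
    for rep in dataset.repetitions:
        if rep.resolved_label is None:
            raise ValueError(f"repetition {rep.repetition_id} has no true label to rate")
        rep.rater_scores = tuple(
            _rate_once(rep.resolved_label, rng, config) for _ in range(config.n_raters)
        )
    dataset.manifest.setdefault("rater_config", asdict(config))
    return dataset
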