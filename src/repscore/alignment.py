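"""Sensor-to-segment alignment.

Each IMU's orientation relative to its body segment is composed from three
marker-derived rotations (IMU->camera, room->camera, segment->room); the
resulting rotation is applied to the accelerometer and gyroscope triplets of
that IMU so all subjects share segment coordinate frames.

Convention: a rotation ``R_a_to_b`` maps coordinates of a vector expressed in
frame ``a`` to its coordinates in frame ``b``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np

from repscore.core import ChannelLayout, Repetition

ORTHONORMALITY_TOL = 1e-9

__all__ = [
    "check_rotation",
    "sensor_to_segment",
    "apply_alignment",
    "load_rotation_sets",
    "save_rotation_sets",
]


def check_rotation(r: np.ndarray, tol: float = ORTHONORMALITY_TOL) -> np.ndarray:
    """Validate that ``r`` is a proper rotation matrix (orthonormal, det +1)."""
    r = np.asarray(r, dtype=np.float64)
    if r.shape != (3, 3):
        raise ValueError(f"rotation must be 3x3, got {r.shape}")
    if not np.allclose(r.T @ r, np.eye(3), atol=tol, rtol=0.0):
        raise ValueError("matrix is not orthonormal")
    if abs(np.linalg.det(r) - 1.0) > tol:
        raise ValueError("matrix determinant is not +1 (improper rotation)")
    return r


def sensor_to_segment(
    r_imu_to_cam: np.ndarray,
    r_room_to_cam: np.ndarray,
    r_segment_to_room: np.ndarray,
) -> np.ndarray:
    """Compose the IMU-to-body-segment rotation from marker-derived rotations.

    R_imu->segment = R_segment->room^-1 . R_room->cam^-1 . R_imu->cam
    """
    a = check_rotation(r_imu_to_cam)
    b = check_rotation(r_room_to_cam)
    c = check_rotation(r_segment_to_room)
    return c.T @ b.T @ a


def apply_alignment(
    rep: Repetition, rotations: Sequence[np.ndarray], layout: ChannelLayout | None = None
) -> Repetition:
    """Rotate every IMU's accelerometer and gyroscope triplets into segment frames.

    One rotation per IMU; the same matrix is applied to both triplets at every
    time step (rigid sensor assumption).  Returns a new Repetition; metadata
    is unchanged and per-sample vector norms are preserved.
    """
    layout = layout or ChannelLayout(
        imu_order=tuple(f"imu{k}" for k in range(rep.data.shape[0] // 6))
    )
    if len(rotations) != layout.n_imus:
        raise ValueError(f"need {layout.n_imus} rotations (one per IMU), got {len(rotations)}")
    data = rep.data.copy()
    for k, rot in enumerate(rotations):
        r = check_rotation(rot)
        base = layout.channels_per_imu * k
        data[base : base + 3, :] = r @ data[base : base + 3, :]
        data[base + 3 : base + 6, :] = r @ data[base + 3 : base + 6, :]
    return Repetition(
        repetition_id=rep.repetition_id,
        subject_id=rep.subject_id,
        exercise=rep.exercise,
        side=rep.side,
        data=data,
        sampling_rate=rep.sampling_rate,
        rater_scores=rep.rater_scores,
        resolved_label=rep.resolved_label,
    )


def save_rotation_sets(rotations: dict[str, list[np.ndarray]], path: str | Path) -> None:
    """Write per-subject, per-IMU rotation sets as structured text (JSON, row-major)."""
    payload = {
        subject: [np.asarray(r, dtype=np.float64).reshape(9).tolist() for r in rots]
        for subject, rots in rotations.items()
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_rotation_sets(path: str | Path) -> dict[str, list[np.ndarray]]:
    """Read rotation sets written by :func:`save_rotation_sets`; validates each matrix."""
    with open(path) as fh:
        payload = json.load(fh)
    return {
        subject: [check_rotation(np.asarray(flat, dtype=np.float64).reshape(3, 3)) for flat in rots]
        for subject, rots in payload.items()
    }
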