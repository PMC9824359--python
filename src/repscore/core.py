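"""Domain types, dataset container, and on-disk dataset storage.

A dataset directory holds one ``manifest.json`` plus one ``.npy`` array file
per repetition.  The manifest records the channel layout, the label map
(score ``1``/``2``/``3`` to class index ``0``/``1``/``2``), creation metadata,
and an index entry per repetition (id, subject, exercise, side, sampling
rate, rater scores, resolved label, array file name and shape).  Variable
repetition durations rule out a single rectangular table, hence per-
repetition array files.

Channel convention: channels are stacked IMU by IMU, with the accelerometer
x, y, z axes first, then the gyroscope x, y, z axes.  Channel ``c`` of IMU
``k`` therefore sits at row ``6 * k + c``.  Units are stored as recorded:
accelerometer in g, gyroscope in degrees per second.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

VALID_SCORES = (1, 2, 3)

#: score value <-> class index; fixed ascending order
LABEL_MAP = {1: 0, 2: 1, 3: 2}
INDEX_TO_LABEL = {v: k for k, v in LABEL_MAP.items()}

MANIFEST_NAME = "manifest.json"

#: Default 17-segment full-body placement (pelvis to feet).
DEFAULT_SEGMENTS = (
    "pelvis",
    "sternum",
    "head",
    "right_shoulder",
    "right_upper_arm",
    "right_forearm",
    "right_hand",
    "left_shoulder",
    "left_upper_arm",
    "left_forearm",
    "left_hand",
    "right_upper_leg",
    "right_lower_leg",
    "right_foot",
    "left_upper_leg",
    "left_lower_leg",
    "left_foot",
)

CHANNEL_SUFFIXES = ("accel_x", "accel_y", "accel_z", "gyro_x", "gyro_y", "gyro_z")


class Exercise(str, enum.Enum):
    """Exercise identifier."""

    DS = "DS"
    HS = "HS"
    IL = "IL"
    TSP = "TSP"


class Side(str, enum.Enum):
    """Active side of an exercise repetition; NONE for symmetric exercises."""

    LEFT = "left"
    RIGHT = "right"
    NONE = "none"


@dataclass(frozen=True)
class ChannelLayout:
    """Fixed ordering of IMU channels as rows of the repetition matrix.

    Parameters
    ----------
    imu_order
        Segment name per IMU, in row-block order.
    channels_per_imu
        Number of channels per IMU (3 accelerometer + 3 gyroscope axes).
    """

    imu_order: tuple[str, ...] = DEFAULT_SEGMENTS
    channels_per_imu: int = 6

    def __post_init__(self) -> None:
        if len(self.imu_order) < 1:
            raise ValueError("layout needs at least one IMU")
        if len(set(self.imu_order)) != len(self.imu_order):
            raise ValueError("duplicate segment names in imu_order")
        if self.channels_per_imu != 6:
            raise ValueError("layout requires 6 channels per IMU (3 accel + 3 gyro)")
        object.__setattr__(self, "imu_order", tuple(self.imu_order))

    @property
    def n_imus(self) -> int:
        return len(self.imu_order)

    @property
    def n_channels(self) -> int:
        """Total number of matrix rows."""
        return self.n_imus * self.channels_per_imu

    def channel_row(self, imu_index: int, channel: int) -> int:
        """Row index of channel ``channel`` of IMU ``imu_index`` (``6k + c``)."""
        if not 0 <= imu_index < self.n_imus:
            raise IndexError(f"imu_index {imu_index} outside 0..{self.n_imus - 1}")
        if not 0 <= channel < self.channels_per_imu:
            raise IndexError(f"channel {channel} outside 0..{self.channels_per_imu - 1}")
        return self.channels_per_imu * imu_index + channel

    def channel_names(self) -> list[str]:
        return [f"{seg}_{suf}" for seg in self.imu_order for suf in CHANNEL_SUFFIXES]

    def accel_rows(self) -> np.ndarray:
        """Row indices of all accelerometer channels."""
        base = np.arange(self.n_imus) * self.channels_per_imu
        return (base[:, None] + np.arange(3)[None, :]).ravel()

    def gyro_rows(self) -> np.ndarray:
        """Row indices of all gyroscope channels."""
        base = np.arange(self.n_imus) * self.channels_per_imu + 3
        return (base[:, None] + np.arange(3)[None, :]).ravel()

    def to_dict(self) -> dict:
        return {
            "imu_order": list(self.imu_order),
            "channels_per_imu": self.channels_per_imu,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelLayout":
        return cls(
            imu_order=tuple(d["imu_order"]),
            channels_per_imu=int(d["channels_per_imu"]),
        )


@dataclass
class Repetition:
    """One exercise execution: channel matrix plus metadata and labels.

    ``data`` has shape ``(layout.n_channels, T)`` with ``T >= 1`` time steps.
    ``rater_scores`` holds 0-3 raw ordinal scores in {1, 2, 3};
    ``resolved_label`` is the majority-vote label, or ``None`` if unresolved
    or excluded.
    """

    repetition_id: str
    subject_id: str
    exercise: Exercise
    side: Side
    data: np.ndarray
    sampling_rate: float = 120.0
    rater_scores: tuple[int, ...] = ()
    resolved_label: int | None = None

    def __post_init__(self) -> None:
        self.exercise = Exercise(self.exercise)
        self.side = Side(self.side)
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError(f"repetition {self.repetition_id}: data must be 2-D")
        if self.data.shape[1] < 1:
            raise ValueError(f"repetition {self.repetition_id}: needs at least 1 time step")
        self.rater_scores = tuple(int(s) for s in self.rater_scores)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return self.n_samples / self.sampling_rate


@dataclass
class Dataset:
    """Ordered collection of repetitions sharing one channel layout."""

    repetitions: list[Repetition] = field(default_factory=list)
    layout: ChannelLayout = field(default_factory=ChannelLayout)
    manifest: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.repetitions)

    def __iter__(self) -> Iterator[Repetition]:
        return iter(self.repetitions)

    def __getitem__(self, key: int) -> Repetition:
        return self.repetitions[key]

    def subject_ids(self) -> list[str]:
        """Distinct subject ids in first-appearance order."""
        seen: dict[str, None] = {}
        for rep in self.repetitions:
            seen.setdefault(rep.subject_id, None)
        return list(seen)

    def labels(self) -> np.ndarray:
        """Resolved labels as an int array; raises if any repetition is unresolved."""
        out = []
        for rep in self.repetitions:
            if rep.resolved_label is None:
                raise ValueError(f"repetition {rep.repetition_id} has no resolved label")
            out.append(rep.resolved_label)
        return np.asarray(out, dtype=np.int64)


@dataclass(frozen=True)
class Violation:
    """One invariant violation found by :func:`validate_dataset`."""

    repetition_id: str | None
    rule: str
    message: str


def validate_dataset(dataset: Dataset) -> list[Violation]:
    """Check all dataset invariants; returns a list of violations (never raises)."""
    violations: list[Violation] = []
    seen: set[str] = set()
    n_rows = dataset.layout.n_channels
    for rep in dataset.repetitions:
        if rep.repetition_id in seen:
            violations.append(
                Violation(rep.repetition_id, "unique_id", f"duplicate repetition_id {rep.repetition_id!r}")
            )
        seen.add(rep.repetition_id)
        if rep.data.shape[0] != n_rows:
            violations.append(
                Violation(
                    rep.repetition_id,
                    "row_count",
                    f"expected {n_rows} channel rows, found {rep.data.shape[0]}",
                )
            )
        if rep.data.shape[1] < 1:
            violations.append(Violation(rep.repetition_id, "min_length", "repetition has no samples"))
        for score in rep.rater_scores:
            if score not in VALID_SCORES:
                violations.append(
                    Violation(rep.repetition_id, "score_domain", f"rater score {score} outside {{1,2,3}}")
                )
        if len(rep.rater_scores) > 3:
            violations.append(
                Violation(rep.repetition_id, "score_count", f"{len(rep.rater_scores)} rater scores (max 3)")
            )
        if rep.resolved_label is not None and rep.resolved_label not in VALID_SCORES:
            violations.append(
                Violation(
                    rep.repetition_id, "label_domain", f"resolved label {rep.resolved_label} outside {{1,2,3}}"
                )
            )
        if rep.sampling_rate <= 0:
            violations.append(
                Violation(rep.repetition_id, "sampling_rate", f"sampling rate {rep.sampling_rate} not positive")
            )
    return violations


def write_dataset(dataset: Dataset, path: str | Path) -> None:
    """Write a dataset directory: ``manifest.json`` + one ``.npy`` file per repetition.

    Round trip through :func:`read_dataset` reproduces the dataset exactly
    (bit-exact metadata, value-exact arrays).

    Raises
    ------
    ValueError
        On duplicate repetition ids.
    OSError
        If the path is not writable.
    """
    path = Path(path)
    ids = [rep.repetition_id for rep in dataset.repetitions]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ValueError(f"duplicate repetition ids: {sorted(dupes)}")
    path.mkdir(parents=True, exist_ok=True)
    index = []
    for rep in dataset.repetitions:
        fname = f"{rep.repetition_id}.npy"
        np.save(path / fname, rep.data)
        index.append(
            {
                "repetition_id": rep.repetition_id,
                "subject_id": rep.subject_id,
                "exercise": rep.exercise.value,
                "side": rep.side.value,
                "sampling_rate": rep.sampling_rate,
                "rater_scores": list(rep.rater_scores),
                "resolved_label": rep.resolved_label,
                "file": fname,
                "shape": list(rep.data.shape),
            }
        )
    manifest = {
        "format_version": 1,
        "layout": dataset.layout.to_dict(),
        "label_map": {str(k): v for k, v in LABEL_MAP.items()},
        "metadata": dataset.manifest,
        "index": index,
    }
    with open(path / MANIFEST_NAME, "w") as fh:
        json.dump(manifest, fh, indent=2)


def read_dataset(path: str | Path) -> Dataset:
    """Read a dataset directory written by :func:`write_dataset`.

    Raises
    ------
    FileNotFoundError
        If the manifest or a referenced array file is missing (names the file).
    ValueError
        On row-count mismatch against the layout, or scores outside {1,2,3}.
    """
    path = Path(path)
    manifest_path = path / MANIFEST_NAME
    if not manifest_path.exists():
        raise FileNotFoundError(f"no {MANIFEST_NAME} in {path}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    layout = ChannelLayout.from_dict(manifest["layout"])
    reps: list[Repetition] = []
    for entry in manifest["index"]:
        array_path = path / entry["file"]
        if not array_path.exists():
            raise FileNotFoundError(
                f"manifest references missing array file {entry['file']!r} "
                f"for repetition {entry['repetition_id']!r}"
            )
        data = np.load(array_path)
        if data.shape[0] != layout.n_channels:
            raise ValueError(
                f"repetition {entry['repetition_id']!r}: array has {data.shape[0]} rows, "
                f"layout requires {layout.n_channels}"
            )
        scores = tuple(int(s) for s in entry["rater_scores"])
        for s in scores:
            if s not in VALID_SCORES:
                raise ValueError(f"repetition {entry['repetition_id']!r}: rater score {s} outside {{1,2,3}}")
        label = entry["resolved_label"]
        reps.append(
            Repetition(
                repetition_id=entry["repetition_id"],
                subject_id=entry["subject_id"],
                exercise=Exercise(entry["exercise"]),
                side=Side(entry["side"]),
                data=data,
                sampling_rate=float(entry["sampling_rate"]),
                rater_scores=scores,
                resolved_label=None if label is None else int(label),
            )
        )
    return Dataset(repetitions=reps, layout=layout, manifest=manifest.get("metadata", {}))


def export_repetition_csv(rep: Repetition, layout: ChannelLayout, path: str | Path) -> None:
    """Delimited-text export of one repetition for inspection (rows = channels)."""
    names = layout.channel_names()
    with open(path, "w") as fh:
        fh.write("channel," + ",".join(f"t{j}" for j in range(rep.n_samples)) + "\n")
        for name, row in zip(names, rep.data):
            fh.write(name + "," + ",".join(format(v, ".10g") for v in row) + "\n")
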