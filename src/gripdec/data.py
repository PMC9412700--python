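"""Containers for glove-recorded movement trials and their on-disk format.

A recording session yields trial-segmented multichannel angular time series
from the 15 flexion sensors of an exoskeleton data glove (three joints J1-J3
on each digit D1-D5), sampled at 100 Hz, plus a per-subject calibration
(per-channel sensor extrema from held postures such as flat hand and fist)
and subject metadata.  Datasets round-trip through a single HDF5 container
with one dataset per trial, ragged trial lengths allowed; a per-trial CSV
export is provided for interoperability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import h5py
import numpy as np

#: The six movement tasks, in block presentation order.
TASKS: tuple[str, ...] = (
    "clothes_peg",
    "fingertip_touching",
    "rubiks_cw",
    "rubiks_ccw",
    "small_rubiks_cw",
    "small_rubiks_ccw",
)

#: Flexion sensor channels: joints J1-J3 of digits D1-D5.
CHANNEL_NAMES: tuple[str, ...] = tuple(
    f"D{d}J{j}" for d in range(1, 6) for j in range(1, 4)
)

N_CHANNELS = len(CHANNEL_NAMES)

STAGES = ("raw", "normalized", "velocity", "aligned")

AGE_GROUPS = ("young", "old")


class DatasetValidationError(ValueError):
    """Raised when a dataset or container violates its invariants."""


@dataclass
class Trial:
    """One movement sequence: a (time x channel) series plus metadata.

    ``values`` holds raw sensor angles (device units), calibration-normalized
    angles, angular velocity (units/s) or template-aligned velocity, as
    indicated by ``stage``.
    """

    values: np.ndarray
    sample_rate: float
    subject_id: str
    run: int
    block: int
    task: str
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DatasetValidationError("trial values must be 2-D (time x channel)")
        if self.values.shape[0] < 2:
            raise DatasetValidationError("trial must have at least 2 samples")
        if self.task not in TASKS:
            raise DatasetValidationError(f"unknown task label {self.task!r}")
        if self.stage not in STAGES:
            raise DatasetValidationError(f"unknown stage {self.stage!r}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    def with_values(self, values: np.ndarray, *, stage: str | None = None,
                    sample_rate: float | None = None) -> "Trial":
        """Copy of this trial with new values (and optionally stage/rate)."""
        return replace(
            self,
            values=np.asarray(values, dtype=float),
            stage=self.stage if stage is None else stage,
            sample_rate=self.sample_rate if sample_rate is None else sample_rate,
        )


@dataclass
class Calibration:
    """Per-channel sensor extrema recorded from a subject's held postures."""

    minimum: np.ndarray
    maximum: np.ndarray

    def __post_init__(self) -> None:
        self.minimum = np.asarray(self.minimum, dtype=float)
        self.maximum = np.asarray(self.maximum, dtype=float)
        if self.minimum.shape != self.maximum.shape or self.minimum.ndim != 1:
            raise DatasetValidationError("calibration extrema must be equal-length 1-D")
        if not np.all(self.maximum > self.minimum):
            raise DatasetValidationError("calibration max must exceed min per channel")

    @property
    def n_channels(self) -> int:
        return self.minimum.shape[0]


@dataclass
class SubjectMeta:
    """Subject covariates: age, age group and hand length (wrist to D3 tip)."""

    subject_id: str
    age: float
    age_group: str
    hand_size: float

    def __post_init__(self) -> None:
        if self.age_group not in AGE_GROUPS:
            raise DatasetValidationError(f"unknown age group {self.age_group!r}")
        if not self.hand_size > 0:
            raise DatasetValidationError("hand_size must be positive")


@dataclass
class Dataset:
    """A collection of trials with per-subject metadata and calibration."""

    trials: list[Trial] = field(default_factory=list)
    subjects: dict[str, SubjectMeta] = field(default_factory=dict)
    calibrations: dict[str, Calibration] = field(default_factory=dict)

    def validate(self) -> None:
        if self.trials:
            c0 = self.trials[0].n_channels
            for i, tr in enumerate(self.trials):
                if tr.n_channels != c0:
                    raise DatasetValidationError(
                        f"trial {i} has {tr.n_channels} channels, expected {c0}"
                    )
                if tr.subject_id not in self.subjects:
                    raise DatasetValidationError(
                        f"trial {i}: unknown subject {tr.subject_id!r}"
                    )
                if tr.subject_id not in self.calibrations:
                    raise DatasetValidationError(
                        f"missing calibration for subject {tr.subject_id!r}"
                    )

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def subject_ids(self) -> list[str]:
        return sorted(self.subjects)

    def labels(self) -> np.ndarray:
        return np.array([t.task for t in self.trials])

    def subset(self, indices: Iterable[int]) -> "Dataset":
        idx = list(indices)
        keep = {self.trials[i].subject_id for i in idx}
        return Dataset(
            trials=[self.trials[i] for i in idx],
            subjects={s: m for s, m in self.subjects.items() if s in keep},
            calibrations={s: c for s, c in self.calibrations.items() if s in keep},
        )


# ---------------------------------------------------------------------------
# HDF5 container
# ---------------------------------------------------------------------------

def write_dataset(dataset: Dataset, path: str | Path) -> None:
    """Write a dataset to a single HDF5 container.

    Layout: ``/trials/<idx>/values`` float64 datasets with trial metadata as
    attributes; subject metadata and calibrations JSON-serialized in root
    attributes; task label set and channel ordering declared once.
    """
    dataset.validate()
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "gripdec-dataset-v1"
        f.attrs["tasks"] = json.dumps(list(TASKS))
        f.attrs["channels"] = json.dumps(list(CHANNEL_NAMES))
        f.attrs["subjects"] = json.dumps({
            s: {"age": m.age, "age_group": m.age_group, "hand_size": m.hand_size}
            for s, m in dataset.subjects.items()
        })
        f.attrs["calibrations"] = json.dumps({
            s: {"minimum": c.minimum.tolist(), "maximum": c.maximum.tolist()}
            for s, c in dataset.calibrations.items()
        })
        grp = f.create_group("trials")
        for i, tr in enumerate(dataset.trials):
            d = grp.create_dataset(str(i), data=tr.values)
            d.attrs["sample_rate"] = tr.sample_rate
            d.attrs["subject_id"] = tr.subject_id
            d.attrs["run"] = tr.run
            d.attrs["block"] = tr.block
            d.attrs["task"] = tr.task
            d.attrs["stage"] = tr.stage


def read_dataset(path: str | Path) -> Dataset:
    """Read a dataset written by :func:`write_dataset`, validating invariants."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        if f.attrs.get("format") != "gripdec-dataset-v1":
            raise DatasetValidationError(f"{path}: not a gripdec dataset container")
        subjects = {
            s: SubjectMeta(subject_id=s, **m)
            for s, m in json.loads(f.attrs["subjects"]).items()
        }
        calibrations = {
            s: Calibration(np.array(c["minimum"]), np.array(c["maximum"]))
            for s, c in json.loads(f.attrs["calibrations"]).items()
        }
        trials = []
        grp = f["trials"]
        for key in sorted(grp, key=int):
            d = grp[key]
            trials.append(Trial(
                values=d[()],
                sample_rate=float(d.attrs["sample_rate"]),
                subject_id=str(d.attrs["subject_id"]),
                run=int(d.attrs["run"]),
                block=int(d.attrs["block"]),
                task=str(d.attrs["task"]),
                stage=str(d.attrs["stage"]),
            ))
    ds = Dataset(trials=trials, subjects=subjects, calibrations=calibrations)
    ds.validate()
    return ds


def export_trials_csv(dataset: Dataset, directory: str | Path) -> list[Path]:
    """Export each trial as a CSV (rows = samples, columns = channel names)."""
    import pandas as pd

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, tr in enumerate(dataset.trials):
        cols = list(CHANNEL_NAMES[: tr.n_channels])
        p = directory / f"trial_{i:05d}_{tr.subject_id}_{tr.task}.csv"
        pd.DataFrame(tr.values, columns=cols).to_csv(p, index=False)
        paths.append(p)
    return paths
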