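"""Readers and writers for the on-disk formats the pipeline touches.

Tracking streams are plain TSV with a fixed column schema, EEG travels as EDF
(see :mod:`stridelock.edf`), and events are BIDS-style ``events.tsv`` tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from . import edf

TRACKING_COLUMNS = [
    "time_s",
    "head_x", "head_y", "head_z",
    "gaze_origin_x", "gaze_origin_y", "gaze_origin_z",
    "gaze_dir_x", "gaze_dir_y", "gaze_dir_z",
    "trial_id",
]

#: 10-20 scalp montage used throughout, in canonical order.
SCALP_CHANNELS = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "O2",
]
REFERENCE_CHANNELS = ["A1", "A2"]


class Condition(str, Enum):
    STATIC = "static"
    SLOW = "slow"
    NATURAL = "natural"


class FormatError(ValueError):
    """Raised when an on-disk file violates the expected schema."""


@dataclass
class GazeHeadRecording:
    """Synchronized tracking streams sampled at ``rate`` Hz.

    ``head_pos``, ``gaze_origin`` and ``gaze_dir`` are (n, 3) arrays; gaze
    directions are unit vectors.  ``dropouts`` lists (start_s, end_s,
    n_missing) spans where more than two consecutive samples are missing.
    """

    time: np.ndarray
    head_pos: np.ndarray
    gaze_origin: np.ndarray
    gaze_dir: np.ndarray
    trial_id: np.ndarray
    rate: float
    dropouts: list = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return len(self.time)

    def copy(self) -> "GazeHeadRecording":
        return GazeHeadRecording(
            self.time.copy(), self.head_pos.copy(), self.gaze_origin.copy(),
            self.gaze_dir.copy(), self.trial_id.copy(), self.rate,
            list(self.dropouts),
        )


@dataclass
class EEGRecording:
    """Channels x time EEG at ``rate`` Hz with trigger events."""

    labels: list
    data: np.ndarray
    rate: float
    triggers: list = field(default_factory=list)
    bad_channels: list = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.labels.index(label)]

    def pick(self, labels: list) -> "EEGRecording":
        idx = [self.labels.index(l) for l in labels]
        return EEGRecording(list(labels), self.data[idx], self.rate,
                            list(self.triggers), list(self.bad_channels))


@dataclass
class RecordingBundle:
    """Paths plus metadata for one participant x condition session."""

    tracking_path: Path
    eeg_path: Path
    events_path: Path
    participant_id: str
    condition: Condition
    tracking_rate: float = 90.0
    eeg_rate: float = 300.0

    def __post_init__(self):
        self.condition = Condition(self.condition)
        if self.tracking_rate <= 0 or self.eeg_rate <= 0:
            raise ValueError("sampling rates must be positive")

    def validate_files(self) -> None:
        for p in (self.tracking_path, self.eeg_path, self.events_path):
            if not Path(p).exists():
                raise FileNotFoundError(p)


def read_tracking(path) -> GazeHeadRecording:
    """Read a tracking TSV into a :class:`GazeHeadRecording`.

    Gaze directions are renormalized to unit length; zero-norm rows are a
    format error.  Gaps of more than two samples in the time vector are
    recorded as dropout intervals.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TRACKING_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    time = df["time_s"].to_numpy(float)
    if len(time) == 0:
        raise FormatError(f"{path}: empty recording")
    dt = np.diff(time)
    if np.any(dt <= 0):
        bad = np.nonzero(dt <= 0)[0][:5]
        raise FormatError(f"{path}: non-monotone time at rows {bad.tolist()}")

    gaze_dir = df[["gaze_dir_x", "gaze_dir_y", "gaze_dir_z"]].to_numpy(float)
    norms = np.linalg.norm(gaze_dir, axis=1)
    zero = np.nonzero(norms == 0)[0]
    if zero.size:
        raise FormatError(
            f"{path}: zero-norm gaze_dir at rows {zero[:10].tolist()}")
    gaze_dir = gaze_dir / norms[:, None]

    if len(time) > 1:
        rate = 1.0 / np.median(dt)
    else:
        rate = 90.0
    dropouts = []
    n_missing = np.round(dt * rate).astype(int) - 1
    for i in np.nonzero(n_missing > 2)[0]:
        dropouts.append((float(time[i]), float(time[i + 1]), int(n_missing[i])))

    return GazeHeadRecording(
        time=time,
        head_pos=df[["head_x", "head_y", "head_z"]].to_numpy(float),
        gaze_origin=df[["gaze_origin_x", "gaze_origin_y", "gaze_origin_z"]]
        .to_numpy(float),
        gaze_dir=gaze_dir,
        trial_id=df["trial_id"].to_numpy(int),
        rate=float(rate),
        dropouts=dropouts,
    )


def write_tracking(path, rec: GazeHeadRecording) -> None:
    df = pd.DataFrame(
        np.column_stack([rec.time, rec.head_pos, rec.gaze_origin,
                         rec.gaze_dir]),
        columns=TRACKING_COLUMNS[:-1],
    )
    df["trial_id"] = rec.trial_id
    df.to_csv(path, sep="\t", index=False)


def read_eeg(path) -> EEGRecording:
    """Read an EDF file into an :class:`EEGRecording` in canonical order.

    Requires the full scalp montage plus A1 and A2 (re-referencing is
    impossible without both earlobes).  Trigger codes come from the TRIG
    channel.
    """
    labels, data, rate = edf.read_edf(path)
    for ref in REFERENCE_CHANNELS:
        if ref not in labels:
            raise FormatError(f"{path}: missing reference channel {ref}")
    missing = [c for c in SCALP_CHANNELS if c not in labels]
    if missing:
        raise FormatError(f"{path}: missing scalp channels {missing}")
    triggers = edf.extract_triggers(labels, data, rate)
    order = SCALP_CHANNELS + REFERENCE_CHANNELS
    idx = [labels.index(l) for l in order]
    return EEGRecording(order, data[idx], rate, triggers)


def write_eeg(path, rec: EEGRecording) -> None:
    trig = np.zeros(rec.n_samples)
    for t, code in rec.triggers:
        trig[int(round(t * rec.rate))] = code
    labels = list(rec.labels) + [edf.TRIGGER_LABEL]
    edf.write_edf(path, labels, np.vstack([rec.data, trig[None, :]]), rec.rate)


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("onset", "duration", "trial_type"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing events column {col}")
    return df


def write_events(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)
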