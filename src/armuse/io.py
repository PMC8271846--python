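"""Epoch data model, CSV dialect, and stream synchronization.

The arm-use monitor consists of three body-worn accelerometers (one on each
wrist, one on the nonparetic thigh).  Each sensor summarises movement as
non-negative counts at 1.6 Hz and stores them in 30 s epochs of 48 samples;
the thigh sensor additionally labels every sample with a whole-body posture
or movement (lying, sitting, standing, walking, cycling, running).

On disk, a stream is a flat CSV with one row per epoch::

    subject_id, week, sensor_role, start_time, c01..c48 [, l01..l48]

``start_time`` is ISO-8601 with a UTC offset; label columns are present only
for the thigh sensor and use the fixed vocabulary LIE/SIT/STA/WAL/CYC/RUN.
Epoch intervals are half-open ``[start, start + 30 s)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("armuse")

#: sensor placements in the three-sensor configuration
SENSOR_ROLES = ("paretic_wrist", "nonparetic_wrist", "thigh")

#: posture/movement vocabulary of the thigh sensor, index = integer code
POSTURES = ("LIE", "SIT", "STA", "WAL", "CYC", "RUN")
LIE, SIT, STA, WAL, CYC, RUN = range(6)

SAMPLES_PER_EPOCH = 48
EPOCH_SECONDS = 30
SAMPLE_HZ = SAMPLES_PER_EPOCH / EPOCH_SECONDS  # 1.6
SAMPLES_PER_MINUTE = SAMPLE_HZ * 60.0  # 96

_COUNT_COLS = [f"c{i:02d}" for i in range(1, SAMPLES_PER_EPOCH + 1)]
_LABEL_COLS = [f"l{i:02d}" for i in range(1, SAMPLES_PER_EPOCH + 1)]
_CODE_OF = {name: code for code, name in enumerate(POSTURES)}


class FormatError(ValueError):
    """Raised when an epoch CSV violates the dialect."""


class SyncError(ValueError):
    """Raised when the three streams share no common epoch."""


def labels_to_codes(labels) -> np.ndarray:
    """Map posture names (LIE/SIT/STA/WAL/CYC/RUN) to int8 codes."""
    arr = np.asarray(labels)
    flat = arr.ravel()
    out = np.empty(flat.shape, dtype=np.int8)
    for i, name in enumerate(flat):
        try:
            out[i] = _CODE_OF[name]
        except KeyError:
            raise FormatError(f"unknown posture label {name!r}; expected one of {POSTURES}")
    return out.reshape(arr.shape)


def codes_to_labels(codes: np.ndarray) -> np.ndarray:
    return np.asarray(POSTURES, dtype=object)[np.asarray(codes, dtype=int)]


@dataclass
class EpochBlock:
    """One 30 s epoch of 48 count samples (plus labels for the thigh)."""

    start_time: pd.Timestamp
    sensor_role: str
    counts: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (SAMPLES_PER_EPOCH,):
            raise FormatError(
                f"epoch must contain exactly {SAMPLES_PER_EPOCH} count samples, "
                f"got {self.counts.shape}"
            )
        if np.any(self.counts < 0):
            raise FormatError("movement counts must be non-negative")
        if (self.labels is not None) != (self.sensor_role == "thigh"):
            raise FormatError("posture labels are present iff sensor_role == 'thigh'")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int8)
            if self.labels.shape != (SAMPLES_PER_EPOCH,):
                raise FormatError(f"epoch must carry {SAMPLES_PER_EPOCH} labels")


@dataclass
class EpochStream:
    """A time-ordered sequence of epochs from one sensor, stored columnar.

    ``counts`` has shape (n_epochs, 48); thigh streams also carry ``labels``
    of the same shape with int8 posture codes.
    """

    sensor_role: str
    start_times: pd.DatetimeIndex
    counts: np.ndarray
    labels: np.ndarray | None = None
    subject_id: str | None = None
    week: int | None = None

    def __post_init__(self):
        if self.sensor_role not in SENSOR_ROLES:
            raise FormatError(
                f"unknown sensor_role {self.sensor_role!r}; expected one of {SENSOR_ROLES}"
            )
        self.start_times = pd.DatetimeIndex(self.start_times)
        self.counts = np.asarray(self.counts, dtype=float)
        n = len(self.start_times)
        if self.counts.shape != (n, SAMPLES_PER_EPOCH):
            raise FormatError(
                f"counts must have shape ({n}, {SAMPLES_PER_EPOCH}), got {self.counts.shape}"
            )
        if np.any(self.counts < 0):
            raise FormatError("movement counts must be non-negative")
        if (self.labels is not None) != (self.sensor_role == "thigh"):
            raise FormatError("labels present iff sensor_role == 'thigh'")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int8)
            if self.labels.shape != (n, SAMPLES_PER_EPOCH):
                raise FormatError("labels must have the same shape as counts")
        if n > 1:
            deltas = np.diff(self.start_times.asi8)
            if np.any(deltas <= 0):
                bad = int(np.argmax(deltas <= 0)) + 1
                raise FormatError(f"start_times must be strictly increasing (epoch {bad})")
            origin = self.start_times.asi8[0]
            off = (self.start_times.asi8 - origin) % (EPOCH_SECONDS * 10**9)
            if np.any(off != 0):
                raise FormatError("start_times must lie on the 30 s epoch grid")

    def __len__(self) -> int:
        return len(self.start_times)

    def __getitem__(self, i: int) -> EpochBlock:
        return EpochBlock(
            start_time=self.start_times[i],
            sensor_role=self.sensor_role,
            counts=self.counts[i],
            labels=None if self.labels is None else self.labels[i],
        )

    def blocks(self):
        for i in range(len(self)):
            yield self[i]

    def select(self, mask_or_idx) -> "EpochStream":
        """New stream restricted to the given epochs (boolean mask or indices)."""
        return EpochStream(
            sensor_role=self.sensor_role,
            start_times=self.start_times[mask_or_idx],
            counts=self.counts[mask_or_idx],
            labels=None if self.labels is None else self.labels[mask_or_idx],
            subject_id=self.subject_id,
            week=self.week,
        )


@dataclass
class SubjectWeekRecording:
    """Three synchronized sensor streams for one subject-week (3/12/26)."""

    subject_id: str
    week: int
    streams: dict = field(default_factory=dict)  # sensor_role -> EpochStream

    def __post_init__(self):
        for role in self.streams:
            if role not in SENSOR_ROLES:
                raise FormatError(f"unknown sensor role {role!r}")

    @property
    def thigh(self) -> EpochStream:
        return self.streams["thigh"]

    def n_epochs(self) -> dict:
        return {role: len(s) for role, s in self.streams.items()}

    def select(self, mask_or_idx) -> "SubjectWeekRecording":
        return SubjectWeekRecording(
            subject_id=self.subject_id,
            week=self.week,
            streams={r: s.select(mask_or_idx) for r, s in self.streams.items()},
        )


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def write_epoch_csv(stream: EpochStream, path) -> None:
    """Write one sensor stream in the flat epoch-per-row CSV dialect."""
    df = pd.DataFrame(stream.counts, columns=_COUNT_COLS)
    if stream.labels is not None:
        df[_LABEL_COLS] = pd.DataFrame(codes_to_labels(stream.labels))
    df.insert(0, "start_time", [t.isoformat() for t in stream.start_times])
    df.insert(0, "sensor_role", stream.sensor_role)
    df.insert(0, "week", stream.week)
    df.insert(0, "subject_id", stream.subject_id)
    # %.17g keeps write -> read -> write lossless for float64 counts
    df.to_csv(path, index=False, float_format="%.17g")


def read_epoch_csv(path, sensor_role: str) -> EpochStream:
    """Read and validate one sensor stream from the epoch CSV dialect.

    Raises :class:`FormatError` naming the violation (and the offending data
    row, counted from 1 excluding the header) for wrong column sets, negative
    counts, non-monotone timestamps, or labels on a wrist stream.
    """
    if sensor_role not in SENSOR_ROLES:
        raise FormatError(f"unknown sensor_role {sensor_role!r}")
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise FormatError(
            f"{path}: malformed CSV (every row needs the full set of "
            f"{SAMPLES_PER_EPOCH} count columns): {exc}"
        ) from exc

    want_labels = sensor_role == "thigh"
    missing = [c for c in _COUNT_COLS if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: expected {SAMPLES_PER_EPOCH} count columns c01..c48; missing {missing[:3]}..."
        )
    has_label_cols = any(c in df.columns for c in _LABEL_COLS)
    if has_label_cols and not want_labels:
        raise FormatError(f"{path}: posture label columns found on a {sensor_role} stream")
    if want_labels:
        missing_l = [c for c in _LABEL_COLS if c not in df.columns]
        if missing_l:
            raise FormatError(f"{path}: thigh stream lacks label columns {missing_l[:3]}...")

    counts = df[_COUNT_COLS].to_numpy(dtype=float)
    if np.isnan(counts).any():
        row = int(np.where(np.isnan(counts).any(axis=1))[0][0]) + 1
        raise FormatError(
            f"{path}: row {row}: expected {SAMPLES_PER_EPOCH} numeric count fields"
        )
    if (counts < 0).any():
        row = int(np.where((counts < 0).any(axis=1))[0][0]) + 1
        raise FormatError(f"{path}: row {row}: negative movement count")

    times = pd.DatetimeIndex(pd.to_datetime(df["start_time"]))
    if len(times) > 1 and np.any(np.diff(times.asi8) <= 0):
        row = int(np.argmax(np.diff(times.asi8) <= 0)) + 2
        raise FormatError(f"{path}: row {row}: non-monotone start_time")

    labels = None
    if want_labels:
        labels = labels_to_codes(df[_LABEL_COLS].to_numpy(dtype=object))

    subject = df["subject_id"].iloc[0] if "subject_id" in df.columns and len(df) else None
    week = int(df["week"].iloc[0]) if "week" in df.columns and len(df) else None
    return EpochStream(
        sensor_role=sensor_role,
        start_times=times,
        counts=counts,
        labels=labels,
        subject_id=subject,
        week=week,
    )


# ---------------------------------------------------------------------------
# Synchronization
# ---------------------------------------------------------------------------

def synchronize_streams(recording: SubjectWeekRecording) -> SubjectWeekRecording:
    """Time-synchronize the three streams on their timestamps.

    Only epochs whose start_time occurs in all three streams are retained;
    the number of epochs dropped from each stream is logged.  Raises
    :class:`SyncError` when no epoch is common to all streams.
    """
    if len(recording.streams) < 3:
        raise SyncError(
            f"{recording.subject_id} week {recording.week}: synchronization needs all "
            f"three sensor streams, got {sorted(recording.streams)}"
        )
    common = None
    for stream in recording.streams.values():
        s = set(stream.start_times.asi8)
        common = s if common is None else (common & s)
    if not common:
        raise SyncError(
            f"{recording.subject_id} week {recording.week}: the sensor streams share no "
            "common epoch; no co-registered data exist"
        )
    out = {}
    for role, stream in recording.streams.items():
        keep = np.isin(stream.start_times.asi8, np.fromiter(common, dtype=np.int64))
        dropped = len(stream) - int(keep.sum())
        if dropped:
            logger.info(
                "%s week %s: dropped %d unmatched epochs from %s during synchronization",
                recording.subject_id, recording.week, dropped, role,
            )
        out[role] = stream.select(keep)
    return SubjectWeekRecording(recording.subject_id, recording.week, out)
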