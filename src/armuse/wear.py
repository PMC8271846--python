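"""Waking-hours restriction, non-wear detection, and valid-day/week rules.

Analysis is limited to waking hours (07:00–22:00 local clock time).
Non-wear is a period of at least one hour during which a sensor records
only zero movement counts; zero runs are traced at the 1.6 Hz sample level
(a run may start mid-epoch) within contiguous stretches of epochs, and any
epoch partially covered by a non-wear interval is excluded.  A measurement
day is valid when the whole three-sensor configuration delivers at least
ten hours of data; a measurement week is valid when it contains at least
two valid days.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    EPOCH_SECONDS,
    SAMPLE_HZ,
    SAMPLES_PER_EPOCH,
    EpochStream,
    SubjectWeekRecording,
)

logger = logging.getLogger("armuse")

WAKING_START = dt.time(7, 0)
WAKING_END = dt.time(22, 0)
NONWEAR_MIN_MINUTES = 60.0      # "zero movement counts ... for at least one hour"
VALID_DAY_MIN_MINUTES = 600.0   # "at least ten hours of data of the whole sensor configuration"
VALID_WEEK_MIN_DAYS = 2         # "at least two valid measurement days"

_NS_PER_SAMPLE = int(round(1e9 / SAMPLE_HZ))


@dataclass
class WearSummary:
    """Wear accounting for one subject-week after the validity rules."""

    subject_id: str
    week: int
    days: pd.DataFrame                    # date, wear_min, valid_day
    nonwear: dict = field(default_factory=dict)  # sensor_role -> [(start, end), ...]

    @property
    def valid_days(self) -> list:
        return list(self.days.loc[self.days["valid_day"], "date"])

    @property
    def valid_week(self) -> bool:
        return len(self.valid_days) >= VALID_WEEK_MIN_DAYS


def restrict_waking_hours(
    recording: SubjectWeekRecording,
    start: dt.time = WAKING_START,
    end: dt.time = WAKING_END,
) -> SubjectWeekRecording:
    """Keep only epochs whose start time falls in [start, end) clock time."""
    any_stream = next(iter(recording.streams.values()))
    if len(any_stream) == 0:
        return recording
    # indexer_between_time includes the end bound only on request
    keep_idx = any_stream.start_times.indexer_between_time(start, end, include_end=False)
    keep = np.zeros(len(any_stream), dtype=bool)
    keep[keep_idx] = True
    dropped = len(any_stream) - int(keep.sum())
    if dropped:
        logger.info(
            "%s week %s: excluded %d epochs outside waking hours %s-%s",
            recording.subject_id, recording.week, dropped, start, end,
        )
    return recording.select(keep)


def _contiguous_segments(times: pd.DatetimeIndex) -> list:
    """Index ranges [i, j) of epochs that follow each other at 30 s spacing."""
    n = len(times)
    if n == 0:
        return []
    breaks = np.where(np.diff(times.asi8) != EPOCH_SECONDS * 10**9)[0] + 1
    edges = np.concatenate(([0], breaks, [n]))
    return [(int(edges[k]), int(edges[k + 1])) for k in range(len(edges) - 1)]


def detect_nonwear(
    stream: EpochStream, min_duration_min: float = NONWEAR_MIN_MINUTES
) -> list:
    """Find non-wear intervals: maximal zero-count runs of at least one hour.

    Runs are traced on the concatenated 1.6 Hz sample sequence within each
    contiguous stretch of epochs, so a run may start or end mid-epoch.
    Returns half-open ``(start, end)`` timestamp pairs.
    """
    min_samples = int(round(min_duration_min * 60 * SAMPLE_HZ))
    intervals = []
    for i0, i1 in _contiguous_segments(stream.start_times):
        flat = stream.counts[i0:i1].ravel()
        zero = flat == 0
        if not zero.any():
            continue
        padded = np.concatenate(([False], zero, [False]))
        d = np.diff(padded.astype(np.int8))
        starts = np.where(d == 1)[0]
        ends = np.where(d == -1)[0]
        seg_origin = stream.start_times.asi8[i0]
        for s, e in zip(starts, ends):
            if e - s >= min_samples:
                intervals.append(
                    (
                        pd.Timestamp(seg_origin + s * _NS_PER_SAMPLE, tz=stream.start_times.tz),
                        pd.Timestamp(seg_origin + e * _NS_PER_SAMPLE, tz=stream.start_times.tz),
                    )
                )
    return intervals


def _epochs_in_intervals(times: pd.DatetimeIndex, intervals: list) -> np.ndarray:
    """Boolean mask of epochs overlapping any half-open (start, end) interval."""
    mask = np.zeros(len(times), dtype=bool)
    if len(times) == 0:
        return mask
    t0 = times.asi8
    t1 = t0 + EPOCH_SECONDS * 10**9
    for start, end in intervals:
        s, e = start.value, end.value
        mask |= (t0 < e) & (t1 > s)
    return mask


def validate_days(
    recording: SubjectWeekRecording,
    nonwear: dict | None = None,
) -> tuple:
    """Apply the valid-day and valid-week rules; return (summary, cleaned).

    ``nonwear`` maps sensor_role to interval lists (computed with
    :func:`detect_nonwear` when omitted).  An epoch counts toward
    whole-configuration wear only when no sensor is in non-wear; wear time
    per calendar day must reach ten hours for a valid day.  The cleaned
    recording retains epochs outside every sensor's non-wear intervals;
    per-day validity (and the two-valid-day week rule) is reported in the
    summary and applied when daily values are aggregated.
    """
    if nonwear is None:
        nonwear = {role: detect_nonwear(s) for role, s in recording.streams.items()}
    any_stream = next(iter(recording.streams.values()))
    times = any_stream.start_times

    excluded = np.zeros(len(times), dtype=bool)
    for role, intervals in nonwear.items():
        hit = _epochs_in_intervals(times, intervals)
        if hit.any():
            logger.info(
                "%s week %s: %d epochs excluded as %s non-wear",
                recording.subject_id, recording.week, int(hit.sum()), role,
            )
        excluded |= hit
    worn = ~excluded

    dates = np.asarray(times.date)
    rows = []
    for date in pd.unique(dates):
        in_day = dates == date
        wear_min = worn[in_day].sum() * EPOCH_SECONDS / 60.0
        valid = wear_min >= VALID_DAY_MIN_MINUTES
        rows.append({"date": date, "wear_min": wear_min, "valid_day": bool(valid)})
    days = pd.DataFrame(rows, columns=["date", "wear_min", "valid_day"])

    summary = WearSummary(
        subject_id=recording.subject_id,
        week=recording.week,
        days=days,
        nonwear=nonwear,
    )
    cleaned = recording.select(worn)
    return summary, cleaned
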