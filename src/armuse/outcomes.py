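"""Daily arm-use outcomes under the P&M and sit/stand methods.

The P&M (postures & movements) method sums a wrist sensor's movement counts
over *all* retained 30 s epochs of a day, so non-functional arm movement
during whole-body movement (walking, cycling) inflates it.  The sit/stand
method sums counts only over epochs in which at least 90% of the 48 thigh
samples are labelled sitting or standing, excluding whole-body movements.
Both methods are computed for the paretic arm, the nonparetic arm, and the
ratio between arms (paretic / nonparetic, from daily summed counts).

Weekly values are the arithmetic mean of daily values over valid
measurement days; a ratio with a zero denominator is undefined (NaN) and is
excluded from its weekly mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import (
    EPOCH_SECONDS,
    SAMPLES_PER_EPOCH,
    SAMPLES_PER_MINUTE,
    SIT,
    STA,
    WAL,
    EpochBlock,
    SubjectWeekRecording,
)
from .wear import VALID_WEEK_MIN_DAYS

SITSTAND_MIN_FRACTION = 0.90  # "at least 90% of the 48 samples"

OUTCOMES = ("paretic", "nonparetic", "ratio")
METHODS = ("PM", "SS")


@dataclass
class DailyOutcomes:
    subject_id: str
    week: int
    date: object
    wear_min: float
    sit_stand_min: float
    walk_min: float
    paretic_PM: float
    nonparetic_PM: float
    ratio_PM: float       # NaN when nonparetic_PM == 0
    paretic_SS: float
    nonparetic_SS: float
    ratio_SS: float       # NaN when nonparetic_SS == 0
    valid_day: bool


@dataclass
class WeeklyOutcomes:
    """Mean daily value of each outcome over the week's valid days."""

    subject_id: str
    week: int
    n_valid_days: int
    means: dict           # outcome name -> mean over valid days (NaN-aware for ratios)
    n_per_outcome: dict   # outcome name -> number of days contributing


def sitstand_fraction(labels: np.ndarray) -> np.ndarray:
    """Fraction of sitting/standing samples per epoch; labels (n, 48) codes."""
    lab = np.atleast_2d(np.asarray(labels))
    return ((lab == SIT) | (lab == STA)).mean(axis=1)


def classify_epoch_sitstand(block) -> bool:
    """True iff at least 90% of the epoch's thigh samples are sitting/standing."""
    if isinstance(block, EpochBlock):
        if block.labels is None:
            raise ValueError("sit/stand classification needs a thigh epoch with labels")
        labels = block.labels
    else:
        labels = np.asarray(block)
    if labels.shape[-1] != SAMPLES_PER_EPOCH:
        raise ValueError(f"expected {SAMPLES_PER_EPOCH} labels per epoch")
    return bool(sitstand_fraction(labels)[0] >= SITSTAND_MIN_FRACTION)


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def compute_daily_outcomes(
    recording: SubjectWeekRecording, date, valid_day: bool = True
) -> DailyOutcomes:
    """Compute the six arm-use outcomes and posture durations for one day.

    ``recording`` must already be synchronized, waking-window restricted and
    non-wear cleaned; ``date`` selects the calendar day.
    """
    thigh = recording.streams["thigh"]
    if thigh.labels is None:
        raise ValueError("thigh stream lacks posture labels")
    in_day = np.asarray(thigh.start_times.date) == date
    labels = thigh.labels[in_day]
    par = recording.streams["paretic_wrist"].counts[in_day]
    non = recording.streams["nonparetic_wrist"].counts[in_day]

    ss_epoch = sitstand_fraction(labels) >= SITSTAND_MIN_FRACTION if len(labels) else np.zeros(0, bool)

    paretic_pm = float(par.sum())
    nonparetic_pm = float(non.sum())
    paretic_ss = float(par[ss_epoch].sum())
    nonparetic_ss = float(non[ss_epoch].sum())

    # durations at sample resolution from the thigh label stream
    sit_stand_min = float(((labels == SIT) | (labels == STA)).sum() / SAMPLES_PER_MINUTE)
    walk_min = float((labels == WAL).sum() / SAMPLES_PER_MINUTE)
    wear_min = float(in_day.sum() * EPOCH_SECONDS / 60.0)

    return DailyOutcomes(
        subject_id=recording.subject_id,
        week=recording.week,
        date=date,
        wear_min=wear_min,
        sit_stand_min=sit_stand_min,
        walk_min=walk_min,
        paretic_PM=paretic_pm,
        nonparetic_PM=nonparetic_pm,
        ratio_PM=_ratio(paretic_pm, nonparetic_pm),
        paretic_SS=paretic_ss,
        nonparetic_SS=nonparetic_ss,
        ratio_SS=_ratio(paretic_ss, nonparetic_ss),
        valid_day=valid_day,
    )


_MEAN_FIELDS = (
    "wear_min", "sit_stand_min", "walk_min",
    "paretic_PM", "nonparetic_PM", "ratio_PM",
    "paretic_SS", "nonparetic_SS", "ratio_SS",
)


def aggregate_weekly(daily: list) -> WeeklyOutcomes | None:
    """Mean daily value per outcome over valid days; None if the week is invalid.

    Undefined ratios (NaN) are excluded from that outcome's mean, with the
    contributing day count reported per outcome.
    """
    valid = [d for d in daily if d.valid_day]
    if len(valid) < VALID_WEEK_MIN_DAYS:
        return None
    means, ns = {}, {}
    for name in _MEAN_FIELDS:
        vals = np.array([getattr(d, name) for d in valid], dtype=float)
        ok = ~np.isnan(vals)
        ns[name] = int(ok.sum())
        means[name] = float(vals[ok].mean()) if ok.any() else float("nan")
    return WeeklyOutcomes(
        subject_id=valid[0].subject_id,
        week=valid[0].week,
        n_valid_days=len(valid),
        means=means,
        n_per_outcome=ns,
    )


def daily_frame(daily: list) -> pd.DataFrame:
    """Tidy per-day table keyed by (subject_id, week, date)."""
    return pd.DataFrame([vars(d) for d in daily])


def weekly_frame(weekly: list) -> pd.DataFrame:
    """Tidy per-week table keyed by (subject_id, week)."""
    rows = []
    for w in weekly:
        if w is None:
            continue
        row = {"subject_id": w.subject_id, "week": w.week, "n_valid_days": w.n_valid_days}
        row.update(w.means)
        rows.append(row)
    return pd.DataFrame(rows)
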