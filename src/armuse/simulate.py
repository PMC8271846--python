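"""Synthetic longitudinal cohort of three-sensor epoch streams.

Emulates the measurement set-up of a post-stroke arm-use study: subjects
wear a count-producing accelerometer on each wrist and a posture-labelling
one on the nonparetic thigh for seven consecutive days at weeks 3, 12 and
26 after stroke.  Days are built inside the 07:00–22:00 waking window from
alternating posture bouts (exponential bout lengths); wrist counts are the
sum of

* functional arm-use bursts during sitting/standing samples (zero-inflated
  gamma magnitudes, the paretic arm scaled down by a deficit multiplier
  that recovers over the weeks),
* non-functional arm sway during walking samples (truncated-Gaussian
  per-sample counts, nonparetic mean >= paretic mean), and
* a small baseline count noise.

Counts are generated directly at the device's 1.6 Hz count resolution;
raw 12.5 Hz tri-axial synthesis exists only as an optional mode to exercise
the rule-based posture-classifier emulator.  Night/water non-wear gaps,
missing subject-weeks and truncated days are injected on top, and every
emitted sample is covered by a ground-truth record for recovery tests.

All randomness derives from one integer seed; per subject/week/day
substreams are split with counter-based spawn keys, so changing the cohort
size does not reshuffle unrelated subjects.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    CYC,
    EPOCH_SECONDS,
    LIE,
    RUN,
    SAMPLE_HZ,
    SAMPLES_PER_EPOCH,
    SAMPLES_PER_MINUTE,
    SIT,
    STA,
    WAL,
    EpochStream,
    SubjectWeekRecording,
)

WAKING_MINUTES = 15 * 60  # 07:00-22:00
_SCHED_POSTURES = ("lying", "sitting", "standing", "walking")
_POSTURE_CODE = {"lying": LIE, "sitting": SIT, "standing": STA, "walking": WAL}


class ConfigError(ValueError):
    """Raised when a simulation config violates its invariants."""


@dataclass
class BurstParams:
    """Zero-inflated-gamma functional arm-use bursts during sitting/standing."""

    rate: float = 0.30        # P(a sit/stand sample carries a burst)
    shape: float = 2.0        # gamma shape of burst magnitude
    scale: float = 10.0       # gamma scale (counts)


@dataclass
class SwayParams:
    """Per-sample arm-sway counts added during walking samples."""

    paretic_mean: float = 20.0
    nonparetic_mean: float = 25.0
    sd: float = 6.0           # Gaussian jitter, truncated at 0


@dataclass
class NonwearParams:
    """Daytime zero-count gaps (sensor taken off, e.g. washing)."""

    daily_prob: float = 0.15          # per sensor per day
    min_duration_min: float = 60.0
    max_duration_min: float = 150.0


@dataclass
class MissingnessParams:
    """Absent subject-weeks and truncated days (device failure, dropout)."""

    # defaults follow the study's missing weeks: 3/33, 5/33, 7/33
    week_prob: dict = field(default_factory=lambda: {3: 0.09, 12: 0.15, 26: 0.21})
    day_truncation_prob: float = 0.05


def _default_schedule():
    # per-week (mean, sd) daily minutes within the waking window; sitting
    # decreases and walking increases over the recovery weeks
    return {
        3: {"lying": (300, 60), "sitting": (480, 60), "standing": (90, 25), "walking": (30, 10)},
        12: {"lying": (300, 60), "sitting": (440, 60), "standing": (100, 25), "walking": (60, 15)},
        26: {"lying": (295, 60), "sitting": (420, 60), "standing": (110, 25), "walking": (75, 20)},
    }


@dataclass
class SimConfig:
    n_subjects: int = 33
    weeks: tuple = (3, 12, 26)
    days_per_week: int = 7
    waking_start: str = "07:00"
    waking_end: str = "22:00"
    schedule_params: dict = field(default_factory=_default_schedule)
    burst_params: BurstParams = field(default_factory=BurstParams)
    # paretic burst magnitude multiplier, recovering over the weeks
    paretic_deficit: dict = field(default_factory=lambda: {3: 0.35, 12: 0.50, 26: 0.60})
    sway_params: SwayParams = field(default_factory=SwayParams)
    nonwear_params: NonwearParams = field(default_factory=NonwearParams)
    missingness: MissingnessParams = field(default_factory=MissingnessParams)
    baseline_noise: float = 0.2       # Poisson mean of wrist count noise per sample
    thigh_count_means: dict = field(
        default_factory=lambda: {"lying": 0.2, "sitting": 0.5, "standing": 1.0, "walking": 30.0}
    )
    bout_mean_min: float = 5.0        # mean posture bout length
    # between-subject heterogeneity (lognormal sigmas)
    subject_walk_sd: float = 0.35
    subject_use_sd: float = 0.20
    subject_deficit_sd: float = 0.10
    nonparetic_nondominant_factor: float = 1.0
    edge_padding_min: float = 30.0    # zero-count epochs emitted outside the window
    start_date: str = "2021-01-04"    # stroke date anchoring the week schedule
    tz_offset_hours: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects <= 0:
            raise ConfigError("n_subjects must be a positive integer")
        if not self.weeks or any(w not in (3, 12, 26) for w in self.weeks):
            raise ConfigError("weeks must be a non-empty ordered subset of {3, 12, 26}")
        if self.days_per_week <= 0:
            raise ConfigError("days_per_week must be a positive integer")
        for w in self.weeks:
            if w not in self.schedule_params:
                raise ConfigError(f"schedule_params missing week {w}")
            sched = self.schedule_params[w]
            total = 0.0
            for p in _SCHED_POSTURES:
                if p not in sched:
                    raise ConfigError(f"schedule_params[{w}] missing posture {p!r}")
                mean, sd = sched[p]
                if mean < 0 or sd < 0:
                    raise ConfigError(f"schedule_params[{w}][{p!r}] has a negative duration")
                total += mean
            if total > WAKING_MINUTES:
                raise ConfigError(
                    f"schedule_params[{w}] mean minutes sum to {total:.0f} > "
                    f"{WAKING_MINUTES} (waking-window length)"
                )
            if w not in self.paretic_deficit:
                raise ConfigError(f"paretic_deficit missing week {w}")
            if not 0 <= self.paretic_deficit[w] <= 1:
                raise ConfigError(f"paretic_deficit[{w}] must lie in [0, 1]")
        if self.burst_params.rate < 0 or self.burst_params.rate > 1:
            raise ConfigError("burst_params.rate must lie in [0, 1]")
        if min(self.burst_params.shape, self.burst_params.scale) < 0:
            raise ConfigError("burst_params magnitudes must be non-negative")
        sw = self.sway_params
        if min(sw.paretic_mean, sw.nonparetic_mean, sw.sd) < 0:
            raise ConfigError("sway_params magnitudes must be non-negative")
        if sw.nonparetic_mean < sw.paretic_mean:
            raise ConfigError("sway_params: nonparetic_mean must be >= paretic_mean")
        nw = self.nonwear_params
        if not 0 <= nw.daily_prob <= 1:
            raise ConfigError("nonwear_params.daily_prob must lie in [0, 1]")
        if nw.min_duration_min > nw.max_duration_min or nw.min_duration_min < 0:
            raise ConfigError("nonwear_params duration range invalid")
        for w, p in self.missingness.week_prob.items():
            if not 0 <= p <= 1:
                raise ConfigError(f"missingness.week_prob[{w}] must lie in [0, 1]")
        if not 0 <= self.missingness.day_truncation_prob <= 1:
            raise ConfigError("missingness.day_truncation_prob must lie in [0, 1]")
        if self.baseline_noise < 0:
            raise ConfigError("baseline_noise must be non-negative")
        if self.bout_mean_min <= 0:
            raise ConfigError("bout_mean_min must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key, typ in (
            ("burst_params", BurstParams),
            ("sway_params", SwayParams),
            ("nonwear_params", NonwearParams),
            ("missingness", MissingnessParams),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        for key in ("schedule_params", "paretic_deficit"):
            if key in d:
                d[key] = {int(k): v for k, v in d[key].items()}
        if "missingness" in d and isinstance(d["missingness"].week_prob, dict):
            d["missingness"].week_prob = {
                int(k): v for k, v in d["missingness"].week_prob.items()
            }
        if "schedule_params" in d:
            d["schedule_params"] = {
                wk: {p: tuple(v) for p, v in sched.items()}
                for wk, sched in d["schedule_params"].items()
            }
        if "weeks" in d:
            d["weeks"] = tuple(int(w) for w in d["weeks"])
        return cls(**d)


def demo_config(n_subjects: int = 12, seed: int = 0, **overrides) -> SimConfig:
    """A compact cohort with the same structure as the full default config."""
    return SimConfig(n_subjects=n_subjects, seed=seed, **overrides)


@dataclass
class SimGroundTruth:
    """Scheduled durations and injected counts per emitted subject-week-day."""

    days: pd.DataFrame     # subject_id, week, date, *_min, injected counts, truncated
    nonwear: pd.DataFrame  # subject_id, week, date, sensor_role, start, end
    config: SimConfig


# ---------------------------------------------------------------------------
# Day-level generation
# ---------------------------------------------------------------------------

def _draw_schedule_samples(sched: dict, walk_factor: float, rng) -> dict:
    """Integer sample budgets per posture, exactly filling the waking window."""
    minutes = {}
    for p in _SCHED_POSTURES:
        mean, sd = sched[p]
        v = max(0.0, rng.normal(mean, sd))
        if p == "walking":
            v *= walk_factor
        minutes[p] = v
    total = sum(minutes.values())
    if total <= 0:
        minutes = {p: (WAKING_MINUTES if p == "lying" else 0.0) for p in _SCHED_POSTURES}
        total = WAKING_MINUTES
    scale = WAKING_MINUTES / total
    samples = {p: int(round(v * scale * SAMPLES_PER_MINUTE)) for p, v in minutes.items()}
    # rounding drift is absorbed by the largest budget
    drift = int(WAKING_MINUTES * SAMPLES_PER_MINUTE) - sum(samples.values())
    samples[max(samples, key=samples.get)] += drift
    return samples


def _bout_labels(samples: dict, bout_mean_samples: float, rng) -> np.ndarray:
    """Sequence the day's sample budgets into alternating exponential bouts."""
    remaining = np.array([samples[p] for p in _SCHED_POSTURES], dtype=np.int64)
    codes = np.array([_POSTURE_CODE[p] for p in _SCHED_POSTURES], dtype=np.int8)
    parts = []
    while remaining.sum() > 0:
        probs = remaining / remaining.sum()
        k = rng.choice(len(codes), p=probs)
        length = max(1, int(round(rng.exponential(bout_mean_samples))))
        length = min(length, int(remaining[k]))
        parts.append(np.full(length, codes[k], dtype=np.int8))
        remaining[k] -= length
    return np.concatenate(parts)


def simulate_day(samples: dict, config: SimConfig, week: int, subject_factors: dict, rng):
    """Generate one day's three per-sample count sequences plus the label track.

    Returns ``(paretic, nonparetic, thigh_counts, labels, truth)`` where the
    count arrays cover the waking window at 1.6 Hz and ``truth`` records the
    injected functional-burst and sway count totals.
    """
    labels = _bout_labels(samples, config.bout_mean_min * SAMPLES_PER_MINUTE, rng)
    n = labels.size

    lam = np.empty(n)
    for p in _SCHED_POSTURES:
        lam[labels == _POSTURE_CODE[p]] = config.thigh_count_means[p]
    thigh_counts = rng.poisson(lam).astype(float)

    ss_mask = (labels == SIT) | (labels == STA)
    walk_mask = labels == WAL

    base_par = rng.poisson(config.baseline_noise, n).astype(float)
    base_non = rng.poisson(config.baseline_noise, n).astype(float)

    bp = config.burst_params
    rate = bp.rate * subject_factors["use"]
    active_par = (rng.random(n) < rate) & ss_mask
    active_non = (rng.random(n) < rate) & ss_mask
    mag_par = rng.gamma(bp.shape, bp.scale, n) if bp.scale > 0 else np.zeros(n)
    mag_non = rng.gamma(bp.shape, bp.scale, n) if bp.scale > 0 else np.zeros(n)
    deficit = subject_factors["deficit"][week]
    bursts_par = mag_par * active_par * deficit
    bursts_non = mag_non * active_non * config.nonparetic_nondominant_factor

    sw = config.sway_params
    sway_par = np.clip(rng.normal(sw.paretic_mean, sw.sd, n), 0, None) * walk_mask
    sway_non = np.clip(rng.normal(sw.nonparetic_mean, sw.sd, n), 0, None) * walk_mask

    paretic = base_par + bursts_par + sway_par
    nonparetic = base_non + bursts_non + sway_non

    truth = {
        "paretic_functional": float(bursts_par.sum()),
        "nonparetic_functional": float(bursts_non.sum()),
        "paretic_sway": float(sway_par.sum()),
        "nonparetic_sway": float(sway_non.sum()),
    }
    return paretic, nonparetic, thigh_counts, labels, truth


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

def _subject_factors(config: SimConfig, subj_idx: int) -> dict:
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(1, subj_idx)))
    walk = float(np.exp(rng.normal(0.0, config.subject_walk_sd)))
    use = float(np.exp(rng.normal(0.0, config.subject_use_sd)))
    jitter = float(np.exp(rng.normal(0.0, config.subject_deficit_sd)))
    deficit = {w: float(np.clip(config.paretic_deficit[w] * jitter, 0.0, 1.0))
               for w in config.weeks}
    return {"walk": walk, "use": use, "deficit": deficit}


def _day_rng(config: SimConfig, subj_idx: int, week: int, day: int):
    return np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(3, subj_idx, week, day))
    )


def simulate_cohort(config: SimConfig):
    """Generate the cohort; returns (recordings, ground_truth).

    One :class:`SubjectWeekRecording` per retained subject-week; the thigh
    stream carries per-sample posture labels, the wrist streams counts only.
    Identical config + seed reproduce byte-identical streams.
    """
    config.validate()
    tzinfo = pd.Timestamp(f"2000-01-01T00:00:00+{config.tz_offset_hours:02d}:00").tz
    stroke = pd.Timestamp(config.start_date)
    wake_start = pd.Timedelta(config.waking_start + ":00")
    epochs_per_day = int(WAKING_MINUTES * 60 / EPOCH_SECONDS)
    pad_epochs = int(round(config.edge_padding_min * 60 / EPOCH_SECONDS))
    ns_per_sample = int(round(1e9 / SAMPLE_HZ))

    recordings = []
    truth_rows = []
    nonwear_rows = []

    for s in range(config.n_subjects):
        subject_id = f"S{s + 1:03d}"
        factors = _subject_factors(config, s)
        for week in config.weeks:
            wk_rng = np.random.default_rng(
                np.random.SeedSequence(config.seed, spawn_key=(2, s, week))
            )
            if wk_rng.random() < config.missingness.week_prob.get(week, 0.0):
                continue  # subject-week absent (dropout / device failure)

            per_role = {role: {"times": [], "counts": [], "labels": []}
                        for role in ("paretic_wrist", "nonparetic_wrist", "thigh")}
            week_start = stroke + pd.Timedelta(days=7 * week)

            for d in range(config.days_per_week):
                rng = _day_rng(config, s, week, d)
                date = week_start + pd.Timedelta(days=d)
                day0 = (date + wake_start).tz_localize(tzinfo)

                samples = _draw_schedule_samples(
                    config.schedule_params[week], factors["walk"], rng
                )
                par, non, thigh, labels, inj = simulate_day(
                    samples, config, week, factors, rng
                )

                truncated = rng.random() < config.missingness.day_truncation_prob
                n_epochs = epochs_per_day
                if truncated:
                    n_epochs = int(rng.integers(600, 1500))
                    keep = n_epochs * SAMPLES_PER_EPOCH
                    par, non, thigh, labels = (a[:keep] for a in (par, non, thigh, labels))

                # non-wear gaps: zero the counts, keep the label track
                streams = {"paretic_wrist": par, "nonparetic_wrist": non, "thigh": thigh}
                for role in streams:
                    if rng.random() < config.nonwear_params.daily_prob:
                        dur = rng.uniform(
                            config.nonwear_params.min_duration_min,
                            config.nonwear_params.max_duration_min,
                        )
                        dur_s = min(int(round(dur * SAMPLES_PER_MINUTE)), streams[role].size)
                        start = int(rng.integers(0, max(1, streams[role].size - dur_s + 1)))
                        streams[role][start:start + dur_s] = 0.0
                        nonwear_rows.append(
                            {
                                "subject_id": subject_id,
                                "week": week,
                                "date": date.date(),
                                "sensor_role": role,
                                "start": day0 + pd.Timedelta(start * ns_per_sample, "ns"),
                                "end": day0 + pd.Timedelta((start + dur_s) * ns_per_sample, "ns"),
                            }
                        )

                row = {"subject_id": subject_id, "week": week, "date": date.date(),
                       "truncated": truncated}
                for p in _SCHED_POSTURES:
                    row[f"{p}_min"] = float((labels == _POSTURE_CODE[p]).sum() / SAMPLES_PER_MINUTE)
                row.update(inj)
                truth_rows.append(row)

                # epoch the day, with zero-count padding outside the window
                for role, arr in streams.items():
                    counts = arr.reshape(n_epochs, SAMPLES_PER_EPOCH)
                    lab = labels.reshape(n_epochs, SAMPLES_PER_EPOCH) if role == "thigh" else None
                    pre = pad_epochs
                    post = pad_epochs if not truncated else 0
                    if pre or post:
                        counts = np.vstack(
                            [np.zeros((pre, SAMPLES_PER_EPOCH)), counts,
                             np.zeros((post, SAMPLES_PER_EPOCH))]
                        )
                        if lab is not None:
                            lab = np.vstack(
                                [np.full((pre, SAMPLES_PER_EPOCH), LIE, dtype=np.int8), lab,
                                 np.full((post, SAMPLES_PER_EPOCH), LIE, dtype=np.int8)]
                            )
                    t0 = day0 - pd.Timedelta(seconds=pre * EPOCH_SECONDS)
                    times = t0 + pd.to_timedelta(
                        np.arange(counts.shape[0]) * EPOCH_SECONDS, unit="s"
                    )
                    per_role[role]["times"].append(times)
                    per_role[role]["counts"].append(counts)
                    if lab is not None:
                        per_role[role]["labels"].append(lab)

            streams_out = {}
            for role, acc in per_role.items():
                if not acc["times"]:
                    continue
                streams_out[role] = EpochStream(
                    sensor_role=role,
                    start_times=pd.DatetimeIndex(np.concatenate([t.asi8 for t in acc["times"]]),
                                                 tz=tzinfo),
                    counts=np.vstack(acc["counts"]),
                    labels=np.vstack(acc["labels"]) if acc["labels"] else None,
                    subject_id=subject_id,
                    week=week,
                )
            recordings.append(SubjectWeekRecording(subject_id, week, streams_out))

    truth_days = pd.DataFrame(truth_rows)
    nonwear = pd.DataFrame(
        nonwear_rows,
        columns=["subject_id", "week", "date", "sensor_role", "start", "end"],
    )
    return recordings, SimGroundTruth(days=truth_days, nonwear=nonwear, config=config)


# ---------------------------------------------------------------------------
# Device-emulation posture classifier (optional raw 12.5 Hz mode)
# ---------------------------------------------------------------------------

RAW_HZ = 12.5
INCLINATION_THRESHOLD_DEG = 45.0  # upright vs. horizontal thigh
WALK_INTENSITY_G = 0.08           # windowed movement-intensity thresholds
RUN_INTENSITY_G = 0.80


def _windows(n_raw: int):
    r = RAW_HZ / SAMPLE_HZ
    n_out = int(n_raw / r)
    edges = np.floor(np.arange(n_out + 1) * r).astype(int)
    return [(edges[k], edges[k + 1]) for k in range(n_out)]


def movement_intensity(raw: np.ndarray) -> np.ndarray:
    """Windowed movement intensity: SD of the acceleration magnitude (g) per
    1.6 Hz output sample."""
    raw = np.asarray(raw, dtype=float)
    mag = np.linalg.norm(raw, axis=1)
    return np.array([mag[a:b].std() for a, b in _windows(len(raw))])


def emulate_posture_classifier(
    raw: np.ndarray,
    inclination_threshold_deg: float = INCLINATION_THRESHOLD_DEG,
    walk_intensity_g: float = WALK_INTENSITY_G,
    run_intensity_g: float = RUN_INTENSITY_G,
) -> np.ndarray:
    """Rule-based posture labels at 1.6 Hz from thigh-worn 12.5 Hz raw data.

    ``raw`` is (n, 3) in g with x the thigh's longitudinal axis (distal
    positive).  Each output sample uses only (1) the inclination of the mean
    acceleration vector relative to gravity and (2) the windowed movement
    intensity: upright + quiet -> standing, upright + moderate -> walking,
    upright + vigorous -> running; horizontal + quiet -> sitting (the
    sitting/lying tie-break), horizontal + moving -> cycling.
    Returns int8 posture codes; an empty signal yields an empty sequence.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        return np.zeros(0, dtype=np.int8)
    if raw.ndim != 2 or raw.shape[1] != 3:
        raise ValueError("raw signal must have shape (n, 3) in g units")
    out = []
    for a, b in _windows(len(raw)):
        w = raw[a:b]
        m = w.mean(axis=0)
        norm = np.linalg.norm(m)
        incl = np.degrees(np.arccos(np.clip(m[0] / norm, -1, 1))) if norm > 0 else 90.0
        intensity = float(np.linalg.norm(w, axis=1).std())
        if incl <= inclination_threshold_deg:
            if intensity >= run_intensity_g:
                out.append(RUN)
            elif intensity >= walk_intensity_g:
                out.append(WAL)
            else:
                out.append(STA)
        else:
            out.append(CYC if intensity >= walk_intensity_g else SIT)
    return np.asarray(out, dtype=np.int8)


def synthesize_raw_from_labels(labels: np.ndarray, rng, noise_g: float = 0.01) -> np.ndarray:
    """Optional raw-mode synthesis: a 12.5 Hz tri-axial track whose windows
    match the given 1.6 Hz posture codes (upright postures along +x,
    horizontal ones along +z; walking/running add a sinusoidal component)."""
    labels = np.asarray(labels)
    r = RAW_HZ / SAMPLE_HZ
    n_raw = int(np.ceil(len(labels) * r)) + 1
    t = np.arange(n_raw) / RAW_HZ
    raw = rng.normal(0.0, noise_g, size=(n_raw, 3))
    out_idx = np.minimum((np.arange(n_raw) / r).astype(int), len(labels) - 1)
    lab_raw = labels[out_idx]
    upright = (lab_raw == STA) | (lab_raw == WAL) | (lab_raw == RUN)
    raw[:, 0] += np.where(upright, 1.0, 0.0)
    raw[:, 2] += np.where(upright, 0.0, 1.0)
    walk = lab_raw == WAL
    raw[walk, 0] += 0.3 * np.sin(2 * np.pi * 2.0 * t[walk])
    run = lab_raw == RUN
    raw[run, 0] += 1.5 * np.sin(2 * np.pi * 3.0 * t[run])
    cyc = lab_raw == CYC
    raw[cyc, 2] += 0.3 * np.sin(2 * np.pi * 1.5 * t[cyc])
    return raw
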