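import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from armuse.io import SAMPLES_PER_EPOCH, EpochStream, SubjectWeekRecording
from armuse.simulate import (
    MissingnessParams,
    NonwearParams,
    demo_config,
    simulate_cohort,
)
from armuse.workflow import process_cohort

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")

TZ = "+01:00"


def make_stream(
    role,
    n_epochs,
    counts=None,
    labels=None,
    start="2021-01-25T08:00:00" + TZ,
    subject_id="T01",
    week=3,
):
    """Hand-built epoch stream: counts/labels broadcast to (n_epochs, 48)."""
    times = pd.date_range(start=start, periods=n_epochs, freq="30s")
    if counts is None:
        counts = np.ones((n_epochs, SAMPLES_PER_EPOCH))
    else:
        counts = np.broadcast_to(
            np.asarray(counts, dtype=float), (n_epochs, SAMPLES_PER_EPOCH)
        ).copy()
    if role == "thigh":
        if labels is None:
            labels = 1  # SIT
        labels = np.broadcast_to(
            np.asarray(labels, dtype=np.int8), (n_epochs, SAMPLES_PER_EPOCH)
        ).copy()
    else:
        labels = None
    return EpochStream(
        sensor_role=role,
        start_times=times,
        counts=counts,
        labels=labels,
        subject_id=subject_id,
        week=week,
    )


def make_recording(n_epochs, thigh_labels=None, counts=1.0, **kwargs):
    """Three-sensor recording with identical timestamps."""
    streams = {
        role: make_stream(role, n_epochs, counts=counts, labels=thigh_labels, **kwargs)
        for role in ("paretic_wrist", "nonparetic_wrist", "thigh")
    }
    return SubjectWeekRecording(
        streams["thigh"].subject_id, streams["thigh"].week, streams
    )


def no_dropout(**overrides):
    """Config pieces disabling non-wear and missingness."""
    return dict(
        nonwear_params=NonwearParams(daily_prob=0.0),
        missingness=MissingnessParams(week_prob={3: 0.0, 12: 0.0, 26: 0.0},
                                      day_truncation_prob=0.0),
        **overrides,
    )


@pytest.fixture(scope="session")
def demo_cohort():
    """The packaged 12-subject demonstration cohort, simulated and processed."""
    config = demo_config(n_subjects=12, seed=0)
    recordings, truth = simulate_cohort(config)
    cohort = process_cohort(recordings)
    return config, recordings, truth, cohort


@pytest.fixture(scope="session")
def cohort10():
    """Ten-subject cohort for day-level identity checks."""
    config = demo_config(n_subjects=10, seed=5)
    recordings, truth = simulate_cohort(config)
    cohort = process_cohort(recordings)
    return config, recordings, truth, cohort
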