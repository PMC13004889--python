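from datetime import datetime

import numpy as np
import pytest

import tendonload as tl

FS = 20.0


def make_recording(
    f_heel=None,
    f_mid=None,
    f_fore=None,
    n=None,
    session_id="S1",
    participant_id="P01",
    start=datetime(2025, 3, 1, 9, 0),
    sample_rate=FS,
):
    """Recording builder: missing channels default to zeros."""
    for arr in (f_heel, f_mid, f_fore):
        if arr is not None:
            n = len(arr)
            break
    if n is None:
        raise ValueError("need at least one channel or n")
    zeros = np.zeros(n)
    return tl.InsoleRecording(
        participant_id=participant_id,
        session_id=session_id,
        start_time=start,
        sample_rate=sample_rate,
        f_heel=zeros if f_heel is None else np.asarray(f_heel, float),
        f_mid=zeros if f_mid is None else np.asarray(f_mid, float),
        f_fore=zeros if f_fore is None else np.asarray(f_fore, float),
    )


def gait_recording(profile, duration_s=300.0, rest_s=40.0, peak_bw=3.0, session_id="S1"):
    """Rest / walking / rest session built through the generator's inversion."""
    spec = tl.PulseTrainSpec(peak_bw=peak_bw, pulse_s=0.654, period_s=1.091)
    bout = tl.synth.bout_from_duration(spec, rest_s, duration_s - 2 * rest_s)
    load, book = tl.generate_load_waveform([bout], duration_s, FS)
    fh, fm, ff = tl.waveform_to_forces(load, FS, tl.DEFAULT_GEOMETRY, profile.body_weight)
    rec = make_recording(
        f_heel=fh, f_mid=fm, f_fore=ff, session_id=session_id,
        participant_id=profile.participant_id,
    )
    return rec, load, book


@pytest.fixture
def profile():
    return tl.ParticipantProfile(
        participant_id="P01", mass=70.0, height=1.75, age=45.0, visa_a=60.0, pas=4.0
    )


@pytest.fixture
def geometry():
    return tl.DEFAULT_GEOMETRY


@pytest.fixture(scope="session")
def tiny_scenario():
    """Small, fast cohort used by pipeline-level tests."""
    return tl.ScenarioConfig(
        n_participants=2,
        days_min=2,
        days_max=2,
        sessions_per_day=(1, 2),
        session_hours=(0.15, 0.25),
        seed=42,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_scenario):
    return tl.generate_cohort(tiny_scenario)
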