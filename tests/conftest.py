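"""Shared fixtures: one noise-free simulated subject reused across modules."""

from __future__ import annotations

import numpy as np
import pytest

from imugait import (
    COHORT_PRESETS,
    detect_events_lumbar,
    detect_events_shank_recording,
    make_gait_script,
    single_bout_preset,
    synthesize_lumbar_accel,
    synthesize_shank_gyro,
)

FS = 100.0


@pytest.fixture(scope="session")
def ya_script():
    """60 s young-adult walk (~54 strides per side), fixed seed."""
    return make_gait_script(COHORT_PRESETS["YA"], single_bout_preset(60.0), seed=11)


@pytest.fixture(scope="session")
def lumbar_recording_clean(ya_script):
    return synthesize_lumbar_accel(ya_script, FS, noise_sd=0.0, tilt_deg=0.0)


@pytest.fixture(scope="session")
def shank_recordings_clean(ya_script):
    return {
        side: synthesize_shank_gyro(ya_script, side, FS, noise_sd=0.0, drift_rate=0.0)
        for side in ("L", "R")
    }


@pytest.fixture(scope="session")
def lumbar_events_clean(lumbar_recording_clean):
    return detect_events_lumbar(lumbar_recording_clean.vertical_accel(), FS)


@pytest.fixture(scope="session")
def shank_events_clean(shank_recordings_clean):
    return {
        side: detect_events_shank_recording(rec)
        for side, rec in shank_recordings_clean.items()
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
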