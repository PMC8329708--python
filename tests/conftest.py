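"""Shared fixtures: a small trefoil flight and one fully generated session.

The short session (single small trefoil, ~122 s) is expensive to build, so it
is generated once per test run and shared read-only across test modules.
"""

import numpy as np
import pytest

from beeflight import detection, preprocess, synthgen


SHORT_TREFOIL = dict(
    n_repetitions=1, start_xy=(-60.0, -60.0), leg_beyond_m=30.0, turn_radius_m=10.0
)


@pytest.fixture(scope="session")
def short_track():
    track, bounds = synthgen.gen_trefoil_telemetry(**SHORT_TREFOIL)
    return track, bounds


@pytest.fixture(scope="session")
def short_session(short_track):
    """Ground truth + recording + cleaned signal for one short flight."""
    track, bounds = short_track
    gt = synthgen.gen_spike_trains(track, n_units=3, seed=1, repetition_bounds=bounds)
    templates = synthgen.default_templates(3)
    rec = synthgen.gen_recording(
        gt, templates, synthgen.default_noise_model(track), duration_s=track.duration_s
    )
    clean = preprocess.clean_recording(rec)
    return {
        "track": track,
        "bounds": bounds,
        "gt": gt,
        "templates": templates,
        "recording": rec,
        "clean": clean,
    }


@pytest.fixture(scope="session")
def short_events(short_session):
    """Threshold-stage events with waveforms on the cleaned short session."""
    clean = short_session["clean"]
    events = detection.detect_spikes(clean.samples, clean.sample_rate_hz)
    events, _ = detection.extract_waveforms(clean.samples, events)
    return events


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
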