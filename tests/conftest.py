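"""Shared fixtures: synthetic recordings rendered once per session."""

import numpy as np
import pytest

from femdrift.events import label_events, segment_fixations
from femdrift.recording import EyeData, GazeRecording
from femdrift.synth import fixture_script, make_scene_script, render_recording


@pytest.fixture(scope="session")
def clean_recording():
    """12 fixations / 11 saccades, no blinks or microsaccades."""
    rec, truth = render_recording(fixture_script("clean", seed=0))
    return rec, truth


@pytest.fixture(scope="session")
def blinky_recording():
    rec, truth = render_recording(fixture_script("blinky", seed=0))
    return rec, truth


@pytest.fixture(scope="session")
def micro_recording():
    """Long fixations with conjugate microsaccade injections at ~1/s."""
    script = make_scene_script(
        seed=17, n_fixations=30, microsaccade_rate_per_s=1.0,
        duration_range_ms=(800.0, 1200.0),
    )
    rec, truth = render_recording(script)
    return rec, truth


@pytest.fixture(scope="session")
def clean_parsed(clean_recording):
    rec, truth = clean_recording
    labels = label_events(rec)
    segments = segment_fixations(labels, dt_ms=rec.dt_ms)
    return rec, truth, labels, segments


def gaussian_noise_recording(seed=9, n=5000, step_sd=0.07):
    """Binocular pure-random-walk recording (no injected events)."""
    rng = np.random.default_rng(seed)
    t = np.arange(n) * 2.0

    def eye():
        x = 350 + np.cumsum(rng.normal(0, step_sd, n))
        y = 280 + np.cumsum(rng.normal(0, step_sd, n))
        return EyeData(
            x=np.round(x * 10) / 10, y=np.round(y * 10) / 10,
            pupil=np.full(n, 900.0),
        )

    return GazeRecording(t=t, left=eye(), right=eye())
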