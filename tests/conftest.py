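"""Shared fixtures: hand-built recordings with known event structure."""

import numpy as np
import pytest

from gazefatigue.recording import GazeRecording


def make_recording(t, x, y, valid=None, rate=None):
    return GazeRecording(
        t=np.asarray(t, float),
        x=np.asarray(x, float),
        y=np.asarray(y, float),
        valid=valid,
        sample_rate=rate,
    )


def piecewise_fixations(epochs, rate=100.0, jump=20.0):
    """Noiseless recording of stationary epochs at well-separated positions.

    ``epochs`` is a list of durations (s); epoch k sits at x = k * jump.
    Returns the recording; each epoch becomes one detectable fixation whose
    detected duration is (n_samples - 1) / rate.
    """
    ts, xs = [], []
    t0 = 0.0
    for k, dur in enumerate(epochs):
        n = int(round(dur * rate))
        ts.append(t0 + np.arange(n) / rate)
        xs.append(np.full(n, k * jump))
        t0 += n / rate
    t = np.concatenate(ts)
    x = np.concatenate(xs)
    return make_recording(t, x, np.zeros_like(x), rate=rate)


@pytest.fixture
def stationary_1s():
    """One second of perfectly stationary gaze at 100 Hz."""
    return piecewise_fixations([1.0])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
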