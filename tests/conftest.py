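import numpy as np
import pytest

from burstdyn.types import Envelope, TimeSeries


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def ou_envelope():
    """A medium-length OU envelope shared across read-only tests."""
    from burstdyn.envelope_models import simulate_ou
    return simulate_ou(1.0, 1.0, 1e-3, 2000.0, seed=42)


@pytest.fixture()
def beta_tone():
    """20 Hz unit tone with weak noise, 30 s at 1 kHz."""
    dt = 1e-3
    t = np.arange(int(30 / dt)) * dt
    rng = np.random.default_rng(7)
    return TimeSeries(np.cos(2 * np.pi * 20 * t) + 0.05 * rng.standard_normal(len(t)), dt)


def brute_force_runs(values, threshold):
    """Reference run-length scanner: independent oracle for burst detection."""
    runs = []
    start = None
    for i, v in enumerate(values):
        above = v > threshold
        if above and start is None:
            start = i
        elif not above and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(values)))
    return runs
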