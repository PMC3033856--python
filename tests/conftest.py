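import numpy as np
import pytest

from fhrscreen import FhrGenConfig, generate_trace
from fhrscreen.core import Signal


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_fhr_trace():
    """A 5-minute artifact-free synthetic FHR trace."""
    cfg = FhrGenConfig(seed=7, duration_s=300.0, missing_fraction=0.0,
                       spike_rate_per_min=0.0)
    trace, _ = generate_trace(cfg)
    return trace


@pytest.fixture(scope="session")
def raw_fhr_trace():
    """A 20-minute trace with spikes and 20% dropout."""
    cfg = FhrGenConfig(seed=11, duration_s=1200.0, missing_fraction=0.2,
                       spike_rate_per_min=1.0)
    trace, events = generate_trace(cfg)
    return trace, events


def two_tone(fs=4.0, duration=240.0, f_fast=0.5, f_slow=0.05,
             phase_fast=0.0, phase_slow=0.0):
    """Sum of two sinusoids plus the fast component separately."""
    t = np.arange(0, duration, 1.0 / fs)
    fast = np.sin(2 * np.pi * f_fast * t + phase_fast)
    slow = np.sin(2 * np.pi * f_slow * t + phase_slow)
    return Signal(fast + slow, fs, "two_tone"), fast
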