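import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pulsevar as pv

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def clean_config():
    """Default waveform model over a short (60 s) window for fast tests."""
    return pv.WaveformSimConfig(duration=60.0, seed=11)


@pytest.fixture(scope="session")
def clean_recording(clean_config):
    """(beats, waveform) for an artifact-free rendered recording."""
    beats = pv.simulate_beat_sequence(clean_config)
    waveform = pv.render_waveform(beats, clean_config)
    return beats, waveform


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
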