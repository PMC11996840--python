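import numpy as np
import pytest

from emgmeo import Signal, generate_recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_signal(rng):
    return Signal(rng.normal(size=200), fs=1024.0)


@pytest.fixture(scope="session")
def short_recording():
    """A 30 s, 8-burst recording at 20 dB used by several detector tests."""
    return generate_recording(duration=30.0, n_bursts=8, snr_db=20.0, seed=7)
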