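import numpy as np
import pytest

from pyrabeat.synthetic import SyntheticConfig, generate_recording


@pytest.fixture(scope="session")
def clean_config():
    """Noise-free, wander-free short recording config."""
    return SyntheticConfig(
        duration=60.0, noise_snr_db=None, wander_amp=0.0, seed=7
    )


@pytest.fixture(scope="session")
def default_recording():
    """A 60 s synthetic recording with default noise and wander."""
    return generate_recording(SyntheticConfig(duration=60.0, seed=3), "syn003")


@pytest.fixture(scope="session")
def clean_recording(clean_config):
    return generate_recording(clean_config, "syn007")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
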