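import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fractalbci import SessionSpec, gen_session

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_session():
    """An 80-trial, 6-channel session with a moderate planted Hurst shift."""
    return gen_session(SessionSpec(n_channels=6, informative_channels=(1, 4),
                                   hurst_shift=0.25, seed=7))


@pytest.fixture(scope="session")
def tiny_session():
    """A fast 20-trial, 4-channel, 1-s session for structural tests."""
    return gen_session(SessionSpec(n_channels=4, epochs_per_class=10,
                                   epoch_seconds=1.0,
                                   informative_channels=(0, 2),
                                   hurst_shift=0.3, seed=11))
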