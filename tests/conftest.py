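import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cgmr.layout import get_setup, make_default_layout
from cgmr.simulate import NoiseModel

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

#: noiseless rendering shortcut used all over the suite
QUIET = NoiseModel(read_noise_sd=0.0, shot_noise=False, jitter_sd_px=0.0)


@pytest.fixture(scope="session")
def setup1():
    return get_setup("setup1")


@pytest.fixture(scope="session")
def setup2():
    return get_setup("setup2")


@pytest.fixture(scope="session")
def tiny_layout(setup1):
    """Two sensor pairs on the characterisation setup."""
    return make_default_layout(setup1, 2)


def gaussian_profile(n, amplitude, centre, width, offset, noise_sd=0.0, rng=None):
    x = np.arange(n, dtype=float)
    y = amplitude * np.exp(-0.5 * ((x - centre) / width) ** 2) + offset
    if noise_sd > 0:
        y = y + (rng or np.random.default_rng(0)).normal(0, noise_sd, n)
    return y
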