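import numpy as np
import pytest

from leafgas import BiochemParams, EnvironmentalDrivers


@pytest.fixture
def params():
    return BiochemParams()


@pytest.fixture
def fig_params():
    """Typical C3 broadleaf magnitudes used by the synthetic generator."""
    return BiochemParams(vcmax25=47.0, jmax25=105.0, rd25=1.3)


@pytest.fixture
def env():
    return EnvironmentalDrivers()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
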