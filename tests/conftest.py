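import numpy as np
import pytest

from hrvrel.series import RRiSeries


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def stationary_series(rng):
    """600 beats of stationary Gaussian RRi around 800 ms."""
    return RRiSeries(rng.normal(800.0, 30.0, 600))


@pytest.fixture
def gaussian_window(rng):
    """A 256-beat stationary Gaussian window."""
    return rng.normal(800.0, 30.0, 256)
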