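import numpy as np
import pytest

from minifract.events import EventSeries
from minifract.significance import poisson_series


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def poisson_2hz_3600s():
    """One homogeneous Poisson train, rate 2 Hz, one hour."""
    return poisson_series(3600.0, 7200, np.random.default_rng(7))


@pytest.fixture
def small_series():
    return EventSeries(times=np.array([0.005, 0.012, 0.025]), span=0.03)
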