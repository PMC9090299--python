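import numpy as np
import pytest

from rrnapipe import RateParameters, RegimeSchedule, Segment
from rrnapipe import synthetic


@pytest.fixture
def default_params():
    return synthetic.default_true_params()


@pytest.fixture
def heat_recovery_schedule():
    return synthetic.default_schedule()


@pytest.fixture
def single_segment_schedule():
    return RegimeSchedule([Segment(0.0, 24.0, "heat37")])


@pytest.fixture
def rng():
    return np.random.default_rng(20240622)


def random_rate_params(rng, alpha=None):
    """Log-uniform rates in [1e-3, 10] h^-1, uniform alpha, sigma log-uniform."""
    k45, k35, kpa3 = 10.0 ** rng.uniform(-3, 1, size=3)
    sigma = 10.0 ** rng.uniform(-1, 1)
    a = rng.uniform() if alpha is None else alpha
    return RateParameters(sigma=sigma, k45=k45, k35=k35, alpha=a, kpa3=kpa3)
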