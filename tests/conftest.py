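import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cscdrift import RateParams, table1_fixture

settings.register_profile(
    "default", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def demo_params() -> RateParams:
    """A plausible parameter set used throughout the worked examples."""
    return RateParams(k1=0.2, k2=0.22, a=0.01, b=0.001)


@pytest.fixture(scope="session")
def table1():
    return table1_fixture()


@pytest.fixture(scope="session")
def rate_draws():
    """Seeded random non-negative rate draws within a numerically
    representable range (eigenvalue times horizon stays below overflow)."""
    rng = np.random.default_rng(12345)
    return [
        RateParams(k1=rng.uniform(0, 0.5), k2=rng.uniform(0, 0.5),
                   a=rng.uniform(0, 0.25), b=rng.uniform(0, 0.25))
        for _ in range(1000)
    ]
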