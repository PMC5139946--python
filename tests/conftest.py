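import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from twosex.core import solve_equilibrium
from twosex.maternal_age import Case1Parameters, maternal_age_model
from twosex.maternal_quality import Case2Parameters, maternal_quality_model
from twosex.strategy import SexRatioStrategy

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20160907)


@pytest.fixture(scope="session")
def case1a_equal_model():
    """Case 1a with equal maternal reproductive rates (the neutral-line setting)."""
    return maternal_age_model(k1=10.0, k2=10.0, Cm=0.4, Cf=0.6)


@pytest.fixture(scope="session")
def case2_default_model():
    return maternal_quality_model()


@pytest.fixture(scope="session")
def case1a_equal_eq(case1a_equal_model):
    s = SexRatioStrategy(0.6, 0.6)
    return s, solve_equilibrium(case1a_equal_model, s)


def random_simplex(rng, n):
    p = rng.dirichlet(np.ones(n))
    return p
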