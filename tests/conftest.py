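import numpy as np
import pytest

from smartrar import make_scenario
from smartrar.randomization import RandomizationPolicy
from smartrar.simulate import run_trial


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def scenario1():
    return make_scenario(1)


@pytest.fixture(scope="session")
def scenario3():
    return make_scenario(3)


@pytest.fixture(scope="session")
def sr_trial(scenario1):
    """One full-size trial under uniform randomization."""
    return run_trial(scenario1, RandomizationPolicy.from_label("SR"), seed=42)


@pytest.fixture(scope="session")
def br_trial(scenario3):
    """One adaptive BR(1) trial on a reduced accrual window (keeps the
    weekly posterior updates cheap while exercising the whole pipeline)."""
    spec = scenario3.replace(n_patients=80, t_enroll=50)
    policy = RandomizationPolicy.from_label("BR(1)", M=300)
    return run_trial(spec, policy, seed=7)
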