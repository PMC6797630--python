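import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def money_space():
    from fastdisc import DesignSpace

    return DesignSpace.for_commodity("money")


@pytest.fixture(scope="session")
def simulated_session(money_space):
    """One adaptive session from a known responder, shared across tests."""
    from fastdisc import ChoiceParams, run_simulated_session

    params = ChoiceParams(log_k=-3.0, alpha=0.5, epsilon=0.01)
    ds = run_simulated_session(params, money_space, rng_seed=7)
    return params, ds


@pytest.fixture(scope="session")
def fitted_session(simulated_session):
    from fastdisc import fit_posterior

    params, ds = simulated_session
    return params, ds, fit_posterior(ds, rng_seed=11)


@pytest.fixture()
def spillover_table(rng):
    """50-participant change table with a clear spillover pattern."""
    loc = np.array([2.0, 0.5, 0.5])
    return rng.standard_cauchy((50, 3)) * 0.5 + loc
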