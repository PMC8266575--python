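import numpy as np
import pytest

from g4tweezers import (
    NoiseModel,
    fit_bell_mixture,
    forces_from_cycles,
    load_scenario,
    simulate_cycles,
)

N_CYCLES = 5000
SEED = 7


@pytest.fixture(scope="session")
def tb1_scenario():
    return load_scenario("TB-1")


@pytest.fixture(scope="session")
def tb8_scenario():
    return load_scenario("TB-8")


@pytest.fixture(scope="session")
def tb2_scenario():
    return load_scenario("TB-2")


def _simulate_and_fit(scenario, K):
    cycles = simulate_cycles(
        scenario.mixture,
        scenario.protocol,
        scenario.polymer,
        NoiseModel(),
        n_cycles=N_CYCLES,
        seed=SEED,
    )
    forces, n_censored = forces_from_cycles(cycles)
    fit = fit_bell_mixture(forces, n_censored, scenario.protocol, K, seed=SEED)
    return cycles, forces, fit


@pytest.fixture(scope="session")
def tb1_sim_fit(tb1_scenario):
    """(cycles, forces, K=3 fit) for the three-state 5'-bulge scenario."""
    return _simulate_and_fit(tb1_scenario, K=3)


@pytest.fixture(scope="session")
def tb8_sim_fit(tb8_scenario):
    return _simulate_and_fit(tb8_scenario, K=2)


@pytest.fixture(scope="session")
def tb2_sim_fit(tb2_scenario):
    return _simulate_and_fit(tb2_scenario, K=2)
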