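import pytest

from ewescan.simulate import SimulationConfig, simulate_population


@pytest.fixture(scope="session")
def default_sim():
    """One default synthetic cohort shared across tests (seed fixed)."""
    return simulate_population(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def default_cfg():
    return SimulationConfig(seed=11)
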