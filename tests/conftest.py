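import pytest

from dropquant import SimulationConfig, classify_well, simulate_well


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=42)


@pytest.fixture(scope="session")
def mutant_well():
    """One simulated well at 5% mutant fraction, default amplitude model."""
    return simulate_well(SimulationConfig(mutant_fraction=0.05, seed=11))


@pytest.fixture(scope="session")
def classified_mutant_well(mutant_well):
    return classify_well(mutant_well)
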