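import pytest

from kinevo.synth import SimulationConfig, simulate_family, simulate_structures


@pytest.fixture(scope="session")
def default_family():
    """One default-condition synthetic family, shared across tests."""
    cfg = SimulationConfig(seed=11)
    galn, truth = simulate_family(cfg)
    return cfg, galn, truth


@pytest.fixture(scope="session")
def default_structures(default_family):
    cfg, galn, truth = default_family
    return simulate_structures(galn, truth, cfg)
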