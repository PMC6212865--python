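import numpy as np
import pytest

from vesicoloc import SimulationConfig, simulate_field


@pytest.fixture(scope="session")
def default_field():
    """A medium-density noisy field with ground truth, shared across tests."""
    cfg = SimulationConfig(n_vesicles=50, coloc_fraction=0.5, seed=42)
    stack, gt = simulate_field(cfg)
    return cfg, stack, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
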