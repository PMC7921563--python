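import numpy as np
import pytest

from intactrna import SimConfig, simulate


@pytest.fixture(scope="session")
def default_sim():
    """One noise-free default simulation shared across tests (read-only)."""
    cfg = SimConfig(seed=20)
    truth, reads, cage, pas = simulate.simulate_all(cfg)
    return cfg, truth, reads, cage, pas


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
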