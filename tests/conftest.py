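import numpy as np
import pytest

import motifcompare as mc

#: Small-but-honest chain protocol shared by tests that need a real fit.
TINY_CONFIG = mc.ChainConfig(n_chains=3, n_iterations=3000, burn_in=1500,
                             thinning=5, seed=123)


@pytest.fixture(scope="session")
def sim_dataset():
    return mc.simulate_motif_dataset("SIM", seed=7)


@pytest.fixture(scope="session")
def sim_fit(sim_dataset):
    """A reduced SIM-on-SIM posterior fit reused across result-level tests."""
    return mc.MotifModel(sim_dataset, "SIM").fit(TINY_CONFIG)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
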