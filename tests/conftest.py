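import numpy as np
import pandas as pd
import pytest

from asekit.simulate import SimulationConfig, simulate_experiment


@pytest.fixture(scope="session")
def small_sim():
    """A 300-gene simulated experiment shared by read-only tests."""
    return simulate_experiment(SimulationConfig(n_genes=300, seed=11, depth_mean=200.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def counts_table():
    """A tiny hand-written allelic count table."""
    return pd.DataFrame(
        {
            "gene_id": ["g1", "g1", "g1", "g1", "g2", "g2"],
            "tissue": ["liver", "liver", "brain", "brain", "liver", "liver"],
            "timepoint": [2, 2, 2, 2, 2, 2],
            "replicate": [1, 2, 1, 2, 1, 2],
            "marine_count": [30, 35, 50, 45, 10, 12],
            "freshwater_count": [10, 15, 52, 49, 11, 9],
        }
    )
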