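import numpy as np
import pytest

from pathsyn.modeling import TrainConfig
from pathsyn.pipeline import synthetic_end_to_end
from pathsyn.synthetic_data import SimulationConfig, generate_universe


@pytest.fixture(scope="session")
def strong_signal_run():
    """One full synthetic study with the default strong planted signal."""
    return synthetic_end_to_end(SimulationConfig(seed=1), TrainConfig(seed=1))


@pytest.fixture(scope="session")
def small_universe():
    """A reduced universe for unit tests that only need consistent inputs."""
    config = SimulationConfig(
        seed=0,
        n_genes=120,
        n_drugs=8,
        n_pathways=8,
        n_cell_lines=6,
        pathway_size=(10, 25),
        targets_per_drug=(12, 25),
    )
    return generate_universe(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
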