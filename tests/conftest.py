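import numpy as np
import pytest

from cap6am import SimulationConfig, simulate_annotation
from cap6am.synthetic import simulate_truth


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_genes=200, depth_ip=200_000,
                            depth_input=200_000, seed=7)


@pytest.fixture(scope="session")
def small_study(small_config):
    """Annotation + ground truth for a 200-gene study (no tracks)."""
    genes, catalog = simulate_annotation(small_config)
    truth = simulate_truth(small_config, genes)
    return small_config, genes, catalog, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
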