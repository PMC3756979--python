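import numpy as np
import pytest

from lineagedup import synthetic_data as sd
from lineagedup.types import SimConfig


@pytest.fixture(scope="session")
def small_genomes():
    """A small 3-species simulation with one planted pair per mechanism."""
    return sd.simulate_genomes(
        SimConfig(seed=9), n_genes=46, n_species=3,
        n_tandem=1, n_segmental_blocks=1, n_dispersed=1, n_chimera=1,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
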