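import numpy as np
import pytest

from netimpute import SimParams, simulate


@pytest.fixture(scope="session")
def small_sim():
    """A modest grouped simulation whose library size suits its gene count."""
    return simulate(
        SimParams(
            n_genes=120,
            n_cells=300,
            de_prob=0.4,
            de_factor_loc=1.0,
            libsize_location=6.8,
            seed=7,
        )
    )


@pytest.fixture(scope="session")
def learnable_sim():
    """Strong group structure and enough cells for default training to converge."""
    return simulate(
        SimParams(
            n_genes=200,
            n_cells=1000,
            de_prob=0.5,
            de_factor_loc=1.0,
            libsize_location=7.3,
            seed=2,
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
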