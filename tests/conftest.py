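import numpy as np
import pytest

from lazynet.core_model import Monomial, MonomialSystem
from lazynet.synthetic_data import (
    ScreenSimConfig,
    sample_monomial_system,
    simulate_guide_screen,
)


@pytest.fixture
def two_gene_monomial_system():
    """Single production term 3 * x1^2 * x2^-1 feeding gene 1."""
    return MonomialSystem(
        2, [[(1, Monomial(3.0, [2.0, -1.0]))], []]
    )


@pytest.fixture
def linear_oscillator_system():
    """dx1/dt = 0.1 x2, dx2/dt = -0.05 x1."""
    return MonomialSystem(
        2,
        [
            [(1, Monomial(0.1, [0.0, 1.0]))],
            [(-1, Monomial(0.05, [1.0, 0.0]))],
        ],
    )


@pytest.fixture(scope="session")
def sparse_system_20():
    return sample_monomial_system(20, 30, sparsity=0.15, seed=1)


@pytest.fixture(scope="session")
def small_screen():
    """A compact simulated guide screen shared by data-pipeline tests."""
    config = ScreenSimConfig(
        seed=0,
        n_genes=10,
        n_terms=15,
        n_housekeeping_genes=20,
        n_control_cells=100,
        n_singlet_cells=300,
        n_multiplet_cells=30,
    )
    matrix, guides, truth = simulate_guide_screen(config)
    return config, matrix, guides, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
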