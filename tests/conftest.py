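import warnings

import numpy as np
import pytest

import treetraits as tt
from treetraits.impute import (
    ImputationConfig,
    attach_phylo_covariates,
    select_covariates,
)

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def small_world():
    """Desk-scale world shared across tests: 60 species, 8 traits in 4
    correlation blocks, 480 observations."""
    return tt.simulate_traits(
        n_species=60, n_traits=8, n_covariates=6, n_obs=480, n_blocks=4, seed=42
    )


@pytest.fixture(scope="session")
def small_world_covariates(small_world):
    """(table-with-covariates, phylo cols, env cols) for the small world."""
    w = small_world
    basis = tt.phylo_eigenvectors(tt.cophenetic_distances(w.tree), 20)
    table = attach_phylo_covariates(w.table, basis)
    phylo_cols, env_cols = select_covariates(basis, table[w.env_names], 6, 4)
    return table, phylo_cols, env_cols


@pytest.fixture
def fast_config():
    return ImputationConfig(n_trees=50, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
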