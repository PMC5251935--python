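import numpy as np
import pandas as pd
import pytest

from nmfem.nmf import fit_nmf
from nmfem.preprocess import filter_genes
from nmfem.simulate import simulate_populations, simulate_ppi


@pytest.fixture(scope="session")
def two_pop():
    """A moderate two-population dataset with planted markers (fast to cluster)."""
    return simulate_populations(n_genes=800, cells_per_group=30, seed=11)


@pytest.fixture(scope="session")
def two_pop_matrix(two_pop):
    """The filtered expression matrix of ``two_pop`` (all-zero genes removed)."""
    m = filter_genes(two_pop.counts.astype(float))
    return m[m.sum(axis=1) > 0]


@pytest.fixture(scope="session")
def rank2_fit(two_pop_matrix):
    return fit_nmf(two_pop_matrix, 2, seed=42)


@pytest.fixture(scope="session")
def planted_graph():
    graph, planted = simulate_ppi(n_nodes=150, edge_prob=0.03,
                                  planted_module_size=10, seed=5)
    return graph, planted


@pytest.fixture()
def block_matrix():
    """Two sample groups with disjoint elevated gene blocks plus low noise."""
    rng = np.random.default_rng(0)
    A = rng.uniform(0.5, 1.5, size=(40, 20))
    A[:20, :10] += 8.0
    A[20:, 10:] += 8.0
    labels = np.array([1] * 10 + [2] * 10)
    return pd.DataFrame(A, index=[f"g{i}" for i in range(40)],
                        columns=[f"s{j}" for j in range(20)]), labels
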