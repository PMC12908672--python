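import numpy as np
import pytest

from scddi import CountMatrix, apply_random_dropout, simulate_groups


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_truth():
    """Small group-structured simulation shared across tests."""
    return simulate_groups(
        n_genes=300, n_cells=120,
        group_props=(0.5, 0.3, 0.2), de_props=(0.3, 0.2, 0.2),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_sim(small_truth):
    """The same simulation with 40% controlled dropout applied."""
    return apply_random_dropout(small_truth, 0.4, seed=8)


@pytest.fixture
def toy_counts():
    """Deterministic 6-gene x 5-cell count matrix."""
    rng = np.random.default_rng(42)
    vals = rng.poisson(4.0, size=(6, 5))
    vals[0] = 0  # an all-zero gene
    return CountMatrix(
        vals,
        np.array([f"g{i}" for i in range(6)], dtype=object),
        np.array([f"c{j}" for j in range(5)], dtype=object),
    )
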