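import numpy as np
import pytest

from divarea import CommunityTable


def make_disjoint_table(n_samples: int = 10, taxa_per_sample: int = 3,
                        count: int = 5) -> CommunityTable:
    """Pairwise-disjoint samples of equal richness: D_0(A) = k * A exactly."""
    S = n_samples * taxa_per_sample
    counts = np.zeros((n_samples, S), dtype=np.int64)
    for i in range(n_samples):
        counts[i, i * taxa_per_sample:(i + 1) * taxa_per_sample] = count
    return CommunityTable(
        counts,
        [f"S{i}" for i in range(n_samples)],
        [f"T{j}" for j in range(S)],
    )


def make_identical_table(n_samples: int = 10) -> CommunityTable:
    """All samples share one identical community: constant curves."""
    row = np.array([8, 4, 2, 1], dtype=np.int64)
    counts = np.tile(row, (n_samples, 1))
    return CommunityTable(
        counts,
        [f"S{i}" for i in range(n_samples)],
        ["a", "b", "c", "d"],
    )


@pytest.fixture
def disjoint_table() -> CommunityTable:
    return make_disjoint_table()


@pytest.fixture
def identical_table() -> CommunityTable:
    return make_identical_table()


def random_simplex(rng: np.random.Generator, size: int) -> np.ndarray:
    x = rng.dirichlet(np.ones(size))
    return x / x.sum()
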