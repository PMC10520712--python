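import numpy as np
import pytest

from geoconverge.regions import RegionMap, make_lattice_map
from geoconverge.weights import SpatialWeights, row_standardize, weights_from_edges


@pytest.fixture(scope="session")
def lattice30() -> RegionMap:
    """The study-scale 5x6 rook lattice (30 regions)."""
    return make_lattice_map(5, 6)


@pytest.fixture(scope="session")
def w30_std(lattice30) -> SpatialWeights:
    return row_standardize(weights_from_edges(lattice30))


@pytest.fixture()
def path4() -> RegionMap:
    """A 4-node path graph a-b-c-d."""
    return RegionMap(("a", "b", "c", "d"), (("a", "b"), ("b", "c"), ("c", "d")))


@pytest.fixture()
def w_path4(path4) -> SpatialWeights:
    return weights_from_edges(path4)


@pytest.fixture()
def grid2x2() -> RegionMap:
    return make_lattice_map(2, 2)


def random_connected_weights(rng: np.random.Generator, n: int) -> SpatialWeights:
    """Random symmetric binary contiguity over a guaranteed-connected graph."""
    m = np.zeros((n, n))
    order = rng.permutation(n)
    for a, b in zip(order[:-1], order[1:]):  # random spanning tree
        m[a, b] = m[b, a] = 1.0
    extra = rng.random((n, n)) < 0.25
    extra = np.triu(extra, 1)
    m = np.clip(m + extra + extra.T, 0, 1)
    np.fill_diagonal(m, 0.0)
    return SpatialWeights(matrix=m, region_order=tuple(f"r{i}" for i in range(n)))
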