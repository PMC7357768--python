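import numpy as np
import pytest

from beenet.network import BipartiteNetwork


@pytest.fixture
def two_block_net() -> BipartiteNetwork:
    """Two disjoint complete 2x2 blocks; true partition scores Q = 0.5."""
    a = np.zeros((4, 4), dtype=np.uint8)
    a[:2, :2] = 1
    a[2:, 2:] = 1
    return BipartiteNetwork(
        [f"b{i}" for i in range(4)], [f"p{j}" for j in range(4)], a
    )


@pytest.fixture
def two_block_truth(two_block_net) -> dict[str, int]:
    return {n: (0 if n in ("b0", "b1", "p0", "p1") else 1)
            for n in two_block_net.node_names()}


@pytest.fixture
def tiny_net() -> BipartiteNetwork:
    """2 bees x 3 plants, adjacency [[1,1,0],[0,1,1]]."""
    return BipartiteNetwork(
        ["b0", "b1"], ["p0", "p1", "p2"],
        np.array([[1, 1, 0], [0, 1, 1]], dtype=np.uint8),
    )


def random_bipartite(seed: int, n_bees: int = 10, n_plants: int = 14,
                     p: float = 0.3) -> BipartiteNetwork:
    """Unstructured random binary network without isolates."""
    rng = np.random.default_rng(seed)
    while True:
        a = (rng.random((n_bees, n_plants)) < p).astype(np.uint8)
        if a.sum() and (a.sum(axis=1) > 0).all() and (a.sum(axis=0) > 0).all():
            return BipartiteNetwork(
                [f"b{i}" for i in range(n_bees)],
                [f"p{j}" for j in range(n_plants)], a,
            )


@pytest.fixture
def random_net_factory():
    return random_bipartite
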