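import numpy as np
import pytest

from degnet import BipartiteNetwork


@pytest.fixture
def toy_net() -> BipartiteNetwork:
    """Small worked example: 2 conditions, 3 genes, 4 edges."""
    return BipartiteNetwork(
        conditions=frozenset({"c1", "c2"}),
        genes=frozenset({"g1", "g2", "g3"}),
        edges=frozenset({("c1", "g1"), ("c1", "g2"), ("c2", "g2"), ("c2", "g3")}),
    )


@pytest.fixture
def four_cycle() -> BipartiteNetwork:
    return BipartiteNetwork(
        conditions=frozenset({"c1", "c2"}),
        genes=frozenset({"g1", "g2"}),
        edges=frozenset({("c1", "g1"), ("c1", "g2"), ("c2", "g1"), ("c2", "g2")}),
    )


def complete_bipartite(n: int, m: int) -> BipartiteNetwork:
    conds = [f"c{i}" for i in range(n)]
    genes = [f"g{j}" for j in range(m)]
    return BipartiteNetwork(
        conditions=frozenset(conds),
        genes=frozenset(genes),
        edges=frozenset((c, g) for c in conds for g in genes),
    )


def star(n_leaves: int) -> BipartiteNetwork:
    """K_{1,n}: one condition connected to n genes."""
    genes = [f"g{j}" for j in range(n_leaves)]
    return BipartiteNetwork(
        conditions=frozenset({"hub"}),
        genes=frozenset(genes),
        edges=frozenset(("hub", g) for g in genes),
    )


def random_bipartite_instance(
    rng: np.random.Generator,
    max_side: int = 12,
    edge_prob: float | None = None,
) -> BipartiteNetwork:
    """Random small bipartite graph with at least one edge (sides may have
    isolated nodes and the graph may be disconnected)."""
    while True:
        n_c = int(rng.integers(1, max_side + 1))
        n_g = int(rng.integers(1, max_side + 1))
        p = edge_prob if edge_prob is not None else float(rng.uniform(0.1, 0.6))
        conds = [f"c{i}" for i in range(n_c)]
        genes = [f"g{j}" for j in range(n_g)]
        edges = frozenset(
            (c, g) for c in conds for g in genes if rng.random() < p
        )
        if edges:
            return BipartiteNetwork(frozenset(conds), frozenset(genes), edges)
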