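"""Validation of a bipartite network against configuration-model nulls.

The question: does the observed condition-gene network have more shared
structure than expected from its degree sequences alone? The statistic is
the node redundancy coefficient — for a node v with degree >= 2, the
fraction of its neighbor pairs that are also co-covered by some other node
— whose distribution over nodes is compared between the real network and
degree-preserving random bipartite graphs (stub matching, parallel edges
collapsed) with a two-sample Kolmogorov-Smirnov test. The network is
declared distinct from its null when the average D-statistic over
replicates exceeds the D-critical value c(alpha)*sqrt((n1+n2)/(n1*n2)).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .bipartite import BipartiteNetwork
from .errors import DegnetError

logger = logging.getLogger(__name__)

# Smirnov coefficients c(alpha) for the large-sample two-sample critical value
KS_COEFFICIENTS = {
    0.10: 1.22,
    0.05: 1.36,
    0.025: 1.48,
    0.01: 1.63,
    0.005: 1.73,
    0.001: 1.95,
}


@dataclass
class RedundancyDistribution:
    """Redundancy coefficients for all nodes of degree >= 2."""

    values: dict[str, float]
    n_excluded: int  # nodes with degree < 2, for which rc is undefined

    @property
    def sample(self) -> np.ndarray:
        return np.array(sorted(self.values.values()))


@dataclass
class KSResult:
    D: float
    p_value: float
    n1: int
    n2: int
    alpha: float
    D_critical: float


@dataclass
class KSValidationReport:
    replicate_results: list[KSResult]
    average_D: float
    D_critical: float
    alpha: float

    @property
    def verdict(self) -> Literal["distinct", "not-distinct"]:
        return "distinct" if self.average_D > self.D_critical else "not-distinct"


def redundancy_coefficients(net: BipartiteNetwork) -> RedundancyDistribution:
    """Node redundancy coefficient for every node with degree >= 2.

    rc(v) = #{neighbor pairs {u, w} of v : some v' != v is adjacent to both}
            / C(deg(v), 2).
    Computed on both sides; degree-<2 nodes are excluded and counted.
    """
    cond_adj = net.condition_neighbors()  # condition -> genes
    gene_adj = net.gene_neighbors()  # gene -> conditions
    values: dict[str, float] = {}
    excluded = 0

    def _rc(neighbors: frozenset[str], self_id: str, back_adj) -> float:
        nbrs = sorted(neighbors)
        covered = 0
        total = 0
        for u, w in combinations(nbrs, 2):
            total += 1
            if (back_adj[u] & back_adj[w]) - {self_id}:
                covered += 1
        return covered / total

    for c, nbrs in cond_adj.items():
        if len(nbrs) < 2:
            excluded += 1
            continue
        values[c] = _rc(nbrs, c, gene_adj)
    for g, nbrs in gene_adj.items():
        if len(nbrs) < 2:
            excluded += 1
            continue
        values[g] = _rc(nbrs, g, cond_adj)
    if excluded:
        logger.info("redundancy: excluded %d nodes with degree < 2", excluded)
    return RedundancyDistribution(values, excluded)


def random_bipartite(
    deg_C: Sequence[int] | dict[str, int],
    deg_G: Sequence[int] | dict[str, int],
    seed: int,
) -> tuple[BipartiteNetwork, dict[str, int]]:
    """Configuration-model bipartite graph from two degree sequences.

    Creates deg(v) stubs per node, pairs condition stubs with a uniformly
    shuffled list of gene stubs, and collapses parallel edges to obtain a
    simple graph. Returns the graph and the per-node degree deficits caused
    by collapsing (multigraph degrees always equal the input exactly).
    """
    if not isinstance(deg_C, dict):
        deg_C = {f"c{i}": d for i, d in enumerate(deg_C)}
    if not isinstance(deg_G, dict):
        deg_G = {f"g{i}": d for i, d in enumerate(deg_G)}
    if sum(deg_C.values()) != sum(deg_G.values()):
        raise DegnetError(
            f"stub totals differ: sum deg_C={sum(deg_C.values())}, "
            f"sum deg_G={sum(deg_G.values())}"
        )
    rng = np.random.default_rng(seed)
    c_stubs = [c for c, d in sorted(deg_C.items()) for _ in range(d)]
    g_stubs = [g for g, d in sorted(deg_G.items()) for _ in range(d)]
    perm = rng.permutation(len(g_stubs))
    edges = set()
    for cs, j in zip(c_stubs, perm):
        edges.add((cs, g_stubs[j]))
    net = BipartiteNetwork(
        conditions=frozenset(deg_C),
        genes=frozenset(deg_G),
        edges=frozenset(edges),
    )
    deficits = {}
    for side, target in (("C", deg_C), ("G", deg_G)):
        actual = net.degree(side)
        for v, d in target.items():
            loss = d - actual.get(v, 0)
            if loss:
                deficits[v] = loss
    return net, deficits


def ks_critical(n1: int, n2: int, alpha: float = 0.05) -> float:
    """Large-sample two-sample KS rejection threshold at level alpha."""
    if n1 < 1 or n2 < 1:
        raise DegnetError("sample sizes must be >= 1")
    if alpha not in KS_COEFFICIENTS:
        raise DegnetError(
            f"unsupported alpha {alpha}; supported: {sorted(KS_COEFFICIENTS)}"
        )
    return KS_COEFFICIENTS[alpha] * math.sqrt((n1 + n2) / (n1 * n2))


def ks_two_sample(
    sample1: Sequence[float], sample2: Sequence[float], alpha: float = 0.05
) -> KSResult:
    """Two-sample KS test: D is the largest vertical ECDF gap."""
    s1 = np.asarray(sample1, dtype=float)
    s2 = np.asarray(sample2, dtype=float)
    if s1.size == 0 or s2.size == 0:
        raise DegnetError("KS test requires non-empty samples")
    res = stats.ks_2samp(s1, s2, method="asymp")
    return KSResult(
        D=float(res.statistic),
        p_value=float(res.pvalue),
        n1=s1.size,
        n2=s2.size,
        alpha=alpha,
        D_critical=ks_critical(s1.size, s2.size, alpha),
    )


def validate_against_null(
    net: BipartiteNetwork,
    replicates: int = 10,
    seed: int = 0,
    alpha: float = 0.05,
) -> KSValidationReport:
    """KS-compare the network's redundancy distribution to configuration-model draws.

    Each replicate i draws a degree-preserving random bipartite graph with
    seed ``seed + i``, computes its redundancy distribution, and runs the
    two-sample KS test against the real network's distribution. The report
    averages the replicate D values; its D-critical is the mean of the
    replicate thresholds (sample sizes are the eligible-node counts, which
    vary slightly across draws after parallel-edge collapsing).
    """
    if replicates < 1:
        raise DegnetError("replicates must be >= 1")
    real = redundancy_coefficients(net)
    deg_C = net.degree("C")
    deg_G = net.degree("G")
    results: list[KSResult] = []
    for i in range(replicates):
        rand_net, _ = random_bipartite(deg_C, deg_G, seed=seed + i)
        rand = redundancy_coefficients(rand_net)
        results.append(ks_two_sample(real.sample, rand.sample, alpha=alpha))
    avg_D = float(np.mean([r.D for r in results]))
    d_crit = float(np.mean([r.D_critical for r in results]))
    return KSValidationReport(results, avg_D, d_crit, alpha)
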