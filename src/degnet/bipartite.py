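"""Condition-gene bipartite networks and their centrality measures.

A direction-specific bipartite graph BG = (C, G, E) connects each condition
(e.g. a cancer type) to the genes called differentially expressed in it in
that direction. Centralities use bipartite-specific normalizations
(Borgatti & Everett style): degree is scaled by the opposite side's size;
closeness by the minimum achievable distance sum in a bipartite graph
(distance 1 to the opposite side, 2 within a side); betweenness by a
closed-form maximum that depends on both side sizes through the integer
quotients/remainders s, t (side C) and p, r (side G).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import networkx as nx

from .errors import EmptyNetworkError, IntegrityError
from .io import DEGTable

Side = Literal["C", "G"]

# internal node tags keep condition and gene id spaces disjoint inside networkx
_C, _G = "C", "G"


@dataclass(frozen=True)
class BipartiteNetwork:
    """Simple bipartite graph between condition nodes C and gene nodes G."""

    conditions: frozenset[str]
    genes: frozenset[str]
    edges: frozenset[tuple[str, str]]  # (condition, gene)

    def __post_init__(self):
        for c, g in self.edges:
            if c not in self.conditions or g not in self.genes:
                raise IntegrityError(f"edge ({c!r}, {g!r}) has endpoints outside C/G")

    @property
    def C_n(self) -> int:
        return len(self.conditions)

    @property
    def G_n(self) -> int:
        return len(self.genes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def gene_neighbors(self) -> dict[str, frozenset[str]]:
        """Map gene -> set of conditions it is linked to."""
        adj: dict[str, set[str]] = {g: set() for g in self.genes}
        for c, g in self.edges:
            adj[g].add(c)
        return {g: frozenset(s) for g, s in adj.items()}

    def condition_neighbors(self) -> dict[str, frozenset[str]]:
        """Map condition -> set of genes linked to it."""
        adj: dict[str, set[str]] = {c: set() for c in self.conditions}
        for c, g in self.edges:
            adj[c].add(g)
        return {c: frozenset(s) for c, s in adj.items()}

    def degree(self, node_side: Side) -> dict[str, int]:
        adj = self.condition_neighbors() if node_side == "C" else self.gene_neighbors()
        return {v: len(nbrs) for v, nbrs in adj.items()}

    def to_networkx(self) -> nx.Graph:
        """Undirected graph over tagged nodes ('C', id) / ('G', id)."""
        g = nx.Graph()
        g.add_nodes_from(((_C, c) for c in self.conditions), bipartite=0)
        g.add_nodes_from(((_G, x) for x in self.genes), bipartite=1)
        g.add_edges_from(((_C, c), (_G, x)) for c, x in self.edges)
        return g


@dataclass
class CentralityTable:
    """Per-node scores for one centrality measure on one bipartite network."""

    measure: Literal["degree", "closeness", "betweenness"]
    scores_C: dict[str, float] = field(default_factory=dict)
    scores_G: dict[str, float] = field(default_factory=dict)

    def side(self, side: Side) -> dict[str, float]:
        return self.scores_C if side == "C" else self.scores_G


@dataclass(frozen=True)
class BetweennessNormalization:
    """Closed-form denominators for bipartite betweenness normalization.

    s = (C_n-1) // G_n, t = (C_n-1) % G_n, and symmetrically p, r for the
    gene side; the denominators are the maximum raw betweenness attainable
    by a node of each side in a bipartite graph of these dimensions.
    """

    C_n: int
    G_n: int

    @property
    def s(self) -> int:
        return (self.C_n - 1) // self.G_n

    @property
    def t(self) -> int:
        return (self.C_n - 1) % self.G_n

    @property
    def p(self) -> int:
        return (self.G_n - 1) // self.C_n

    @property
    def r(self) -> int:
        return (self.G_n - 1) % self.C_n

    @property
    def denom_C(self) -> float:
        s, t, G_n = self.s, self.t, self.G_n
        return 0.5 * (
            G_n**2 * (s + 1) ** 2
            + G_n * (s + 1) * (2 * t - s - 1)
            - t * (2 * s - t + 3)
        )

    @property
    def denom_G(self) -> float:
        p, r, C_n = self.p, self.r, self.C_n
        return 0.5 * (
            C_n**2 * (p + 1) ** 2
            + C_n * (p + 1) * (2 * r - p - 1)
            - r * (2 * p - r + 3)
        )


def build_bipartite(table: DEGTable, direction: Literal["up", "down"]) -> BipartiteNetwork:
    """Bipartite condition-gene graph from one direction of a DEG table.

    An edge (c, g) exists iff gene g is differentially expressed in
    condition c with the requested direction. A gene up in one condition
    and down in another appears in both direction networks.
    """
    sub = table.df[table.df["direction"] == direction]
    if sub.empty:
        raise EmptyNetworkError(f"no records with direction={direction!r}")
    edges = frozenset(zip(sub["condition"], sub["gene"]))
    return BipartiteNetwork(
        conditions=frozenset(sub["condition"]),
        genes=frozenset(sub["gene"]),
        edges=edges,
    )


def _require_nonempty(net: BipartiteNetwork) -> None:
    if net.C_n == 0 or net.G_n == 0:
        raise EmptyNetworkError("bipartite network has an empty side")


def degree_centrality(net: BipartiteNetwork) -> CentralityTable:
    """D_c = deg(c)/G_n for conditions, D_g = deg(g)/C_n for genes."""
    _require_nonempty(net)
    deg_C = net.degree("C")
    deg_G = net.degree("G")
    return CentralityTable(
        measure="degree",
        scores_C={c: d / net.G_n for c, d in deg_C.items()},
        scores_G={g: d / net.C_n for g, d in deg_G.items()},
    )


def closeness_centrality(net: BipartiteNetwork) -> CentralityTable:
    """Closeness_c = (G_n + 2(C_n-1)) / d_c and symmetrically for genes.

    d_v is the sum of geodesic distances from v to every other node,
    computed by BFS on the unweighted graph. On disconnected graphs the sum
    runs over v's component only while the numerator keeps the global side
    sizes — a documented convention, not part of the normalization's design.
    """
    _require_nonempty(net)
    g = net.to_networkx()
    num_C = net.G_n + 2 * (net.C_n - 1)
    num_G = net.C_n + 2 * (net.G_n - 1)
    scores_C: dict[str, float] = {}
    scores_G: dict[str, float] = {}
    for node in g.nodes:
        dists = nx.single_source_shortest_path_length(g, node)
        d_v = sum(dists.values())  # distance to self is 0
        tag, name = node
        if d_v == 0:  # isolated node
            score = 0.0
        elif tag == _C:
            score = num_C / d_v
        else:
            score = num_G / d_v
        (scores_C if tag == _C else scores_G)[name] = score
    return CentralityTable("closeness", scores_C, scores_G)


def betweenness_centrality(net: BipartiteNetwork) -> CentralityTable:
    """Raw shortest-path betweenness scaled by the bipartite closed-form maxima.

    B(v) sums sigma_xy(v)/sigma_xy over unordered node pairs {x, y} with
    endpoints excluded; Bet(v) = B(v)/denom for the node's side.
    """
    _require_nonempty(net)
    g = net.to_networkx()
    raw = nx.betweenness_centrality(g, normalized=False)
    norm = BetweennessNormalization(net.C_n, net.G_n)
    scores_C = {
        name: raw[(_C, name)] / norm.denom_C if norm.denom_C > 0 else 0.0
        for name in net.conditions
    }
    scores_G = {
        name: raw[(_G, name)] / norm.denom_G if norm.denom_G > 0 else 0.0
        for name in net.genes
    }
    return CentralityTable("betweenness", scores_C, scores_G)


def top_fraction_union(
    tables: list[CentralityTable],
    fraction: float = 0.05,
    side: Side = "G",
) -> tuple[set[str], dict[str, set[str]]]:
    """Union of the top-``fraction`` nodes under each centrality measure.

    Per table, nodes of the requested side are ranked by descending score
    and the top ceil(fraction*N) are selected, extended to include every
    node tied with the boundary score. Returns (union, selected_by) where
    selected_by maps each selected node to the measures that picked it.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    node_sets = {frozenset(t.side(side)) for t in tables}
    if len(node_sets) != 1:
        raise IntegrityError("centrality tables cover inconsistent node sets")
    selected_by: dict[str, set[str]] = {}
    for t in tables:
        scores = t.side(side)
        ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
        k = math.ceil(fraction * len(ranked))
        if k == 0:
            continue
        boundary = ranked[k - 1][1]
        for name, s in ranked:
            if s > boundary or math.isclose(s, boundary, rel_tol=0, abs_tol=1e-12):
                selected_by.setdefault(name, set()).add(t.measure)
            else:
                break
    return set(selected_by), selected_by


def centrality_frame(tables: list[CentralityTable], net: BipartiteNetwork):
    """Combine measure tables into one tidy frame (node, side, one column per measure)."""
    import pandas as pd

    rows = []
    for side, names in (("C", net.conditions), ("G", net.genes)):
        for name in sorted(names):
            row = {"node": name, "side": side}
            for t in tables:
                row[t.measure] = t.side(side)[name]
            rows.append(row)
    return pd.DataFrame(rows)
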