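"""Jaccard-weighted one-mode projection and component analysis.

Projecting the bipartite graph onto its gene side links two genes whenever
they share at least one condition, weighting the edge by the Jaccard index
of their condition neighborhoods, w(u,v) = |N(u) ∩ N(v)| / |N(u) ∪ N(v)|.
Thresholding at a high cutoff (default 0.9) keeps only near-identical
differential-expression profiles; the resulting connected components are
candidate co-regulated gene groups, and each component's per-condition
coverage plus a hypergeometric enrichment identifies which conditions (or
condition subtypes) the component characterizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Literal

import networkx as nx
import pandas as pd

from .bipartite import BipartiteNetwork, Side
from .enrichment import bh_adjust, hypergeometric_tail
from .errors import DegnetError, EmptyNetworkError
from .io import DEGTable


@dataclass
class ProjectedNetwork:
    """One-mode projection with Jaccard edge weights in (0, 1]."""

    side: Side
    nodes: frozenset[str]
    edges: dict[tuple[str, str], float]  # canonical (min, max) pairs
    isolated_dropped: frozenset[str] = frozenset()

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for (u, v), w in self.edges.items():
            g.add_edge(u, v, weight=w)
        return g


@dataclass
class ComponentProfile:
    """Per-condition coverage and enrichment of one projected component."""

    component: frozenset[str]
    table: pd.DataFrame  # columns: condition, coverage, p, adj_p

    @property
    def enriched_conditions(self) -> list[str]:
        sub = self.table[self.table["adj_p"] < 0.05]
        return sorted(sub["condition"])


def _canonical(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u <= v else (v, u)


def project(net: BipartiteNetwork, side: Side = "G") -> ProjectedNetwork:
    """One-mode projection of a bipartite network onto one side.

    Nodes u, v of the chosen side are linked iff their bipartite
    neighborhoods intersect, with Jaccard weight.
    """
    if side == "G":
        adj = net.gene_neighbors()
        opp_adj = net.condition_neighbors()
    else:
        adj = net.condition_neighbors()
        opp_adj = net.gene_neighbors()
    if not adj:
        raise EmptyNetworkError(f"side {side} is empty")
    # enumerate candidate pairs through shared opposite-side nodes
    candidates: set[tuple[str, str]] = set()
    for nbrs in opp_adj.values():
        for u, v in combinations(sorted(nbrs), 2):
            candidates.add((u, v))
    edges: dict[tuple[str, str], float] = {}
    for u, v in candidates:
        inter = len(adj[u] & adj[v])
        if inter:
            edges[(u, v)] = inter / len(adj[u] | adj[v])
    return ProjectedNetwork(side=side, nodes=frozenset(adj), edges=edges)


def threshold_edges(pn: ProjectedNetwork, cutoff: float = 0.9) -> ProjectedNetwork:
    """Keep edges with weight >= cutoff (inclusive); drop newly isolated nodes.

    Dropped nodes are reported on the result's ``isolated_dropped`` field.
    """
    if not 0 <= cutoff <= 1:
        raise DegnetError(f"cutoff must be in [0, 1], got {cutoff}")
    kept = {e: w for e, w in pn.edges.items() if w >= cutoff}
    with_edges = frozenset(n for e in kept for n in e)
    return ProjectedNetwork(
        side=pn.side,
        nodes=with_edges,
        edges=kept,
        isolated_dropped=pn.nodes - with_edges,
    )


def connected_components(pn: ProjectedNetwork) -> list[frozenset[str]]:
    """Components of the projected graph, largest first.

    Ties in size are broken by the lexicographically smallest member, so
    the ordering is deterministic.
    """
    comps = [frozenset(c) for c in nx.connected_components(pn.to_networkx())]
    return sorted(comps, key=lambda c: (-len(c), min(c)))


def cutoff_sweep(
    pn: ProjectedNetwork, cutoffs: list[float]
) -> pd.DataFrame:
    """Component count and largest-component size at each weight cutoff.

    Counts are taken over the projection's full node set, with nodes left
    isolated by thresholding counted as singleton components; on this fixed
    node set raising the cutoff only removes edges, so the component count
    is non-decreasing and the largest component non-increasing in cutoff.
    """
    rows = []
    for c in cutoffs:
        g = nx.Graph()
        g.add_nodes_from(pn.nodes)
        g.add_edges_from(e for e, w in pn.edges.items() if w >= c)
        comps = sorted(nx.connected_components(g), key=len, reverse=True)
        rows.append(
            {
                "cutoff": c,
                "n_components": len(comps),
                "largest_component": len(comps[0]) if comps else 0,
                "n_edges": g.number_of_edges(),
            }
        )
    return pd.DataFrame(rows)


def component_condition_profile(
    component: frozenset[str] | set[str],
    table: DEGTable,
    direction: Literal["up", "down"],
) -> ComponentProfile:
    """Coverage fraction and hypergeometric enrichment of a component per condition.

    Universe M = all genes in the direction's network; successes K = genes
    DEG in the condition; draws n = the component. P-values are BH-adjusted
    across conditions.
    """
    component = frozenset(component)
    sub = table.df[table.df["direction"] == direction]
    universe = set(sub["gene"])
    unknown = component - universe
    if unknown:
        raise DegnetError(f"genes not in {direction}-network universe: {sorted(unknown)[:10]}")
    M = len(universe)
    n = len(component)
    rows = []
    for cond, cond_genes in sub.groupby("condition")["gene"]:
        hits = set(cond_genes)
        k = len(component & hits)
        rows.append(
            {
                "condition": cond,
                "coverage": k / n,
                "p": hypergeometric_tail(k, len(hits), n, M),
            }
        )
    df = pd.DataFrame(rows).sort_values("condition").reset_index(drop=True)
    df["adj_p"] = bh_adjust(df["p"].tolist())
    return ComponentProfile(component=component, table=df)
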