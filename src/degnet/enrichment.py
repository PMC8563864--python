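"""Hypergeometric over-representation tests with Benjamini-Hochberg control.

Three flavors share the same upper-tail statistic P(X >= k) for an overlap
k between a query of size n and a category of size K inside a universe of
size M: (a) gene-set enrichment against a GMT-style collection, (b) TF
enrichment against a regulatory network with the rank / p-value / target-
count filter cascade, and (c) edge-overlap significance between a projected
network and a reference interaction network, where the universe is the set
of unordered node pairs over the shared nodes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DegnetError
from .io import GeneSetCollection, InteractionNetwork, RegulatoryNetwork

ENRICHMENT_COLUMNS = ["term", "k", "K", "n", "M", "p", "adj_p"]


@dataclass
class EdgeOverlapResult:
    shared_edges: int
    query_edges: int
    reference_edges: int
    pair_universe: int
    p: float


def hypergeometric_tail(k: int, K: int, n: int, M: int) -> float:
    """Upper-tail probability P(X >= k), X ~ Hypergeometric(M, K, n)."""
    if not (0 <= K <= M and 0 <= n <= M and k >= 0):
        raise DegnetError(f"invalid hypergeometric parameters k={k}, K={K}, n={n}, M={M}")
    if k == 0:
        return 1.0
    if k > min(K, n):
        return 0.0
    return float(stats.hypergeom.sf(k - 1, M, K, n))


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    ps = list(pvalues)
    if not ps:
        return []
    if any(p < 0 or p > 1 for p in ps):
        raise DegnetError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(ps, method="fdr_bh")
    return [float(p) for p in adj]


def gene_set_enrichment(
    query: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric enrichment of a gene query against each term of a collection.

    Terms are intersected with the universe first; terms empty after
    intersection are not tested. Result rows are sorted by adj_p then term.
    """
    query = set(query)
    universe = set(universe)
    offenders = query - universe
    if offenders:
        raise DegnetError(f"query genes outside universe: {sorted(offenders)[:10]}")
    M = len(universe)
    n = len(query)
    rows = []
    for term in sorted(collection):
        members = collection.members(term) & universe
        if not members:
            continue
        k = len(members & query)
        rows.append(
            {"term": term, "k": k, "K": len(members), "n": n, "M": M,
             "p": hypergeometric_tail(k, len(members), n, M)}
        )
    df = pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS[:-1])
    if df.empty:
        df["adj_p"] = []
        return df
    df["adj_p"] = bh_adjust(df["p"].tolist())
    return df.sort_values(["adj_p", "term"]).reset_index(drop=True)


def tf_enrichment(
    query: Iterable[str],
    grn: RegulatoryNetwork,
    top_fraction: float = 0.25,
    adj_p_max: float = 0.05,
    min_targets_in_query: int = 10,
) -> pd.DataFrame:
    """Per-TF enrichment of regulatory targets in a gene query, then filter.

    The universe is the union of all target genes in the regulatory
    network. After BH adjustment across TFs, three filters apply in order:
    keep the top ceil(top_fraction * #TFs) by ascending adj_p (ties at the
    boundary included), then adj_p < adj_p_max, then overlap k >=
    min_targets_in_query.
    """
    if not grn.targets_of:
        raise DegnetError("regulatory network has no TFs")
    universe = grn.all_targets
    query = set(query) & universe
    M = len(universe)
    n = len(query)
    rows = []
    for tf in sorted(grn.targets_of):
        targets = grn.targets_of[tf]
        k = len(targets & query)
        rows.append(
            {"term": tf, "k": k, "K": len(targets), "n": n, "M": M,
             "p": hypergeometric_tail(k, len(targets), n, M)}
        )
    df = pd.DataFrame(rows)
    df["adj_p"] = bh_adjust(df["p"].tolist())
    df = df.sort_values(["adj_p", "term"]).reset_index(drop=True)
    n_keep = math.ceil(top_fraction * len(df))
    if n_keep:
        boundary = df["adj_p"].iloc[n_keep - 1]
        df = df[df["adj_p"] <= boundary]
    df = df[df["adj_p"] < adj_p_max]
    df = df[df["k"] >= min_targets_in_query]
    return df.reset_index(drop=True)


def edge_overlap_significance(
    pn, ref: InteractionNetwork, universe: str = "shared"
) -> EdgeOverlapResult:
    """Hypergeometric significance of shared edges between a projected and a reference network.

    Both edge sets are restricted to nodes present in both networks; the
    universe is all unordered pairs over those shared nodes (or over the
    node union with ``universe='union'`` for sensitivity analysis).
    """
    pn_nodes = set(pn.nodes)
    ref_nodes = set(ref.nodes)
    shared = pn_nodes & ref_nodes
    if len(shared) < 2:
        raise DegnetError("fewer than 2 shared nodes: no pair universe")
    if universe == "shared":
        pool = shared
    elif universe == "union":
        pool = pn_nodes | ref_nodes
    else:
        raise DegnetError(f"unknown universe {universe!r}")
    m = len(pool)
    M = m * (m - 1) // 2
    proj_edges = {e for e in pn.edges if e[0] in shared and e[1] in shared}
    ref_edges = {e for e in ref.edges if e[0] in shared and e[1] in shared}
    k = len(proj_edges & ref_edges)
    return EdgeOverlapResult(
        shared_edges=k,
        query_edges=len(proj_edges),
        reference_edges=len(ref_edges),
        pair_universe=M,
        p=hypergeometric_tail(k, len(ref_edges), len(proj_edges), M),
    )
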