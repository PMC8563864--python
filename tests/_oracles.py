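"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from first principles (adjacency counting,
hand-rolled BFS, exhaustive shortest-path enumeration, double-loop ECDFs,
combinatorial sums) and deliberately shares no code with the package.
"""

from __future__ import annotations

import math
from collections import deque
from itertools import combinations


def bipartite_adjacency(net) -> dict:
    """Adjacency over tagged nodes ('C', c) / ('G', g) built edge by edge."""
    adj = {("C", c): set() for c in net.conditions}
    adj.update({("G", g): set() for g in net.genes})
    for c, g in net.edges:
        adj[("C", c)].add(("G", g))
        adj[("G", g)].add(("C", c))
    return adj


def bfs_distances(adj: dict, source) -> dict:
    dist = {source: 0}
    q = deque([source])
    while q:
        u = q.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def brute_degree_centrality(net) -> dict:
    adj = bipartite_adjacency(net)
    out = {}
    for (tag, name), nbrs in adj.items():
        denom = net.G_n if tag == "C" else net.C_n
        out[(tag, name)] = len(nbrs) / denom
    return out


def brute_closeness_centrality(net) -> dict:
    adj = bipartite_adjacency(net)
    out = {}
    for node in adj:
        tag = node[0]
        d = sum(bfs_distances(adj, node).values())
        if d == 0:
            out[node] = 0.0
        elif tag == "C":
            out[node] = (net.G_n + 2 * (net.C_n - 1)) / d
        else:
            out[node] = (net.C_n + 2 * (net.G_n - 1)) / d
    return out


def _all_shortest_paths(adj: dict, x, y):
    """Enumerate every shortest x-y path by DFS over the BFS distance layers."""
    dist = bfs_distances(adj, x)
    if y not in dist:
        return []
    paths = []

    def extend(path):
        u = path[-1]
        if u == y:
            paths.append(list(path))
            return
        for v in adj[u]:
            if dist.get(v) == dist[u] + 1 and dist[v] <= dist[y]:
                path.append(v)
                extend(path)
                path.pop()

    extend([x])
    return paths


def brute_betweenness_raw(net) -> dict:
    """B(v) = sum over unordered pairs {x,y} of sigma_xy(v)/sigma_xy."""
    adj = bipartite_adjacency(net)
    nodes = sorted(adj)
    B = {v: 0.0 for v in nodes}
    for x, y in combinations(nodes, 2):
        paths = _all_shortest_paths(adj, x, y)
        if not paths:
            continue
        sigma = len(paths)
        interior_counts = {}
        for p in paths:
            for v in p[1:-1]:
                interior_counts[v] = interior_counts.get(v, 0) + 1
        for v, cnt in interior_counts.items():
            B[v] += cnt / sigma
    return B


def brute_betweenness_denominators(C_n: int, G_n: int) -> tuple[float, float]:
    s, t = divmod(C_n - 1, G_n)
    p, r = divmod(G_n - 1, C_n)
    denom_C = 0.5 * (
        G_n**2 * (s + 1) ** 2 + G_n * (s + 1) * (2 * t - s - 1) - t * (2 * s - t + 3)
    )
    denom_G = 0.5 * (
        C_n**2 * (p + 1) ** 2 + C_n * (p + 1) * (2 * r - p - 1) - r * (2 * p - r + 3)
    )
    return denom_C, denom_G


def brute_jaccard_projection(net, side: str) -> dict:
    """Double loop over same-side node pairs computing set overlaps exactly."""
    if side == "G":
        members = sorted(net.genes)
        nbr = {g: {c for c, x in net.edges if x == g} for g in members}
    else:
        members = sorted(net.conditions)
        nbr = {c: {x for cc, x in net.edges if cc == c} for c in members}
    out = {}
    for u, v in combinations(members, 2):
        inter = nbr[u] & nbr[v]
        if inter:
            out[(u, v)] = len(inter) / len(nbr[u] | nbr[v])
    return out


def brute_redundancy(net) -> dict:
    """rc per node of degree >= 2 by exhaustive neighbor-pair checking."""
    adj = bipartite_adjacency(net)
    out = {}
    for v, nbrs in adj.items():
        if len(nbrs) < 2:
            continue
        pairs = list(combinations(sorted(nbrs), 2))
        covered = 0
        for u, w in pairs:
            if any(
                v2 != v and u in adj[v2] and w in adj[v2]
                for v2 in adj  # scan every node as potential co-coverer
            ):
                covered += 1
        out[v] = covered / len(pairs)
    return out


def brute_ks_D(sample1, sample2) -> float:
    """Largest ECDF gap evaluated at every observed point."""
    n1, n2 = len(sample1), len(sample2)
    best = 0.0
    for x in list(sample1) + list(sample2):
        f1 = sum(1 for v in sample1 if v <= x) / n1
        f2 = sum(1 for v in sample2 if v <= x) / n2
        best = max(best, abs(f1 - f2))
    return best


def brute_hypergeom_tail(k: int, K: int, n: int, M: int) -> float:
    total = math.comb(M, n)
    acc = 0
    for j in range(k, min(K, n) + 1):
        acc += math.comb(K, j) * math.comb(M - K, n - j)
    return acc / total


def brute_bh(pvalues):
    """Step-up BH computed literally from the definition."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adj = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, pvalues[i] * m / rank)
        adj[i] = running_min
    return adj
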