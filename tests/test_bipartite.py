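import math

import numpy as np
import pandas as pd
import pytest

from degnet import (
    BetweennessNormalization,
    DEGTable,
    EmptyNetworkError,
    IntegrityError,
    betweenness_centrality,
    build_bipartite,
    closeness_centrality,
    degree_centrality,
    top_fraction_union,
)
from degnet.bipartite import CentralityTable

from _oracles import (
    brute_betweenness_denominators,
    brute_betweenness_raw,
    brute_closeness_centrality,
    brute_degree_centrality,
)
from conftest import complete_bipartite, random_bipartite_instance, star


class TestBuildBipartite:
    def test_edges_follow_per_record_direction(self):
        df = pd.DataFrame(
            {
                "gene": ["g1", "g1", "g2"],
                "condition": ["c1", "c2", "c1"],
                "log_fc": [2.0, -2.0, 1.5],
                "adj_p": [0.01, 0.01, 0.01],
            }
        )
        table = DEGTable(df)
        up = build_bipartite(table, "up")
        down = build_bipartite(table, "down")
        # g1 is up in c1 and down in c2, so it appears in both networks
        assert ("c1", "g1") in up.edges and ("c1", "g2") in up.edges
        assert down.edges == {("c2", "g1")}
        assert up.C_n == 1 and up.G_n == 2 and up.n_edges == 2

    def test_no_records_of_direction_raises(self):
        df = pd.DataFrame(
            {"gene": ["g1"], "condition": ["c1"], "log_fc": [2.0], "adj_p": [0.01]}
        )
        with pytest.raises(EmptyNetworkError):
            build_bipartite(DEGTable(df), "down")

    def test_degree_sums_match_edge_count(self, toy_net):
        assert sum(toy_net.degree("C").values()) == toy_net.n_edges
        assert sum(toy_net.degree("G").values()) == toy_net.n_edges


class TestWorkedExample:
    """Hand-derived centrality values on the 2x3 toy graph."""

    def test_degree(self, toy_net):
        t = degree_centrality(toy_net)
        assert t.scores_C["c1"] == pytest.approx(2 / 3)
        assert t.scores_G["g2"] == pytest.approx(1.0)
        assert t.scores_G["g1"] == pytest.approx(1 / 2)

    def test_closeness(self, toy_net):
        t = closeness_centrality(toy_net)
        # d(g2) = 1+1+2+2 = 6 ; numerator C_n + 2(G_n-1) = 6
        assert t.scores_G["g2"] == pytest.approx(1.0)
        # d(c1) = 1+1+2+3 = 7 ; numerator G_n + 2(C_n-1) = 5
        assert t.scores_C["c1"] == pytest.approx(5 / 7)

    def test_betweenness(self, toy_net):
        t = betweenness_centrality(toy_net)
        # B(g2)=4 and denom_G = 4 with p=1, r=0
        assert t.scores_G["g2"] == pytest.approx(1.0)
        norm = BetweennessNormalization(C_n=2, G_n=3)
        assert (norm.p, norm.r) == (1, 0)
        assert norm.denom_G == pytest.approx(4.0)


class TestClosedFormLimits:
    @pytest.mark.parametrize("n,m", [(2, 2), (3, 5), (4, 4), (1, 6)])
    def test_complete_bipartite_degree_and_closeness_are_one(self, n, m):
        net = complete_bipartite(n, m)
        deg = degree_centrality(net)
        clo = closeness_centrality(net)
        for t in (deg, clo):
            for score in list(t.scores_C.values()) + list(t.scores_G.values()):
                assert score == pytest.approx(1.0)

    @pytest.mark.parametrize("n_leaves", [2, 5, 9])
    def test_star_center_betweenness_is_one_and_leaves_zero(self, n_leaves):
        net = star(n_leaves)
        t = betweenness_centrality(net)
        assert t.scores_C["hub"] == pytest.approx(1.0)
        assert all(v == 0.0 for v in t.scores_G.values())

    def test_degree_one_node_has_zero_betweenness(self, toy_net):
        t = betweenness_centrality(toy_net)
        assert t.scores_G["g1"] == 0.0 and t.scores_G["g3"] == 0.0


class TestOracleEquivalence:
    """All three centralities match independent brute-force implementations
    on random small bipartite graphs."""

    def test_centralities_match_brute_force(self):
        rng = np.random.default_rng(42)
        for _ in range(40):
            net = random_bipartite_instance(rng, max_side=10)
            deg = degree_centrality(net)
            clo = closeness_centrality(net)
            bet = betweenness_centrality(net)
            b_deg = brute_degree_centrality(net)
            b_clo = brute_closeness_centrality(net)
            b_raw = brute_betweenness_raw(net)
            d_C, d_G = brute_betweenness_denominators(net.C_n, net.G_n)
            for c in net.conditions:
                assert deg.scores_C[c] == pytest.approx(b_deg[("C", c)], abs=1e-9)
                assert clo.scores_C[c] == pytest.approx(b_clo[("C", c)], abs=1e-9)
                expect = b_raw[("C", c)] / d_C if d_C > 0 else 0.0
                assert bet.scores_C[c] == pytest.approx(expect, abs=1e-9)
            for g in net.genes:
                assert deg.scores_G[g] == pytest.approx(b_deg[("G", g)], abs=1e-9)
                assert clo.scores_G[g] == pytest.approx(b_clo[("G", g)], abs=1e-9)
                expect = b_raw[("G", g)] / d_G if d_G > 0 else 0.0
                assert bet.scores_G[g] == pytest.approx(expect, abs=1e-9)

    def test_matches_networkx_bipartite_variants(self):
        """Independent cross-check against the networkx bipartite module."""
        import networkx as nx
        from networkx.algorithms import bipartite as nxb

        from _oracles import brute_betweenness_denominators

        rng = np.random.default_rng(7)
        checked = 0
        while checked < 20:
            net = random_bipartite_instance(rng, max_side=8, edge_prob=0.5)
            d_C, d_G = brute_betweenness_denominators(net.C_n, net.G_n)
            if d_C <= 0 or d_G <= 0:  # networkx divides by these unconditionally
                continue
            checked += 1
            g = nx.Graph()
            g.add_nodes_from((("C", c) for c in net.conditions), bipartite=0)
            g.add_nodes_from((("G", x) for x in net.genes), bipartite=1)
            g.add_edges_from((("C", c), ("G", x)) for c, x in net.edges)
            top = {("C", c) for c in net.conditions}
            nx_deg = nxb.degree_centrality(g, top)
            nx_bet = nxb.betweenness_centrality(g, top)
            deg = degree_centrality(net)
            bet = betweenness_centrality(net)
            for c in net.conditions:
                assert deg.scores_C[c] == pytest.approx(nx_deg[("C", c)], abs=1e-9)
                assert bet.scores_C[c] == pytest.approx(nx_bet[("C", c)], abs=1e-9)
            for x in net.genes:
                assert deg.scores_G[x] == pytest.approx(nx_deg[("G", x)], abs=1e-9)
                assert bet.scores_G[x] == pytest.approx(nx_bet[("G", x)], abs=1e-9)


class TestTopFractionUnion:
    @staticmethod
    def _table(scores: dict[str, float], measure="degree") -> CentralityTable:
        return CentralityTable(measure=measure, scores_C={}, scores_G=scores)

    def test_union_of_identical_tables_is_single_top_set(self):
        scores = {f"g{i}": 1.0 - i / 100 for i in range(100)}
        tables = [self._table(scores, m) for m in ("degree", "closeness", "betweenness")]
        union, selected_by = top_fraction_union(tables, 0.05)
        assert len(union) == 5
        assert all(selected_by[g] == {"degree", "closeness", "betweenness"}
                   for g in union)

    def test_distinct_scores_select_exact_ceiling(self):
        scores = {f"g{i}": float(100 - i) for i in range(100)}
        union, _ = top_fraction_union([self._table(scores)], 0.05)
        assert union == {"g0", "g1", "g2", "g3", "g4"}

    def test_boundary_ties_are_all_included(self):
        # ranks 4-6 share the boundary score: selection grows from 5 to 7
        scores = {f"g{i}": float(100 - i) for i in range(100)}
        scores["g4"] = scores["g5"] = scores["g6"] = 96.0
        union, _ = top_fraction_union([self._table(scores)], 0.05)
        assert len(union) == 7
        assert {"g4", "g5", "g6"} <= union

    def test_inconsistent_node_sets_rejected(self):
        t1 = self._table({"a": 1.0, "b": 0.5})
        t2 = self._table({"a": 1.0, "c": 0.5}, measure="closeness")
        with pytest.raises(IntegrityError):
            top_fraction_union([t1, t2], 0.5)

    def test_adding_an_edge_never_lowers_endpoint_degree_centrality(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            net = random_bipartite_instance(rng, max_side=6)
            non_edges = [
                (c, g)
                for c in net.conditions
                for g in net.genes
                if (c, g) not in net.edges
            ]
            if not non_edges:
                continue
            c, g = non_edges[rng.integers(len(non_edges))]
            bigger = type(net)(
                net.conditions, net.genes, net.edges | {(c, g)}
            )
            before = degree_centrality(net)
            after = degree_centrality(bigger)
            assert after.scores_C[c] >= before.scores_C[c]
            assert after.scores_G[g] >= before.scores_G[g]
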