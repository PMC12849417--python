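"""Network stage: score combination, enrichment, MCL, BH-FDR."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from famprio.cohort_io import read_edge_list
from famprio.network import (
    MCLParams,
    Network,
    _normalize_columns,
    benjamini_hochberg,
    combine_channel_scores,
    filter_edges,
    gene_set_enrichment,
    mcl_cluster,
    ppi_enrichment,
)


def nx_network(g: nx.Graph) -> Network:
    return Network(graph=g)


class TestCombineScores:
    def test_single_channel_identity_at_zero_prior(self):
        assert combine_channel_scores([0.6], prior=0.0) == pytest.approx(0.6)

    def test_plain_noisy_or(self):
        assert combine_channel_scores([0.5, 0.5], prior=0.0) == pytest.approx(0.75)

    def test_prior_corrected_formula_oracle(self):
        # independent step-by-step evaluation of the stated formula
        prior = 0.041
        s = (0.9 - prior) / (1 - prior)
        expected = (1 - (1 - s) ** 2) * (1 - prior) + prior
        assert combine_channel_scores([0.9, 0.9], prior=prior) == pytest.approx(expected)

    def test_channel_below_prior_contributes_nothing(self):
        assert combine_channel_scores([0.02], prior=0.041) == pytest.approx(0.0)

    @pytest.mark.parametrize("bad", [[1.2], []])
    def test_invalid_channels(self, bad):
        with pytest.raises(ValueError):
            combine_channel_scores(bad, prior=0.0)

    def test_prior_one_rejected(self):
        with pytest.raises(ValueError):
            combine_channel_scores([0.5], prior=1.0)

    @given(
        scores=st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=4),
        prior=st.floats(min_value=0, max_value=0.5),
    )
    def test_combined_in_unit_interval_and_dominates_channels(self, scores, prior):
        c = combine_channel_scores(scores, prior=prior)
        assert 0.0 <= c <= 1.0
        corrected = [max(0.0, (s - prior) / (1 - prior)) for s in scores]
        if max(corrected) > 0:
            assert c >= max(scores) - 1e-12 or c >= prior


class TestFilterEdges:
    def test_inclusive_boundary_and_node_retention(self, edge_tsv):
        df = pd.DataFrame(
            {
                "protein_a": ["A", "A", "B"],
                "protein_b": ["B", "C", "C"],
                "combined_score": [0.400, 0.399, 0.9],
            }
        )
        net = Network.from_edge_table(df)
        kept = filter_edges(net, 0.400)
        assert kept.graph.has_edge("A", "B")      # 0.400 kept (minimum required)
        assert not kept.graph.has_edge("A", "C")  # 0.399 dropped
        assert kept.nodes == {"A", "B", "C"}

    def test_all_below_leaves_edgeless_graph_with_nodes(self):
        df = pd.DataFrame(
            {"protein_a": ["A"], "protein_b": ["B"], "combined_score": [0.1]}
        )
        kept = filter_edges(Network.from_edge_table(df), 0.4)
        assert kept.m == 0 and kept.nodes == {"A", "B"}

    def test_from_edge_list_reader(self, edge_tsv):
        net = Network.from_edge_table(read_edge_list(edge_tsv), prior=0.0)
        assert net.nodes == {"X", "Y", "Z"}
        # X-Y combined = noisy-OR of (0.9, 0.4, 0.2)
        expected = 1 - (1 - 0.9) * (1 - 0.4) * (1 - 0.2)
        assert net.graph["X"]["Y"]["combined_score"] == pytest.approx(expected)


class TestPpiEnrichment:
    def test_planted_clique_is_significant(self):
        g = nx.gnp_random_graph(100, 0.05, seed=42)
        g = nx.relabel_nodes(g, {i: f"P{i:03d}" for i in range(100)})
        clique = [f"P{i:03d}" for i in range(6)]
        for a, b in itertools.combinations(clique, 2):
            g.add_edge(a, b)
        res = ppi_enrichment(nx_network(g), clique, reps=1000, seed=7)
        assert res.observed_edges == 15
        assert res.p_value <= 0.01

    def test_two_disconnected_nodes_give_p_one(self):
        g = nx.Graph()
        g.add_edges_from([("A", "B"), ("C", "D")])
        g.add_nodes_from(["E", "F"])
        res = ppi_enrichment(nx_network(g), ["E", "F"], reps=500, seed=0)
        # observed 0 edges: every permutation draw has >= 0, so p is exactly 1
        assert res.observed_edges == 0
        assert res.p_value == 1.0

    def test_determinism_under_seed(self):
        g = nx.gnp_random_graph(50, 0.1, seed=3)
        g = nx.relabel_nodes(g, {i: str(i) for i in g})
        q = [str(i) for i in range(8)]
        r1 = ppi_enrichment(nx_network(g), q, reps=300, seed=11)
        r2 = ppi_enrichment(nx_network(g), q, reps=300, seed=11)
        assert r1.p_value == r2.p_value

    def test_degree_poisson_expected_matches_brute_force(self):
        g = nx.gnp_random_graph(30, 0.2, seed=5)
        g = nx.relabel_nodes(g, {i: str(i) for i in g})
        query = [str(i) for i in range(10)]
        res = ppi_enrichment(nx_network(g), query, method="degree_poisson")
        m = g.number_of_edges()
        lam = sum(
            min(g.degree[a] * g.degree[b] / (2 * m), 1.0)
            for a, b in itertools.combinations(query, 2)
        )
        assert res.expected_edges == pytest.approx(lam)

    def test_query_outside_network_names_missing(self):
        g = nx.Graph([("A", "B")])
        with pytest.raises(KeyError, match="ZZZ"):
            ppi_enrichment(nx_network(g), ["A", "ZZZ"])

    def test_permutation_p_lower_bound(self):
        g = nx.complete_graph(10)
        g = nx.relabel_nodes(g, {i: str(i) for i in g})
        res = ppi_enrichment(nx_network(g), ["0", "1", "2"], reps=200, seed=1)
        assert res.p_value >= 1 / 201


class TestMcl:
    def test_two_disjoint_triangles(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c")])
        g.add_edges_from([("x", "y"), ("y", "z"), ("x", "z")])
        cs = mcl_cluster(nx_network(g))
        assert sorted(map(sorted, cs.clusters)) == [["a", "b", "c"], ["x", "y", "z"]]

    def test_complete_graph_single_cluster(self):
        g = nx.complete_graph(5)
        g = nx.relabel_nodes(g, {i: str(i) for i in g})
        cs = mcl_cluster(nx_network(g), MCLParams(inflation=3.0))
        assert len(cs) == 1 and len(cs.clusters[0]) == 5

    def test_partition_covers_every_node_exactly_once(self):
        g = nx.gnp_random_graph(40, 0.15, seed=9)
        g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g})
        cs = mcl_cluster(nx_network(g))
        nodes = [n for c in cs.clusters for n in c]
        assert sorted(nodes) == sorted(g.nodes)
        assert all(len(c) > 0 for c in cs.clusters)

    def test_invariant_under_relabeling(self):
        g = nx.gnp_random_graph(25, 0.25, seed=2)
        mapping = {i: f"A{i:02d}" for i in g}
        g1 = nx.relabel_nodes(g, mapping)
        # a different labelling of the same graph
        perm = {f"A{i:02d}": f"B{(i * 7) % 25:02d}" for i in range(25)}
        g2 = nx.relabel_nodes(g1, perm)
        p1 = {frozenset(perm[n] for n in c) for c in mcl_cluster(nx_network(g1)).clusters}
        p2 = {frozenset(c) for c in mcl_cluster(nx_network(g2)).clusters}
        assert p1 == p2

    def test_never_merges_components(self):
        g = nx.disjoint_union(nx.gnp_random_graph(12, 0.5, seed=1),
                              nx.gnp_random_graph(12, 0.5, seed=2))
        g = nx.relabel_nodes(g, {i: str(i) for i in g})
        comp = {n: ci for ci, c in enumerate(nx.connected_components(g)) for n in c}
        for cluster in mcl_cluster(nx_network(g)).clusters:
            assert len({comp[n] for n in cluster}) == 1

    def test_column_normalization_is_stochastic(self):
        rng = np.random.default_rng(0)
        m = _normalize_columns(rng.random((30, 30)))
        assert np.allclose(m.sum(axis=0), 1.0, atol=1e-12)

    def test_bad_params_rejected(self):
        with pytest.raises(ValueError):
            MCLParams(inflation=1.0)
        with pytest.raises(ValueError):
            MCLParams(expansion=1)


class TestGeneSetEnrichment:
    def test_closed_form_oracle_perfect_overlap(self):
        universe = {f"G{i}" for i in range(1000)}
        term = {f"G{i}" for i in range(10)}
        res = gene_set_enrichment(term, {"T": term}, universe)
        row = res.terms.iloc[0]
        expected = 1.0 / math.comb(1000, 10)
        assert row["p"] == pytest.approx(expected, rel=1e-9)
        assert row["overlap"] == 10

    def test_zero_overlap_p_one(self):
        universe = {f"G{i}" for i in range(100)}
        res = gene_set_enrichment(
            {"G1", "G2"}, {"T": {"G90", "G91"}}, universe
        )
        assert res.terms.iloc[0]["p"] == 1.0

    def test_q_never_below_p_and_sorted(self):
        universe = {f"G{i}" for i in range(200)}
        sets = {f"T{j}": {f"G{i}" for i in range(j, j + 20)} for j in range(0, 100, 10)}
        res = gene_set_enrichment({f"G{i}" for i in range(15)}, sets, universe)
        assert (res.terms["q"] >= res.terms["p"] - 1e-15).all()
        assert res.terms["q"].is_monotonic_increasing

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            gene_set_enrichment({"A"}, {"T": {"A"}}, set())


class TestBenjaminiHochberg:
    def test_hand_computed_step_up(self):
        q = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.3])[0] == pytest.approx(0.3)

    def test_ties_get_equal_q(self):
        q = benjamini_hochberg([0.02, 0.02, 0.5])
        assert q[0] == q[1]

    def test_order_equivariant_and_dominates_p(self):
        rng = np.random.default_rng(4)
        p = rng.random(20)
        q = benjamini_hochberg(p)
        assert (q >= p - 1e-12).all() and (q <= 1).all()
        perm = rng.permutation(20)
        assert np.allclose(benjamini_hochberg(p[perm]), q[perm])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(8)
        for _ in range(20):
            p = rng.random(rng.integers(1, 40))
            ours = benjamini_hochberg(p)
            theirs = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(ours, theirs)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.1, 1.5])
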