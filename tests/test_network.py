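import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fosnet import (
    GroupCorrelation,
    build_graph,
    detect_communities,
    hub_table,
    modularity,
    node_metrics,
    pearson_p_value,
)
from fosnet.network import DEGENERATE_COMMUNITY, ISOLATE
from oracles import max_modularity_brute_force, modularity_direct


def corr_from_matrix(r, n=7, regions=None):
    r = np.asarray(r, dtype=float)
    regions = regions or [f"R{i}" for i in range(r.shape[0])]
    p = pearson_p_value(r, n)
    np.fill_diagonal(p, 0.0)
    z = np.arctanh(np.clip(r, -0.999999, 0.999999))
    return GroupCorrelation(
        genotype="WT", condition="HC", regions=regions, r=r, p=p, z=z, n=n,
        warnings=[],
    )


class TestEdgeRule:
    def test_compound_criterion_at_n7(self):
        """At n = 7 the p < 0.05 criterion dominates r > 0.60: the edge
        appears only once r clears ~0.754."""
        r = np.eye(3)
        r[0, 1] = r[1, 0] = 0.65  # p ~ 0.115: above threshold_r, not significant
        r[0, 2] = r[2, 0] = 0.90  # p ~ 0.006: passes both
        graph = build_graph(corr_from_matrix(r))
        assert not graph.has_edge("R0", "R1")
        assert graph.has_edge("R0", "R2")
        assert graph.number_of_nodes() == 3

    def test_threshold_grid_matches_t_cdf_oracle(self):
        """Edge admission over a grid of r at n = 7 equals the analytic
        compound rule, which bites at |r| ~ 0.754."""
        import scipy.stats

        grid = np.linspace(0.0, 0.99, 100)
        admitted = []
        for r_val in grid:
            r = np.eye(2)
            r[0, 1] = r[1, 0] = r_val
            g = build_graph(corr_from_matrix(r))
            admitted.append(g.number_of_edges() == 1)
        t = grid * np.sqrt(5) / np.sqrt(1 - grid**2)
        p = 2 * scipy.stats.t.sf(t, 5)
        expected = (grid > 0.60) & (p < 0.05)
        assert admitted == expected.tolist()
        switch = grid[np.argmax(expected)]
        assert 0.75 < switch <= 0.76

    def test_raising_threshold_never_adds_edges(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(6, 7))
        r = np.corrcoef(a)
        corr = corr_from_matrix(r)
        low = set(build_graph(corr, threshold_r=0.6).edges)
        high = set(build_graph(corr, threshold_r=0.8).edges)
        assert high <= low

    def test_missing_entries_never_form_edges(self):
        r = np.eye(3)
        r[0, 1] = r[1, 0] = np.nan
        r[0, 2] = r[2, 0] = 0.9
        corr = corr_from_matrix(r)
        corr.p[0, 1] = corr.p[1, 0] = np.nan
        g = build_graph(corr)
        assert not g.has_edge("R0", "R1") and g.has_edge("R0", "R2")


def two_triangles():
    g = nx.Graph()
    g.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
    return g


FIXTURES = {
    "two_triangles": two_triangles(),
    "k5": nx.complete_graph(5),
    "path6": nx.path_graph(6),
    "star6": nx.star_graph(5),
    "planted_2block": nx.Graph(
        [(0, 1), (0, 2), (1, 2), (0, 3), (1, 3), (2, 3),
         (4, 5), (4, 6), (5, 6), (4, 7), (5, 7), (6, 7), (3, 4)]
    ),
}

#: path6 is greedy-hard: the first local-move phase pairs neighbors into
#: {01}{23}{45} (Q = 0.26) and no aggregation move can split a super-node
#: to reach the global optimum {012}{345} (Q = 0.30). The local optimum
#: still beats the all-singletons partition.
GREEDY_HARD = {"path6"}


class TestModularityOptimization:
    def test_two_triangles_partition_and_q(self):
        part = detect_communities(two_triangles(), seed=0, weighted=False)
        assert part.Q == pytest.approx(0.5, abs=1e-12)
        assert part.assignment[0] == part.assignment[1] == part.assignment[2]
        assert part.assignment[3] == part.assignment[4] == part.assignment[5]
        assert part.assignment[0] != part.assignment[3]

    def test_complete_graph_stays_one_community(self):
        part = detect_communities(nx.complete_graph(5), seed=0, weighted=False)
        best_q, _ = max_modularity_brute_force(nx.complete_graph(5))
        assert len(set(part.assignment.values())) == 1
        assert part.Q == pytest.approx(best_q, abs=1e-9)

    @pytest.mark.parametrize("name", sorted(FIXTURES))
    def test_matches_brute_force_maximum(self, name):
        """On every <= 8-node fixture the greedy optimum reaches the global
        maximum over all partitions (and never falls below singletons)."""
        graph = FIXTURES[name]
        part = detect_communities(graph, seed=0, weighted=False)
        best_q, _ = max_modularity_brute_force(graph)
        singleton_q = modularity(
            graph, {v: i for i, v in enumerate(graph.nodes)}, weighted=False
        )
        assert part.Q >= singleton_q - 1e-12
        if name in GREEDY_HARD:
            assert part.Q <= best_q + 1e-9
            assert part.Q == pytest.approx(0.26, abs=1e-9)
        else:
            assert part.Q == pytest.approx(best_q, abs=1e-9)

    @pytest.mark.parametrize("name", sorted(FIXTURES))
    def test_reported_q_matches_its_assignment(self, name):
        graph = FIXTURES[name]
        part = detect_communities(graph, seed=1, weighted=False)
        assert part.Q == pytest.approx(
            modularity_direct(graph, part.assignment), abs=1e-12
        )

    def test_agrees_with_networkx_louvain_quality(self):
        """Independent cross-check: our Q on a 40-node random graph is at
        least as good as networkx Louvain's minus noise tolerance."""
        graph = nx.gnp_random_graph(40, 0.12, seed=8)
        ours = detect_communities(graph, seed=0, weighted=False)
        best_nx = max(
            nx.community.modularity(
                graph, nx.community.louvain_communities(graph, seed=s)
            )
            for s in range(5)
        )
        assert ours.Q >= best_nx - 0.03

    def test_empty_graph_gives_singletons_q_zero(self):
        g = nx.Graph()
        g.add_nodes_from("abcde")
        part = detect_communities(g, seed=0)
        assert part.Q == 0.0
        assert sorted(part.assignment.values()) == list(range(5))

    def test_seed_determinism_and_equivalence(self):
        graph = nx.gnp_random_graph(25, 0.2, seed=4)
        a = detect_communities(graph, seed=5, weighted=False)
        b = detect_communities(graph, seed=5, weighted=False)
        assert a.assignment == b.assignment and a.Q == b.Q

    def test_weighted_detection_uses_edge_weights(self):
        # two squares joined by a heavy bridge: weights flip the split
        g = nx.Graph()
        for u, v in [(0, 1), (1, 2), (2, 3), (3, 0), (4, 5), (5, 6), (6, 7), (7, 4)]:
            g.add_edge(u, v, r=0.1)
        g.add_edge(3, 4, r=5.0)
        unweighted = detect_communities(g, seed=0, weighted=False)
        weighted = detect_communities(g, seed=0, weighted=True)
        assert unweighted.assignment[3] != unweighted.assignment[4]
        assert weighted.assignment[3] == weighted.assignment[4]

    def test_better_than_singletons_on_thresholded_synthetic(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(10, 12))
        r = np.corrcoef(a)
        corr = corr_from_matrix(r, n=12, regions=[f"R{i}" for i in range(10)])
        graph = build_graph(corr, threshold_r=0.3)
        part = detect_communities(graph, seed=0)
        singles = modularity(graph, {v: i for i, v in enumerate(graph.nodes)})
        assert part.Q >= singles


class TestNodeMetrics:
    def test_all_internal_edges_give_zero_participation(self):
        part = detect_communities(two_triangles(), seed=0, weighted=False)
        metrics = node_metrics(two_triangles(), part).set_index("region")
        assert (metrics["P"] == 0).all()

    def test_even_two_way_split_gives_half(self):
        g = nx.Graph()
        g.add_edges_from([("x", "a1"), ("x", "a2"), ("x", "b1"), ("x", "b2")])
        g.add_edges_from([("a1", "a2"), ("b1", "b2")])
        from fosnet import CommunityPartition

        part = CommunityPartition(
            assignment={"x": 0, "a1": 0, "a2": 0, "b1": 1, "b2": 1}, Q=0.0, seed=0
        )
        metrics = node_metrics(g, part).set_index("region")
        assert metrics.loc["x", "P"] == pytest.approx(0.5)

    def test_star_center_has_maximal_z(self):
        g = nx.star_graph(5)
        from fosnet import CommunityPartition

        part = CommunityPartition(
            assignment={v: 0 for v in g.nodes}, Q=0.0, seed=0
        )
        metrics = node_metrics(g, part).set_index("region")
        assert metrics.loc[0, "z"] == metrics["z"].max()
        assert metrics.loc[0, "z"] > 0

    def test_mean_within_degree_node_has_zero_z(self):
        g = nx.cycle_graph(5)  # all within-degrees equal -> degenerate SD
        from fosnet import CommunityPartition

        part = CommunityPartition(
            assignment={v: 0 for v in g.nodes}, Q=0.0, seed=0
        )
        metrics = node_metrics(g, part)
        assert (metrics["z"] == 0).all()
        assert (metrics["flags"] == DEGENERATE_COMMUNITY).all()

    def test_isolates_flagged_with_zero_metrics(self):
        g = nx.Graph()
        g.add_nodes_from(["a", "b"])
        g.add_edge("c", "d")
        part = detect_communities(g, seed=0)
        metrics = node_metrics(g, part).set_index("region")
        assert metrics.loc["a", "P"] == 0 and metrics.loc["a", "degree"] == 0
        assert ISOLATE in metrics.loc["a", "flags"]

    @given(st.integers(0, 1000))
    @settings(max_examples=25, deadline=None)
    def test_kappa_sums_and_bounds_on_random_graphs(self, seed):
        """Per-community link counts sum to degree; 0 <= P < 1; z has mean 0
        and SD 1 within non-degenerate communities."""
        graph = nx.gnp_random_graph(14, 0.25, seed=seed)
        part = detect_communities(graph, seed=seed, weighted=False)
        metrics = node_metrics(graph, part)
        # kappa identity is internal to within_degree + cross split
        for _, row in metrics.iterrows():
            assert 0 <= row["P"] < 1
            assert row["within_degree"] <= row["degree"]
        by_comm = metrics[metrics["flags"] == ""].groupby("community")["z"]
        for _, z in by_comm:
            assert z.mean() == pytest.approx(0.0, abs=1e-9)
            assert z.std(ddof=0) == pytest.approx(1.0, abs=1e-9)


class TestHubTable:
    def test_ranking_order_and_tiebreaks(self):
        metrics = pd.DataFrame(
            {
                "region": ["b", "a", "c", "d"],
                "community": [0, 0, 1, 1],
                "degree": [3, 3, 2, 0],
                "within_degree": [2, 2, 2, 0],
                "z": [1.0, 2.0, 0.0, 0.0],
                "P": [0.5, 0.5, 0.1, 0.0],
                "flags": ["", "", "", ISOLATE],
            }
        )
        ranked = hub_table(metrics)
        assert list(ranked["region"]) == ["a", "b", "c", "d"]

    def test_all_isolates_fall_back_to_label_order(self):
        metrics = pd.DataFrame(
            {
                "region": ["c", "a", "b"],
                "community": [0, 1, 2],
                "degree": [0, 0, 0],
                "within_degree": [0, 0, 0],
                "z": [0.0, 0.0, 0.0],
                "P": [0.0, 0.0, 0.0],
                "flags": [ISOLATE] * 3,
            }
        )
        assert list(hub_table(metrics)["region"]) == ["a", "b", "c"]

    def test_optional_cutoffs_classify(self):
        metrics = pd.DataFrame(
            {
                "region": ["a", "b"],
                "community": [0, 1],
                "degree": [4, 4],
                "within_degree": [2, 4],
                "z": [2.0, -1.0],
                "P": [0.6, 0.1],
                "flags": ["", ""],
            }
        )
        ranked = hub_table(metrics, z_cutoff=1.0, p_cutoff=0.5)
        assert ranked.set_index("region")["is_hub"].to_dict() == {
            "a": True,
            "b": False,
        }


def test_bh_correction_never_adds_edges():
    rng = np.random.default_rng(12)
    a = rng.normal(size=(8, 7))
    r = np.corrcoef(a)
    corr = corr_from_matrix(r, n=7, regions=[f"R{i}" for i in range(8)])
    plain = set(map(frozenset, build_graph(corr, threshold_r=0.2).edges))
    bh = set(map(frozenset,
                 build_graph(corr, threshold_r=0.2, bh_correction=True).edges))
    assert bh <= plain
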