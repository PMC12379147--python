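import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from eddc import (
    Graph,
    clgc,
    closeness_centrality,
    clustering_coefficient,
    degree_centrality,
    betweenness_centrality,
    eclgc,
    eddc,
    eddc_aggregate,
    isolating_centrality,
    k_shell,
    lgc,
    neighbor_probabilities,
    node_entropy,
    rank_nodes,
)
from eddc.centrality import ScoreTable, compute_method

from conftest import make_er
from oracles import (
    bc_pair_counting,
    clgc_naive,
    clustering_brute,
    eclgc_naive,
    eddc_naive,
    entropy_brute,
    floyd_warshall,
    kshell_naive,
    lgc_naive,
)


def complete(n):
    return Graph([(i, j) for i in range(n) for j in range(i + 1, n)])


def cycle(n):
    return Graph([(i, (i + 1) % n) for i in range(n)])


class TestBaselines:
    def test_degree_centrality(self, toy, star5):
        assert degree_centrality(toy).scores[2] == 4
        dc = degree_centrality(star5).scores
        assert dc[0] == 4 and all(dc[i] == 1 for i in range(1, 5))

    def test_degree_equals_adjacency_row_sums(self):
        g = make_er(30, 0.1, seed=2)
        a = np.zeros((g.N, g.N))
        for i in range(g.N):
            for j in g.neighbor_indices(i):
                a[i, j] = 1
        expected = a.sum(axis=1)
        got = degree_centrality(g).array(g.nodes)
        np.testing.assert_array_equal(got, expected)

    def test_betweenness_path_and_clique(self):
        p3 = Graph([(1, 2), (2, 3)])
        bc = betweenness_centrality(p3).scores
        assert bc == {1: 0.0, 2: 1.0, 3: 0.0}
        assert all(v == 0.0 for v in betweenness_centrality(complete(4)).scores.values())

    def test_closeness(self, path4):
        p3 = Graph([(1, 2), (2, 3)])
        assert closeness_centrality(p3).scores[2] == 1.0
        assert all(v == 1.0 for v in closeness_centrality(complete(5)).scores.values())
        g = make_er(25, 0.15, seed=4)
        fw = floyd_warshall(g)
        got = closeness_centrality(g).array(g.nodes)
        for i in range(g.N):
            row = fw[i][np.isfinite(fw[i])]
            expected = (g.N - 1) / row.sum() if row.sum() > 0 else 0.0
            assert got[i] == pytest.approx(expected, abs=1e-12)

    def test_closeness_isolated_node_is_zero(self):
        g = Graph([(1, 2)], nodes=[1, 2, 3])
        assert closeness_centrality(g).scores[3] == 0.0

    def test_clustering(self, star5):
        tri = Graph([(1, 2), (2, 3), (1, 3)])
        assert all(v == 1.0 for v in clustering_coefficient(tri).scores.values())
        assert clustering_coefficient(star5).scores[0] == 0.0
        g = make_er(30, 0.2, seed=6)
        brute = clustering_brute(g)
        got = clustering_coefficient(g).scores
        assert got == pytest.approx(brute, abs=1e-12)

    def test_isolating_centrality(self, star5):
        # no neighbor of the star center has degree >= 2
        assert isolating_centrality(star5, delta=2).scores[0] == 0.0
        assert all(v == 9.0 for v in isolating_centrality(complete(4), delta=2).scores.values())

    def test_isolating_delta_zero_is_degree_squared(self):
        g = make_er(20, 0.2, seed=8)
        got = isolating_centrality(g, delta=0).scores
        assert got == {v: float(g.degree(v) ** 2) for v in g.nodes}

    def test_lgc_closed_forms(self):
        k2 = Graph([(1, 2)])
        assert lgc(k2).scores == pytest.approx({1: 0.5, 2: 0.5})
        s3 = Graph([(0, 1), (0, 2)])
        assert lgc(s3).scores[0] == pytest.approx(4 / 3)

    def test_k_shell(self, star5):
        assert all(v == 2.0 for v in k_shell(cycle(6)).scores.values())
        assert all(v == 1.0 for v in k_shell(star5).scores.values())

    def test_k_shell_matches_naive_peeling(self):
        for seed in range(8):
            g = make_er(40, 0.1, seed=seed)
            assert k_shell(g).scores == kshell_naive(g)

    def test_clgc_tree_is_zero(self, path4, star5):
        for g in (path4, star5):
            assert all(v == 0.0 for v in clgc(g).scores.values())

    def test_clgc_two_triangles_joined(self):
        g = Graph([(1, 2), (2, 3), (1, 3), (4, 5), (5, 6), (4, 6), (3, 4)])
        assert clgc(g).scores == pytest.approx(clgc_naive(g), abs=1e-12)
        # bridge endpoints have CLC 1/3, others 1: spot-check one hand value
        clc = clustering_coefficient(g).scores
        assert clc[3] == pytest.approx(1 / 3)

    def test_eclgc_tree_and_triangle(self, path4):
        assert all(v == 0.0 for v in eclgc(path4).scores.values())
        tri = Graph([(1, 2), (2, 3), (1, 3)])
        assert eclgc(tri).scores == pytest.approx(
            {v: 2 + 2 * math.sqrt(2) for v in (1, 2, 3)}
        )

    @pytest.mark.parametrize("seed", range(3))
    def test_distance_sum_centralities_match_naive_oracles(self, seed):
        g = make_er(25, 0.15, seed=seed)
        assert lgc(g).scores == pytest.approx(lgc_naive(g), abs=1e-9)
        assert clgc(g).scores == pytest.approx(clgc_naive(g), abs=1e-9)
        assert eclgc(g).scores == pytest.approx(eclgc_naive(g), abs=1e-9)
        assert eddc(g).scores == pytest.approx(eddc_naive(g), abs=1e-9)
        assert betweenness_centrality(g).scores == pytest.approx(
            bc_pair_counting(g), abs=1e-9
        )


class TestEntropy:
    def test_toy_node_2_probabilities(self, toy):
        p = neighbor_probabilities(toy, 2)
        assert p == pytest.approx({1: 1 / 9, 3: 3 / 9, 4: 1 / 9, 5: 4 / 9})
        assert p[5] == pytest.approx(0.444, abs=5e-4)

    def test_single_neighbor_is_point_mass(self, toy):
        assert neighbor_probabilities(toy, 1) == {2: 1.0}

    def test_equal_degree_neighbors_uniform(self):
        g = cycle(6)
        p = neighbor_probabilities(g, 0)
        assert list(p.values()) == pytest.approx([0.5, 0.5])

    def test_isolated_node_errors(self):
        g = Graph([(1, 2)], nodes=[1, 2, 3])
        with pytest.raises(ValueError, match="isolated"):
            neighbor_probabilities(g, 3)

    def test_probabilities_sum_to_one(self, toy):
        for v in toy.nodes:
            assert sum(neighbor_probabilities(toy, v).values()) == pytest.approx(1, abs=1e-12)

    def test_entropy_toy_values(self, toy):
        assert node_entropy(toy, 2) == pytest.approx(1.752, abs=5e-3)
        assert node_entropy(toy, 1) == 0.0

    def test_entropy_uniform_neighbors_is_log2_k(self):
        g = cycle(8)
        assert node_entropy(g, 0) == pytest.approx(1.0)
        k5 = complete(5)
        assert node_entropy(k5, 0) == pytest.approx(math.log2(4))

    def test_entropy_degree_zero_is_zero(self):
        g = Graph([(1, 2)], nodes=[1, 2, 3])
        assert node_entropy(g, 3) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_entropy_bounds_random_graphs(self, seed):
        g = make_er(30, 0.15, seed=seed)
        for v in g.nodes:
            e = node_entropy(g, v)
            deg = g.degree(v)
            assert 0.0 <= e <= math.log2(max(deg, 1)) + 1e-12
            assert e == pytest.approx(entropy_brute(g, v), abs=1e-12)
            if deg >= 2:
                uniform = len({g.degree(u) for u in g.neighbors(v)}) == 1
                assert (abs(e - math.log2(deg)) < 1e-12) == uniform


class TestEDDC:
    def test_aggregate_zero_entropy(self):
        assert eddc_aggregate(1, 2, 0.0, [(0.0, 1.0)]) == 0.0

    def test_aggregate_star_hand_value(self):
        got = eddc_aggregate(2, 3, 1.0, [(0.0, 1.0), (0.0, 1.0)])
        assert got == pytest.approx(4 / 3)

    def test_aggregate_infinite_distance_contributes_zero(self):
        assert eddc_aggregate(1, 4, 1.0, [(1.0, 1.0), (1.0, math.inf)]) == pytest.approx(
            math.sqrt(2) / 4
        )

    def test_aggregate_negative_entropy_errors(self):
        with pytest.raises(ValueError, match="non-negative"):
            eddc_aggregate(1, 2, -0.1, [])
        with pytest.raises(ValueError, match="non-negative"):
            eddc_aggregate(1, 2, 0.1, [(-1.0, 1.0)])

    def test_k2_scores_zero(self):
        assert eddc(Graph([(1, 2)])).scores == {1: 0.0, 2: 0.0}

    def test_complete_graph_symmetric(self):
        scores = list(eddc(complete(6)).scores.values())
        assert scores == pytest.approx([scores[0]] * 6)

    def test_matches_naive_oracle(self):
        g = make_er(30, 0.15, seed=9)
        assert eddc(g).scores == pytest.approx(eddc_naive(g), abs=1e-9)

    def test_isolated_node_scores_zero(self):
        g = Graph([(1, 2), (2, 3)], nodes=[1, 2, 3, 4])
        assert eddc(g).scores[4] == 0.0

    def test_relabeling_invariance(self):
        g = make_er(20, 0.2, seed=12)
        perm = {v: f"n{(v * 7) % 20}" for v in g.nodes}
        h = Graph(
            [(perm[u], perm[v]) for u, v in g.edges()],
            nodes=[perm[v] for v in g.nodes],
        )
        for fn in (closeness_centrality, lgc, clgc, eclgc, eddc):
            a = fn(g).scores
            b = fn(h).scores
            assert {perm[v]: s for v, s in a.items()} == pytest.approx(b, abs=1e-9)

    def test_vertex_transitive_graphs_constant(self):
        for g in (cycle(8), complete(5)):
            for name in ("dc", "bc", "cc", "clc", "lgc", "kshell", "clgc", "eclgc", "eddc"):
                vals = list(compute_method(g, name).scores.values())
                assert vals == pytest.approx([vals[0]] * g.N), name


class TestRanking:
    def test_rank_order_and_ties(self):
        r = rank_nodes(ScoreTable("t", {"a": 2.0, "b": 1.0, "c": 3.0}))
        assert r.nodes == ("c", "a", "b")
        r = rank_nodes(ScoreTable("t", {"b": 1.0, "c": 1.0, "a": 1.0}))
        assert r.nodes == ("a", "b", "c")
        assert r.ranks == {"a": 1, "b": 2, "c": 3}

    @given(st.lists(st.integers(-10**6, 10**6), min_size=2, max_size=40, unique=True))
    def test_rank_permutation_round_trip(self, scores):
        scores = [float(s) for s in scores]  # distinct after the rounding rule
        labels = list(range(len(scores)))
        table = ScoreTable("t", dict(zip(labels, scores)))
        r = rank_nodes(table)
        assert sorted(r.nodes) == labels
        by_rank = [table.scores[v] for v in r.nodes]
        assert by_rank == sorted(scores, reverse=True)
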