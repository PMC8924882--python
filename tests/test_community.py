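import numpy as np
import pytest

from coexnet.community import (
    assign_all_transcripts,
    kruskal_msf,
    louvain,
    modularity,
)
from coexnet.graph import WeightedEdgeList

from _oracles import max_modularity, min_forest_weight, modularity_direct, n_components


def edge_list(n, triples, threshold=1.0):
    """Build a WeightedEdgeList from (u, v, distance) triples."""
    if triples:
        u, v, d = (np.asarray(x) for x in zip(*triples))
    else:
        u = v = np.empty(0, dtype=np.intp)
        d = np.empty(0)
    return WeightedEdgeList(
        n_vertices=n,
        u=u.astype(np.intp),
        v=v.astype(np.intp),
        corr=1.0 - np.asarray(d, dtype=float),
        distance=np.asarray(d, dtype=float),
        threshold=threshold,
    )


def random_graph(rng, max_n=7, p=0.5):
    n = int(rng.integers(2, max_n + 1))
    triples = [
        (i, j, float(rng.uniform(0.01, 1.0)))
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    ]
    return n, triples


class TestKruskal:
    def test_triangle(self):
        forest = kruskal_msf(edge_list(3, [(0, 1, 0.01), (1, 2, 0.02), (0, 2, 0.03)]))
        got = set(zip(forest.u.tolist(), forest.v.tolist()))
        assert got == {(0, 1), (1, 2)}
        assert forest.total_weight == pytest.approx(0.03)

    def test_tree_input_identity(self):
        triples = [(0, 1, 0.5), (1, 2, 0.2), (2, 3, 0.9)]
        forest = kruskal_msf(edge_list(4, triples))
        assert set(zip(forest.u.tolist(), forest.v.tolist())) == {
            (0, 1), (1, 2), (2, 3)
        }

    def test_two_disjoint_triangles(self):
        triples = [
            (0, 1, 0.1), (1, 2, 0.2), (0, 2, 0.3),
            (3, 4, 0.1), (4, 5, 0.2), (3, 5, 0.3),
        ]
        forest = kruskal_msf(edge_list(6, triples))
        assert forest.n_edges == 4
        assert forest.n_components == 2
        assert forest.total_weight == pytest.approx(0.6)

    def test_empty_edge_list(self):
        forest = kruskal_msf(edge_list(4, []))
        assert forest.n_edges == 0
        assert forest.n_components == 4

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_minimum(self, seed):
        rng = np.random.default_rng(seed)
        n, triples = random_graph(rng)
        forest = kruskal_msf(edge_list(n, triples))
        assert forest.n_edges == n - n_components(n, triples)
        expected = min_forest_weight(n, triples)
        if forest.n_edges:
            assert forest.total_weight == pytest.approx(expected, abs=1e-12)

    def test_tie_break_deterministic_on_ids(self):
        # all weights equal: the forest must still be uniquely defined
        triples = [(0, 1, 0.5), (0, 2, 0.5), (1, 2, 0.5)]
        ids = ["b", "a", "c"]
        forest = kruskal_msf(edge_list(3, triples), ids)
        got = set(zip(forest.u.tolist(), forest.v.tolist()))
        # sorted by (weight, u_id, v_id): ("a","c") from (1,2) comes before
        # ("b","a")=(0,1) and ("b","c")=(0,2); (1,2) then (0,1) span the graph
        assert got == {(1, 2), (0, 1)}


def two_clique_bridge(a, b):
    """Two cliques of sizes a and b joined by one bridge edge."""
    triples = []
    for i in range(a):
        for j in range(i + 1, a):
            triples.append((i, j, 1.0))
    for i in range(b):
        for j in range(i + 1, b):
            triples.append((a + i, a + j, 1.0))
    triples.append((a - 1, a, 1.0))
    return a + b, triples


class TestLouvain:
    def test_edgeless_graph_singletons(self):
        res = louvain(5, [], [], [], seed=1)
        assert sorted(res.labels.tolist()) == [0, 1, 2, 3, 4]
        assert res.modularity == 0.0

    def test_two_triangle_bridge_exact(self):
        n, triples = two_clique_bridge(3, 3)
        u, v, w = zip(*triples)
        res = louvain(n, u, v, w, seed=1)
        # the two cliques are the optimal communities, Q = 5/14
        assert len(set(res.labels[:3])) == 1
        assert len(set(res.labels[3:])) == 1
        assert res.labels[0] != res.labels[3]
        assert res.modularity == pytest.approx(5 / 14, abs=1e-12)

    def test_path_graph_matches_exhaustive(self):
        # path of 5 vertices / 4 unit edges, an MST-like shape
        triples = [(i, i + 1, 1.0) for i in range(4)]
        u, v, w = zip(*triples)
        res = louvain(5, u, v, w, seed=1)
        q_opt, _ = max_modularity(5, triples)
        assert res.modularity == pytest.approx(q_opt, abs=1e-9)

    @pytest.mark.parametrize("k,size", [(2, 3), (3, 4), (4, 3)])
    def test_disjoint_cliques_recovered(self, k, size):
        triples = []
        for c in range(k):
            off = c * size
            for i in range(size):
                for j in range(i + 1, size):
                    triples.append((off + i, off + j, 1.0))
        u, v, w = zip(*triples)
        res = louvain(k * size, u, v, w, seed=3)
        labels = res.labels
        for c in range(k):
            block = labels[c * size : (c + 1) * size]
            assert len(set(block.tolist())) == 1
        assert len(set(labels.tolist())) == k

    def test_same_seed_identical(self):
        rng = np.random.default_rng(11)
        n, triples = random_graph(rng, max_n=30, p=0.2)
        u, v, w = zip(*triples)
        a = louvain(n, u, v, w, seed=9)
        b = louvain(n, u, v, w, seed=9)
        assert np.array_equal(a.labels, b.labels)
        assert a.modularity == b.modularity

    def test_final_q_not_below_singleton_q(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n, triples = random_graph(rng, max_n=12, p=0.4)
            if not triples:
                continue
            u, v, w = zip(*triples)
            res = louvain(n, u, v, w, seed=seed)
            q_singleton = modularity_direct(n, triples, list(range(n)))
            assert res.modularity >= q_singleton - 1e-12

    def test_seed_stability_on_planted_benchmark(self, sim_benchmark):
        """Different seeds may move nodes but the achieved modularity is
        stable (spread < 0.05 over 20 seeds) on a planted-module forest."""
        from coexnet.graph import build_edges

        edges = build_edges(sim_benchmark.matrix.values, 0.1)
        forest = kruskal_msf(edges, sim_benchmark.matrix.transcript_ids)
        w = 1.0 - forest.weight
        qs = [
            louvain(edges.n_vertices, forest.u, forest.v, w, seed=s).modularity
            for s in range(20)
        ]
        assert max(qs) - min(qs) < 0.05

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            louvain(2, [0], [1], [-0.5], seed=1)

    def test_isolated_vertices_are_singletons(self):
        res = louvain(4, [0], [1], [1.0], seed=1)
        assert res.labels[0] == res.labels[1]
        assert len({res.labels[2], res.labels[3], res.labels[0]}) == 3


class TestModularity:
    def test_single_community_is_zero(self):
        n, triples = two_clique_bridge(3, 3)
        u, v, w = zip(*triples)
        assert modularity(n, u, v, w, [0] * n) == pytest.approx(0.0, abs=1e-15)

    def test_clique_partition_value(self):
        n, triples = two_clique_bridge(3, 3)
        u, v, w = zip(*triples)
        labels = [0, 0, 0, 1, 1, 1]
        assert modularity(n, u, v, w, labels) == pytest.approx(5 / 14, abs=1e-15)

    def test_singleton_partition_nonpositive(self):
        rng = np.random.default_rng(2)
        n, triples = random_graph(rng, max_n=10, p=0.6)
        if not triples:
            triples = [(0, 1, 0.5)]
        u, v, w = zip(*triples)
        assert modularity(n, u, v, w, list(range(n))) <= 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_networkx(self, seed):
        import networkx as nx

        rng = np.random.default_rng(seed)
        n, triples = random_graph(rng, max_n=12, p=0.5)
        if not triples:
            return
        u, v, w = zip(*triples)
        labels = rng.integers(0, 3, n)
        G = nx.Graph()
        G.add_nodes_from(range(n))
        G.add_weighted_edges_from(triples)
        comms = [set(np.flatnonzero(labels == c)) for c in np.unique(labels)]
        comms = [c for c in comms if c]
        expected = nx.community.modularity(G, comms, weight="weight")
        assert modularity(n, u, v, w, labels) == pytest.approx(expected, abs=1e-12)

    def test_unassigned_vertex_errors(self):
        with pytest.raises(ValueError, match="assigned"):
            modularity(3, [0], [1], [1.0], [0, 1])


class TestAssignAllTranscripts:
    def test_appends_excluded_as_singletons(self):
        labels = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2, 2])  # 10 graph vertices
        ids = [f"t{i}" for i in range(12)]
        part = assign_all_transcripts(
            labels, [10, 11], ids, modularity=0.3, seed=1, weighting_mode="similarity"
        )
        assert part.n_modules == 5
        assert len(part.transcript_ids) == 12
        sizes = sorted(part.module_sizes().tolist())
        assert sizes == [1, 1, 3, 3, 4]

    def test_no_excluded_only_densifies(self):
        labels = np.array([7, 7, 3, 3])
        part = assign_all_transcripts(
            labels, [], ["a", "b", "c", "d"],
            modularity=0.0, seed=1, weighting_mode="similarity",
        )
        assert part.labels.tolist() == [0, 0, 1, 1]

    def test_all_excluded_all_singletons(self):
        part = assign_all_transcripts(
            np.empty(0, dtype=int), [0, 1, 2], ["a", "b", "c"],
            modularity=0.0, seed=1, weighting_mode="similarity",
        )
        assert part.labels.tolist() == [0, 1, 2]
        assert part.n_modules == 3
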