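import itertools

import numpy as np
import pytest

from _oracles import brute_force_sparse, kl_by_integration, map_equation
from siambin import graph as gr
from siambin.types import Bin, MarkerHit


class TestKlNormal:
    def test_identical_distributions(self):
        assert gr.kl_normal(10.0, 4.0, 10.0, 4.0) == pytest.approx(0.0, abs=1e-12)

    def test_unit_shift_hand_value(self):
        # KL(N(0,1) || N(1,1)) = 1/2 in both directions
        assert gr.kl_normal(0.0, 1.0, 1.0, 1.0) == pytest.approx(0.5, abs=1e-9)

    def test_symmetry(self):
        assert gr.kl_normal(3.0, 2.0, 7.0, 5.0) == pytest.approx(
            gr.kl_normal(7.0, 5.0, 3.0, 2.0)
        )

    def test_matches_numerical_integration(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            m1, m2 = rng.uniform(0.5, 50.0, size=2)
            v1, v2 = rng.uniform(0.5, 30.0, size=2)
            expected = 0.5 * (
                kl_by_integration(m1, v1, m2, v2) + kl_by_integration(m2, v2, m1, v1)
            )
            assert gr.kl_normal(m1, v1, m2, v2) == pytest.approx(expected, abs=1e-6)

    def test_multi_sample_mean(self):
        one = gr.kl_normal(0.0, 1.0, 1.0, 1.0)
        two = gr.kl_normal([0.0, 0.0], [1.0, 1.0], [1.0, 0.0], [1.0, 1.0])
        assert two == pytest.approx(one / 2)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            gr.kl_normal(np.nan, 1.0, 0.0, 1.0)


class TestPairSimilarity:
    def test_zero_distance_is_full_similarity(self):
        assert gr.pair_similarity(0.0, 0.9, 1) == 1.0
        assert gr.pair_similarity(0.0, None, 5) == 1.0

    def test_distance_cap(self):
        assert gr.pair_similarity(2.0, None, 5) == 0.0

    def test_abundance_multiplier(self):
        assert gr.pair_similarity(0.5, 0.8, 1) == pytest.approx(0.6)

    def test_abundance_required_below_five_samples(self):
        with pytest.raises(ValueError):
            gr.pair_similarity(0.5, None, 3)


class TestSparseGraph:
    def test_small_graph_keeps_everything(self):
        sim = np.array([[0, 0.5, 0.4], [0.5, 0, 0.3], [0.4, 0.3, 0]])
        g = gr.build_sparse_graph(["a", "b", "c"], sim, max_edges=200)
        assert len(g.edges) == 3

    def test_union_of_nominations_can_exceed_max_edges(self):
        # star: hub "a" similar to everyone; spokes dissimilar to each other
        ids = ["a", "b", "c", "d", "e"]
        sim = np.full((5, 5), 0.01)
        sim[0, 1:] = sim[1:, 0] = [0.9, 0.8, 0.7, 0.6]
        np.fill_diagonal(sim, 0)
        g = gr.build_sparse_graph(ids, sim, max_edges=1)
        # each spoke nominates the hub; hub nominates only b
        assert set(g.edges) == {(0, 1), (0, 2), (0, 3), (0, 4)}
        degree_a = sum(1 for (i, j) in g.edges if 0 in (i, j))
        assert degree_a == 4 > 1

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 31))
        sim = rng.uniform(0, 1, size=(n, n))
        sim = (sim + sim.T) / 2
        sim[sim < 0.2] = 0.0  # exercise zero-weight dropping
        np.fill_diagonal(sim, 0)
        ids = [f"n{i:02d}" for i in range(n)]
        k = int(rng.integers(1, 6))
        g = gr.build_sparse_graph(ids, sim, max_edges=k)
        assert g.edges == brute_force_sparse(ids, sim, k)

    def test_weights_match_similarity(self):
        rng = np.random.default_rng(5)
        sim = rng.uniform(0.1, 1, size=(6, 6))
        sim = (sim + sim.T) / 2
        np.fill_diagonal(sim, 0)
        ids = list("abcdef")
        g = gr.build_sparse_graph(ids, sim, max_edges=3)
        for (i, j), w in g.edges.items():
            assert w == pytest.approx(sim[i, j])


class TestIntersect:
    def _graph(self, ids, edges):
        return gr.SimilarityGraph(nodes=ids, edges=dict(edges))

    def test_identity(self):
        ids = ["a", "b", "c"]
        g = self._graph(ids, {(0, 1): 0.5, (1, 2): 0.4})
        out = gr.intersect_graphs(g, self._graph(ids, {(0, 1): 0.9, (1, 2): 0.1}))
        assert out.edges == g.edges  # weights from the first graph

    def test_disjoint_edge_sets(self):
        ids = ["a", "b", "c"]
        out = gr.intersect_graphs(
            self._graph(ids, {(0, 1): 0.5}), self._graph(ids, {(1, 2): 0.5})
        )
        assert out.edges == {}

    def test_node_mismatch_rejected(self):
        with pytest.raises(ValueError):
            gr.intersect_graphs(
                self._graph(["a"], {}), self._graph(["b"], {})
            )

    @pytest.mark.parametrize("seed", range(5))
    def test_random_graphs_match_set_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        ids = [f"n{i}" for i in range(10)]
        all_pairs = list(itertools.combinations(range(10), 2))

        def random_edges():
            chosen = rng.random(len(all_pairs)) < 0.4
            return {p: float(rng.uniform(0.1, 1)) for p, c in zip(all_pairs, chosen) if c}

        e1, e2 = random_edges(), random_edges()
        out = gr.intersect_graphs(self._graph(ids, e1), self._graph(ids, e2))
        assert set(out.edges) == set(e1) & set(e2)


class TestPartition:
    def _clique_graph(self, sizes, bridge_weight=None):
        ids = []
        edges = {}
        offset = 0
        blocks = []
        for s in sizes:
            block = [f"n{offset + i:02d}" for i in range(s)]
            ids.extend(block)
            for i, j in itertools.combinations(range(s), 2):
                edges[(offset + i, offset + j)] = 1.0
            blocks.append(block)
            offset += s
        if bridge_weight is not None:
            edges[(0, sizes[0])] = bridge_weight
        return gr.SimilarityGraph(nodes=ids, edges=edges), blocks

    def test_disconnected_cliques_recovered_exactly(self):
        g, blocks = self._clique_graph([5, 5])
        assert gr.partition(g, rng_seed=0) == [sorted(b) for b in blocks]

    def test_weak_bridge_split_matches_exhaustive_map_equation(self):
        g, blocks = self._clique_graph([6, 6], bridge_weight=0.01)
        nodes = g.nodes
        named_edges = {
            (nodes[i], nodes[j]): w for (i, j), w in g.edges.items()
        }
        best, best_L = None, np.inf
        for mask in range(1, 2 ** (len(nodes) - 1)):  # node 0 fixed in module A
            a = [nodes[0]] + [v for k, v in enumerate(nodes[1:]) if mask >> k & 1]
            b = [v for k, v in enumerate(nodes[1:]) if not mask >> k & 1]
            if not b:
                continue
            L = map_equation(nodes, named_edges, [a, b])
            if L < best_L:
                best, best_L = (sorted(a), sorted(b)), L
        assert set(map(tuple, best)) == {tuple(sorted(b)) for b in blocks}
        result = gr.partition(g, rng_seed=0)
        assert {tuple(c) for c in result} == set(map(tuple, best))
        # and the two-module score beats the trivial single-module one
        one_module = map_equation(nodes, named_edges, [list(nodes)])
        assert best_L <= one_module

    def test_empty_edge_set_gives_singletons(self):
        g = gr.SimilarityGraph(nodes=["a", "b", "c"])
        assert gr.partition(g, rng_seed=0) == [["a"], ["b"], ["c"]]

    def test_deterministic_under_seed(self):
        g, _ = self._clique_graph([4, 4], bridge_weight=0.5)
        assert gr.partition(g, rng_seed=3) == gr.partition(g, rng_seed=3)


class TestBinsAndRecluster:
    def test_mean_scg_count(self):
        hits = [MarkerHit("c1", "m1"), MarkerHit("c2", "m1"), MarkerHit("c1", "m2")]
        bins = gr.make_bins(
            [["c1", "c2"]], {"c1": 1000, "c2": 2000}, hits
        )
        assert bins[0].total_bp == 3000
        assert bins[0].mean_scg_count == pytest.approx(3 / 2)  # 3 hits, panel of 2

    def test_clean_bin_passes_through(self):
        b = Bin("b0", ["c1"], 1000, mean_scg_count=1.0)
        out = gr.recluster_bin(b, [], {}, {}, {"c1": 1000})
        assert out == [b]

    def test_duplicated_marker_splits_planted_genomes(self):
        rng = np.random.default_rng(6)
        ids = [f"g{g}_c{i}" for g in (0, 1) for i in range(8)]
        centers = {0: np.zeros(4), 1: np.full(4, 3.0)}
        embeddings = {
            cid: centers[int(cid[1])] + rng.normal(scale=0.3, size=4) for cid in ids
        }
        abundance = {cid: np.array([0.2 + 0.3 * int(cid[1])]) for cid in ids}
        lengths = {cid: 10_000 for cid in ids}
        hits = [MarkerHit("g0_c0", "m1"), MarkerHit("g1_c0", "m1")]
        b = Bin("b0", ids, sum(lengths.values()), mean_scg_count=2.0)
        out = gr.recluster_bin(b, hits, embeddings, abundance, lengths)
        assert len(out) == 2
        groups = [{cid[:2] for cid in x.contig_ids} for x in out]
        assert groups == [{"g0"}, {"g1"}] or groups == [{"g1"}, {"g0"}]

    def test_inconsistent_marker_evidence_rejected(self):
        b = Bin("b0", ["c1", "c2"], 2000, mean_scg_count=1.5)
        hits = [MarkerHit("c1", "m1"), MarkerHit("c2", "m2")]  # no duplication
        with pytest.raises(ValueError, match="duplicated"):
            gr.recluster_bin(b, hits, {}, {}, {"c1": 1000, "c2": 1000})

    def test_filter_small_bins_boundary(self):
        bins = [
            Bin("a", ["c1"], 199_999),
            Bin("b", ["c2"], 200_000),
        ]
        assert gr.filter_small_bins(bins) == [bins[1]]
        assert gr.filter_small_bins([]) == []
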