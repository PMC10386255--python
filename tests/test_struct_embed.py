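"""Structural embedding chain: degree sequences, DTW, distances,
multilayer graph, walks, skip-gram."""

import itertools

import networkx as nx
import numpy as np
import pytest

import drivnet as dn
from drivnet.net_io import GeneNetwork
from drivnet.struct_embed import (
    DEGREE_SHIFT,
    jump_up_probability,
    layer_transition_probs,
)

from conftest import cosine_matrix


def dtw_bruteforce(a, b):
    """Independent oracle: minimum over all monotone alignment paths."""
    def cost(u, v):
        return max(u, v) / min(u, v) - 1.0

    best = [np.inf]

    def walk(i, j, acc):
        acc = acc + cost(a[i], b[j])
        if acc >= best[0]:
            return
        if i == len(a) - 1 and j == len(b) - 1:
            best[0] = acc
            return
        for di, dj in ((1, 0), (0, 1), (1, 1)):
            ni, nj = i + di, j + dj
            if ni < len(a) and nj < len(b):
                walk(ni, nj, acc)

    walk(0, 0, 0.0)
    return best[0]


STAR = GeneNetwork.from_edges([("C", "L1"), ("C", "L2"), ("C", "L3")])


class TestDegreeSequences:
    def test_star_leaf_hop_sequences(self):
        table = dn.degree_sequences(STAR, k_max=3)
        i = table.node_ids.index("L1")
        assert table.seqs[i][0].tolist() == [1.0]
        assert table.seqs[i][1].tolist() == [3.0]
        assert table.seqs[i][2].tolist() == [1.0, 1.0]
        assert table.seqs[i][3].size == 0  # beyond eccentricity

    def test_hop_zero_is_own_degree(self):
        table = dn.degree_sequences(STAR, k_max=1)
        c = table.node_ids.index("C")
        assert table.seqs[c][0].tolist() == [3.0]

    def test_sequences_sorted_nondecreasing(self):
        net = dn.make_scale_free(40, 2, seed=1)
        table = dn.degree_sequences(net, k_max=3)
        for seqs in table.seqs:
            for s in seqs:
                assert (np.diff(s) >= 0).all()


class TestDtwCost:
    @pytest.mark.parametrize("a,b,expected", [
        ([2], [2], 0.0),
        ([1], [4], 3.0),                       # 4/1 - 1
        ([1, 2], [2], 1.0),                    # (2/1-1) + (2/2-1)
    ])
    def test_known_values(self, a, b, expected):
        assert dn.dtw_cost(a, b) == pytest.approx(expected, abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.integers(1, 9, rng.integers(1, 6)).tolist()
            b = rng.integers(1, 9, rng.integers(1, 6)).tolist()
            assert dn.dtw_cost(a, b) == pytest.approx(dn.dtw_cost(b, a), abs=1e-12)

    def test_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a = rng.integers(1, 9, rng.integers(1, 7)).tolist()
            b = rng.integers(1, 9, rng.integers(1, 7)).tolist()
            assert dn.dtw_cost(a, b) == pytest.approx(dtw_bruteforce(a, b), abs=1e-12)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            dn.dtw_cost([], [1])


class TestStructuralDistance:
    def test_star_leaves_identical(self):
        table = dn.degree_sequences(STAR, k_max=2)
        for k in range(3):
            assert dn.structural_distance(table, "L1", "L2", k) == 0.0

    def test_self_distance_zero(self):
        table = dn.degree_sequences(STAR, k_max=2)
        assert dn.structural_distance(table, "C", "C", 2) == 0.0

    def test_six_node_graph_matches_manual_recomputation(self):
        # path A-B-C-D plus triangle edge B-C-E: varied degrees
        net = GeneNetwork.from_edges(
            [("A", "B"), ("B", "C"), ("C", "D"), ("B", "E"), ("C", "E"), ("E", "F")])
        g = net.to_networkx()
        table = dn.degree_sequences(net, k_max=2)

        def manual_f(x, y, k):
            total = 0.0
            for layer in range(k + 1):
                sx = sorted(g.degree(u) + DEGREE_SHIFT
                            for u, d in nx.single_source_shortest_path_length(g, x).items()
                            if d == layer)
                sy = sorted(g.degree(u) + DEGREE_SHIFT
                            for u, d in nx.single_source_shortest_path_length(g, y).items()
                            if d == layer)
                total += dtw_bruteforce(sx, sy)
            return total

        for x, y in [("A", "D"), ("A", "F"), ("B", "C"), ("D", "F")]:
            for k in (0, 1):
                assert dn.structural_distance(table, x, y, k) == pytest.approx(
                    manual_f(x, y, k), abs=1e-9)

    def test_table_symmetric_and_monotone_in_k(self, twins_bundle):
        fk = twins_bundle["dist"].fk
        for k in range(fk.shape[0]):
            layer = fk[k]
            finite = np.isfinite(layer)
            assert (finite == finite.T).all()
            assert np.allclose(layer[finite], layer.T[finite.T])
        both = np.isfinite(fk[:-1]) & np.isfinite(fk[1:])
        assert (fk[1:][both] >= fk[:-1][both] - 1e-12).all()


class TestMultilayer:
    def test_weights_in_unit_interval_and_one_iff_zero_distance(self, twins_bundle):
        mlg = twins_bundle["mlg"]
        dist = twins_bundle["dist"]
        for k in range(mlg.k_star + 1):
            w = mlg.weights[k]
            pos = w > 0
            assert (w[pos] <= 1 + 1e-15).all()
            ones = np.isclose(w, 1.0) & pos
            assert (dist.fk[k][ones] == 0).all()

    def test_weight_monotone_decreasing_in_distance(self):
        f = np.linspace(0, 5, 20)
        w = np.exp(-f)
        assert (np.diff(w) < 0).all()

    def test_gamma_zero_gives_unit_up_weight(self, twins_bundle):
        mlg = twins_bundle["mlg"]
        for k in range(mlg.k_star):
            mask = (mlg.gamma[k] == 0) & (mlg.up_weight[k] > 0)
            assert np.allclose(mlg.up_weight[k][mask], 1.0)  # log(e)


class TestWalks:
    def test_transition_probabilities_normalized(self, twins_bundle):
        mlg = twins_bundle["mlg"]
        for k in range(mlg.k_star + 1):
            for i in range(len(mlg.node_ids)):
                nbr, p = layer_transition_probs(mlg, k, i)
                if nbr.size:
                    assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_equal_distances_give_uniform_choice(self):
        # triangle: all pairwise f = 0, two neighbors each with p = 1/2
        net = GeneNetwork.from_edges([("A", "B"), ("B", "C"), ("A", "C")])
        table = dn.degree_sequences(net, k_max=1)
        dist = dn.structural_distances(table, k_star=1)
        mlg = dn.build_multilayer(dist)
        _, p = layer_transition_probs(mlg, 0, 0)
        assert np.allclose(p, [0.5, 0.5])

    def test_jump_probabilities_sum_to_one(self, twins_bundle):
        mlg = twins_bundle["mlg"]
        for k in range(1, mlg.k_star + 1):
            for i in range(len(mlg.node_ids)):
                if mlg.in_layer[k, i]:
                    up = jump_up_probability(mlg, k, i)
                    assert 0.0 <= up <= 1.0
                    assert up + (1.0 - up) == 1.0

    def test_corpus_reproducible_and_token_domain(self, twins_bundle):
        mlg = twins_bundle["mlg"]
        c1 = dn.sample_walks(mlg, num_walks=2, walk_length=10, seed=5)
        c2 = dn.sample_walks(mlg, num_walks=2, walk_length=10, seed=5)
        assert c1.walks == c2.walks
        assert len(c1.walks) == 2 * len(mlg.node_ids)
        nodes = set(mlg.node_ids)
        assert all(tok in nodes for w in c1.walks for tok in w)
        assert all(len(w) <= 10 for w in c1.walks)

    def test_different_seeds_differ(self, twins_bundle):
        mlg = twins_bundle["mlg"]
        c1 = dn.sample_walks(mlg, num_walks=1, walk_length=20, seed=5)
        c2 = dn.sample_walks(mlg, num_walks=1, walk_length=20, seed=6)
        assert c1.walks != c2.walks


class TestSkipgram:
    def test_deterministic_given_seed(self, twins_bundle):
        mlg = twins_bundle["mlg"]
        corpus = dn.sample_walks(mlg, num_walks=2, walk_length=20, seed=5)
        e1 = dn.train_skipgram(corpus, dim=16, epochs=2, seed=9)
        e2 = dn.train_skipgram(corpus, dim=16, epochs=2, seed=9)
        assert e1.gene_ids == e2.gene_ids
        assert (e1.vectors == e2.vectors).all()

    def test_every_corpus_node_embedded_at_requested_dim(self, twins_bundle):
        emb = twins_bundle["emb"]
        assert emb.dim == 128
        assert set(emb.gene_ids) == set(twins_bundle["net"].nodes)

    def test_counterparts_more_similar_than_random(self, twins_bundle):
        S, idx = cosine_matrix(twins_bundle["emb"])
        cp = [S[idx[a], idx[b]] for a, b in twins_bundle["pairs"]]
        tri = S[np.triu_indices_from(S, k=1)]
        assert np.median(cp) > np.median(tri) + 0.3


class TestLabelInvariance:
    def test_order_preserving_relabel_preserves_similarity(self):
        # structural methods must ignore node identity: renaming every gene
        # (order-preserving so seeded walk streams align) leaves the cosine
        # similarity matrix unchanged
        net, _ = dn.make_structural_twins(seed=1)
        emb1 = dn.embed_network(net, dim=16, num_walks=4, walk_length=20, epochs=2, seed=3)
        relabeled = GeneNetwork.from_edges(
            (f"X{a}", f"X{b}") for a, b in net.edges)
        emb2 = dn.embed_network(relabeled, dim=16, num_walks=4, walk_length=20, epochs=2, seed=3)
        S1, idx1 = cosine_matrix(emb1)
        S2, idx2 = cosine_matrix(emb2)
        genes = sorted(emb1.gene_ids)
        perm1 = [idx1[g] for g in genes]
        perm2 = [idx2[f"X{g}"] for g in genes]
        assert np.allclose(S1[np.ix_(perm1, perm1)], S2[np.ix_(perm2, perm2)])
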