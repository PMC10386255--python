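"""Structural gene embeddings (struc2vec-style) for the mutation
integration network.

The chain implemented here:

1. For every gene x and hop distance k, collect the ordered (non-decreasing)
   degree sequence s(R_k(x)) of the nodes at exactly distance k from x.
2. Compare sequences pairwise with exact dynamic time warping under the
   element cost c(u, v) = max(u, v)/min(u, v) - 1, accumulating the
   per-layer costs into a cumulative structural distance
   f_k(x, y) = f_{k-1}(x, y) + g(s(R_k(x)), s(R_k(y))), f_{-1} = 0.
3. Build a multilayer graph: one layer per hop depth, intra-layer weight
   w_k(x, y) = exp(-f_k(x, y)); a node connects to its own copy one layer
   up with weight log(Gamma_k(x) + e) (Gamma_k = number of its intra-layer
   edges heavier than the layer's mean weight) and one layer down with
   weight 1.
4. Sample biased random walks: stay in the current layer with probability
   q, stepping to y with probability exp(-f_k(x, y)) / Z_k(x); otherwise
   jump up/down proportionally to the inter-layer weights. Walk tokens are
   gene identities with the layer index stripped.
5. Train a skip-gram model (hierarchical softmax, single-threaded, fully
   seeded) on the walk corpus to obtain one d-dimensional vector per gene.

Because the distances depend only on degree sequences, two genes that are
far apart (even in different connected components) but locally isomorphic
get f_k = 0 and end up with near-identical embeddings — the property the
framework uses to find long-distance structurally similar gene pairs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
from numba import njit

from .net_io import EmbeddingTable, GeneNetwork

log = logging.getLogger("drivnet")

__all__ = [
    "DegreeSequenceTable",
    "StructuralDistanceTable",
    "MultilayerGraph",
    "WalkCorpus",
    "degree_sequences",
    "dtw_cost",
    "structural_distance",
    "structural_distances",
    "build_multilayer",
    "sample_walks",
    "train_skipgram",
    "embed_network",
]

DEFAULT_K_CAP = 6
DEFAULT_NUM_WALKS = 20
DEFAULT_WALK_LENGTH = 80
DEFAULT_STAY_PROB = 0.7
DEFAULT_DIM = 128
DEFAULT_WINDOW = 10
DEFAULT_EPOCHS = 5
DEGREE_SHIFT = 1.0  # added to degrees before the max/min ratio (guards degree 0)


# ---------------------------------------------------------------------------
# hop-wise degree sequences
# ---------------------------------------------------------------------------


@dataclass
class DegreeSequenceTable:
    """s(R_k(x)) for every node x and hop k = 0..k_max.

    ``seqs[i][k]`` is the sorted array of degrees of nodes at exactly
    distance k from node i; empty beyond the node's eccentricity.
    ``depth[i]`` is the largest k with a non-empty hop set.
    """

    node_ids: list[str]
    seqs: list[list[np.ndarray]]
    depth: np.ndarray
    k_max: int


def degree_sequences(net: GeneNetwork, k_max: int) -> DegreeSequenceTable:
    """Exact BFS hop sets; each sequence sorted non-decreasing."""
    g = net.to_networkx()
    nodes = sorted(net.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    degs = np.array([g.degree(v) for v in nodes], dtype=np.float64)
    seqs: list[list[np.ndarray]] = []
    depth = np.zeros(len(nodes), dtype=np.int64)
    for v in nodes:
        dist = nx.single_source_shortest_path_length(g, v, cutoff=k_max)
        by_k: list[list[float]] = [[] for _ in range(k_max + 1)]
        for u, d in dist.items():
            by_k[d].append(degs[index[u]])
        node_seqs = [np.sort(np.array(s, dtype=np.float64)) for s in by_k]
        seqs.append(node_seqs)
        depth[index[v]] = max(k for k in range(k_max + 1) if len(node_seqs[k]) > 0)
    return DegreeSequenceTable(node_ids=nodes, seqs=seqs, depth=depth, k_max=k_max)


# ---------------------------------------------------------------------------
# dynamic time warping with ratio cost
# ---------------------------------------------------------------------------


@njit(cache=False)
def _dtw(a: np.ndarray, b: np.ndarray) -> float:
    la, lb = a.shape[0], b.shape[0]
    D = np.empty((la + 1, lb + 1), dtype=np.float64)
    D[0, 0] = 0.0
    for i in range(1, la + 1):
        D[i, 0] = np.inf
    for j in range(1, lb + 1):
        D[0, j] = np.inf
    for i in range(1, la + 1):
        ai = a[i - 1]
        for j in range(1, lb + 1):
            bj = b[j - 1]
            if ai > bj:
                c = ai / bj - 1.0
            else:
                c = bj / ai - 1.0
            best = D[i - 1, j - 1]
            if D[i - 1, j] < best:
                best = D[i - 1, j]
            if D[i, j - 1] < best:
                best = D[i, j - 1]
            D[i, j] = c + best
    return D[la, lb]


def dtw_cost(a, b) -> float:
    """Minimal-cost monotone alignment under c(u, v) = max(u, v)/min(u, v) - 1.

    Sequences must be non-empty with strictly positive entries (degree
    sequences are shifted by +1 upstream before reaching this cost).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("DTW is undefined for empty sequences")
    if (a <= 0).any() or (b <= 0).any():
        raise ValueError("DTW ratio cost needs strictly positive entries")
    return float(_dtw(a, b))


# ---------------------------------------------------------------------------
# structural distances f_k
# ---------------------------------------------------------------------------


@dataclass
class StructuralDistanceTable:
    """Cumulative structural distances; fk[k, i, j] is NaN where undefined.

    A pair accrues layers only while both hop-k degree sequences are
    non-empty, so fk is non-decreasing in k wherever defined.
    """

    node_ids: list[str]
    fk: np.ndarray  # (k_star + 1, n, n)
    k_star: int


@njit(cache=False)
def _all_pairs_fk(flat: np.ndarray, offsets: np.ndarray, lengths: np.ndarray,
                  depth: np.ndarray, k_star: int, comp: np.ndarray,
                  restrict_components: bool) -> np.ndarray:
    n = depth.shape[0]
    fk = np.full((k_star + 1, n, n), np.nan)
    for k in range(k_star + 1):
        for i in range(n):
            fk[k, i, i] = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if restrict_components and comp[i] != comp[j]:
                continue
            kmax = min(depth[i], depth[j])
            if kmax > k_star:
                kmax = k_star
            cum = 0.0
            for k in range(kmax + 1):
                oa, la = offsets[i, k], lengths[i, k]
                ob, lb = offsets[j, k], lengths[j, k]
                cum += _dtw(flat[oa:oa + la], flat[ob:ob + lb])
                fk[k, i, j] = cum
                fk[k, j, i] = cum
    return fk


def structural_distances(
    table: DegreeSequenceTable,
    k_star: int,
    net: GeneNetwork | None = None,
    mode: str = "global",
) -> StructuralDistanceTable:
    """All-pairs cumulative distances up to layer ``k_star``.

    ``mode="global"`` (default) compares every pair, including pairs in
    different connected components — structural similarity does not require
    connectivity. ``mode="component"`` restricts to within-component pairs
    as an O(sum of component^2) optimization and needs ``net``.
    """
    n = len(table.node_ids)
    if k_star > table.k_max:
        raise ValueError("k_star exceeds the precomputed hop depth")
    # pack ragged sequences (shifted by +1 for the ratio cost) into one array
    offsets = np.zeros((n, k_star + 1), dtype=np.int64)
    lengths = np.zeros((n, k_star + 1), dtype=np.int64)
    chunks: list[np.ndarray] = []
    pos = 0
    for i in range(n):
        for k in range(k_star + 1):
            s = table.seqs[i][k]
            offsets[i, k] = pos
            lengths[i, k] = s.size
            chunks.append(s + DEGREE_SHIFT)
            pos += s.size
    flat = np.concatenate(chunks) if chunks else np.zeros(0)
    comp = np.zeros(n, dtype=np.int64)
    restrict = mode == "component"
    if restrict:
        if net is None:
            raise ValueError("component mode needs the network")
        for ci, cc in enumerate(nx.connected_components(net.to_networkx())):
            for v in cc:
                comp[table.node_ids.index(v)] = ci
    elif mode != "global":
        raise ValueError(f"unknown mode {mode!r}")
    fk = _all_pairs_fk(flat, offsets, lengths, table.depth, k_star, comp, restrict)
    return StructuralDistanceTable(node_ids=list(table.node_ids), fk=fk, k_star=k_star)


def structural_distance(table: DegreeSequenceTable, x: str, y: str, k: int) -> float:
    """f_k(x, y) for one pair: cumulative DTW cost over layers 0..k.

    Raises if either hop set is empty at some layer <= k (the pair simply
    does not exist at that depth).
    """
    i, j = table.node_ids.index(x), table.node_ids.index(y)
    if x == y:
        return 0.0
    cum = 0.0
    for layer in range(k + 1):
        a, b = table.seqs[i][layer], table.seqs[j][layer]
        if a.size == 0 or b.size == 0:
            raise ValueError(f"pair ({x}, {y}) undefined at layer {layer}")
        cum += dtw_cost(a + DEGREE_SHIFT, b + DEGREE_SHIFT)
    return cum


# ---------------------------------------------------------------------------
# multilayer graph
# ---------------------------------------------------------------------------


@dataclass
class MultilayerGraph:
    """k_star + 1 layers; intra-layer weights exp(-f_k); inter-layer edges
    up with weight log(Gamma_k(x) + e) and down with weight 1."""

    node_ids: list[str]
    k_star: int
    weights: np.ndarray      # (k_star + 1, n, n); 0 where no intra-layer edge
    in_layer: np.ndarray     # (k_star + 1, n) bool
    gamma: np.ndarray        # (k_star + 1, n) int
    up_weight: np.ndarray    # (k_star + 1, n); log(gamma + e) where layer above exists, else 0


def build_multilayer(dist: StructuralDistanceTable, k_star: int | None = None) -> MultilayerGraph:
    if k_star is None:
        k_star = dist.k_star
    if k_star > dist.k_star:
        raise ValueError("k_star exceeds computed distances")
    n = len(dist.node_ids)
    weights = np.zeros((k_star + 1, n, n))
    in_layer = np.zeros((k_star + 1, n), dtype=bool)
    gamma = np.zeros((k_star + 1, n), dtype=np.int64)
    for k in range(k_star + 1):
        fk = dist.fk[k]
        defined = np.isfinite(fk)
        np.fill_diagonal(defined, False)
        w = np.where(defined, np.exp(-np.where(defined, fk, 0.0)), 0.0)
        weights[k] = w
        in_layer[k] = defined.any(axis=1)
        if defined.any():
            mean_w = w[defined].mean()  # each edge counted twice; ratio unchanged
            gamma[k] = ((w > mean_w) & defined).sum(axis=1)
    up_weight = np.zeros((k_star + 1, n))
    for k in range(k_star):
        exists_above = in_layer[k + 1]
        up_weight[k] = np.where(exists_above & in_layer[k], np.log(gamma[k] + math.e), 0.0)
    return MultilayerGraph(
        node_ids=list(dist.node_ids), k_star=k_star,
        weights=weights, in_layer=in_layer, gamma=gamma, up_weight=up_weight,
    )


def layer_transition_probs(mlg: MultilayerGraph, k: int, i: int) -> tuple[np.ndarray, np.ndarray]:
    """Within-layer step distribution from node i in layer k (Z_k-normalized)."""
    w = mlg.weights[k, i]
    nbr = np.flatnonzero(w > 0)
    if nbr.size == 0:
        return nbr, np.zeros(0)
    p = w[nbr] / w[nbr].sum()
    return nbr, p


def jump_up_probability(mlg: MultilayerGraph, k: int, i: int) -> float:
    """P(jump up | jumping) = w_up / (w_up + w_down); down weight 1 for k > 0."""
    w_up = mlg.up_weight[k, i]
    w_down = 1.0 if k > 0 else 0.0
    tot = w_up + w_down
    if tot == 0.0:
        return 0.0  # single-layer node: nowhere to jump
    return w_up / tot


# ---------------------------------------------------------------------------
# biased random walks
# ---------------------------------------------------------------------------


@dataclass
class WalkCorpus:
    walks: list[list[str]]
    num_walks: int
    walk_length: int
    q: float
    seed: int


def sample_walks(
    mlg: MultilayerGraph,
    num_walks: int = DEFAULT_NUM_WALKS,
    walk_length: int = DEFAULT_WALK_LENGTH,
    q: float = DEFAULT_STAY_PROB,
    seed: int = 0,
) -> WalkCorpus:
    """Biased multilayer walks, started at layer 0 of every node.

    Each (node, walk-index) pair gets its own seeded random stream so the
    corpus is reproducible regardless of iteration order. Layer jumps do
    not emit tokens; recorded tokens are gene identities only.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("stay probability q must lie in (0, 1)")
    n = len(mlg.node_ids)
    # precompute per (layer, node): neighbor ids + cumulative probabilities
    cums: list[list[tuple[np.ndarray, np.ndarray] | None]] = []
    for k in range(mlg.k_star + 1):
        row: list[tuple[np.ndarray, np.ndarray] | None] = []
        for i in range(n):
            nbr, p = layer_transition_probs(mlg, k, i)
            row.append((nbr, np.cumsum(p)) if nbr.size else None)
        cums.append(row)
    p_up = np.array([[jump_up_probability(mlg, k, i) for i in range(n)]
                     for k in range(mlg.k_star + 1)])
    walks: list[list[str]] = []
    n_forced = 0
    for i in range(n):
        for w_idx in range(num_walks):
            rng = np.random.default_rng([seed, i, w_idx])
            layer, cur = 0, i
            walk = [mlg.node_ids[cur]]
            steps = 0
            while len(walk) < walk_length and steps < 50 * walk_length:
                steps += 1
                entry = cums[layer][cur]
                jump = entry is None or rng.random() >= q
                if entry is None:
                    n_forced += 1
                if jump:
                    up = p_up[layer, cur]
                    down_ok = layer > 0
                    up_ok = mlg.up_weight[layer, cur] > 0
                    if not up_ok and not down_ok:
                        if entry is None:
                            break  # isolated in its only layer: walk ends
                        continue
                    if rng.random() < up:
                        layer += 1
                    elif down_ok:
                        layer -= 1
                    elif up_ok:
                        layer += 1
                    continue
                nbr, cum = entry
                cur = int(nbr[np.searchsorted(cum, rng.random(), side="right")])
                walk.append(mlg.node_ids[cur])
            walks.append(walk)
    if n_forced:
        log.info("sample_walks: %d forced layer jumps (no intra-layer neighbors)", n_forced)
    return WalkCorpus(walks=walks, num_walks=num_walks, walk_length=walk_length, q=q, seed=seed)


# ---------------------------------------------------------------------------
# skip-gram (hierarchical softmax), single-threaded and seeded
# ---------------------------------------------------------------------------


def _build_huffman(counts: np.ndarray) -> tuple[list[list[int]], list[list[int]]]:
    """Huffman coding of the vocabulary by frequency (word2vec layout).

    Returns per-word binary codes and inner-node paths, root first.
    Deterministic: ties broken by the stable ascending-count order.
    """
    V = len(counts)
    count = np.empty(2 * V, dtype=np.int64)
    count[:V] = counts
    count[V:] = np.iinfo(np.int64).max
    parent = np.zeros(2 * V, dtype=np.int64)
    binary = np.zeros(2 * V, dtype=np.int8)
    sorted_leaves = np.argsort(counts, kind="stable")
    i1, i2 = 0, V  # next unmerged leaf / internal node
    for a in range(V - 1):
        picks = []
        for _ in range(2):
            if i1 < V and (i2 >= V + a or count[sorted_leaves[i1]] <= count[i2]):
                picks.append(int(sorted_leaves[i1]))
                i1 += 1
            else:
                picks.append(i2)
                i2 += 1
        m1, m2 = picks
        count[V + a] = count[m1] + count[m2]
        parent[m1] = V + a
        parent[m2] = V + a
        binary[m2] = 1
    codes: list[list[int]] = []
    points: list[list[int]] = []
    root = 2 * V - 2
    for w in range(V):
        code: list[int] = []
        point: list[int] = []
        node = w
        while node != root:
            if node >= V:
                point.append(node - V)
            code.append(int(binary[node]))
            node = parent[node]
        point.append(root - V)
        codes.append(list(reversed(code)))
        points.append(list(reversed(point)))
    return codes, points


@njit(cache=False)
def _sg_train_hs(tokens: np.ndarray, sent_off: np.ndarray, syn0: np.ndarray,
                 syn1: np.ndarray, code_flat: np.ndarray, point_flat: np.ndarray,
                 code_off: np.ndarray, code_len: np.ndarray,
                 window: int, epochs: int, lr0: float, seed: int) -> None:
    state = np.uint64(seed * 2862933555777941757 + 3037000493)
    dim = syn0.shape[1]
    total_pairs = np.int64(0)
    # linear learning-rate decay over the expected pair count
    sched = float(tokens.shape[0]) * window * epochs + 1.0
    for _ in range(epochs):
        for s in range(sent_off.shape[0] - 1):
            lo, hi = sent_off[s], sent_off[s + 1]
            for pos in range(lo, hi):
                center = tokens[pos]
                # xorshift64* PRNG for the reduced window
                state ^= state >> np.uint64(12)
                state ^= state << np.uint64(25)
                state &= np.uint64(0xFFFFFFFFFFFFFFFF)
                state ^= state >> np.uint64(27)
                r = np.uint64(state * np.uint64(2685821657736338717))
                b = int(r % np.uint64(window))
                span = window - b
                for cpos in range(max(lo, pos - span), min(hi, pos + span + 1)):
                    if cpos == pos:
                        continue
                    ctx = tokens[cpos]
                    lr = lr0 * (1.0 - total_pairs / sched)
                    if lr < lr0 * 1e-4:
                        lr = lr0 * 1e-4
                    total_pairs += 1
                    neu = np.zeros(dim)
                    co, cl = code_off[center], code_len[center]
                    for ci in range(cl):
                        node = point_flat[co + ci]
                        f = 0.0
                        for e in range(dim):
                            f += syn0[ctx, e] * syn1[node, e]
                        if f > 6.0:
                            sig = 1.0
                        elif f < -6.0:
                            sig = 0.0
                        else:
                            sig = 1.0 / (1.0 + math.exp(-f))
                        g = (1.0 - code_flat[co + ci] - sig) * lr
                        for e in range(dim):
                            neu[e] += g * syn1[node, e]
                            syn1[node, e] += g * syn0[ctx, e]
                    for e in range(dim):
                        syn0[ctx, e] += neu[e]


def train_skipgram(
    corpus: WalkCorpus,
    dim: int = DEFAULT_DIM,
    window: int = DEFAULT_WINDOW,
    epochs: int = DEFAULT_EPOCHS,
    seed: int = 0,
    lr: float = 0.025,
) -> EmbeddingTable:
    """Hierarchical-softmax skip-gram over the walk corpus.

    Output nodes form a Huffman tree over token frequencies; every token in
    the corpus receives a vector (min count 0). Training is single-threaded
    with its own PRNG, so results are bit-reproducible for a given seed.
    """
    sentences = [w for w in corpus.walks if len(w) >= 2]
    if not sentences:
        raise ValueError("empty walk corpus")
    vocab = sorted({tok for s in sentences for tok in s})
    index = {g: i for i, g in enumerate(vocab)}
    counts = np.zeros(len(vocab), dtype=np.int64)
    tokens_list: list[np.ndarray] = []
    sent_off = np.zeros(len(sentences) + 1, dtype=np.int64)
    for si, s in enumerate(sentences):
        arr = np.array([index[t] for t in s], dtype=np.int64)
        tokens_list.append(arr)
        sent_off[si + 1] = sent_off[si] + arr.size
        np.add.at(counts, arr, 1)
    tokens = np.concatenate(tokens_list)
    rng = np.random.default_rng([seed, 7919])
    syn0 = (rng.random((len(vocab), dim)) - 0.5) / dim
    if len(vocab) == 1:  # degenerate corpus: nothing to contrast against
        return EmbeddingTable(gene_ids=vocab, vectors=syn0)
    codes, points = _build_huffman(counts)
    code_len = np.array([len(c) for c in codes], dtype=np.int64)
    code_off = np.zeros(len(vocab), dtype=np.int64)
    code_off[1:] = np.cumsum(code_len)[:-1]
    code_flat = np.array([b for c in codes for b in c], dtype=np.float64)
    point_flat = np.array([p for ps in points for p in ps], dtype=np.int64)
    syn1 = np.zeros((len(vocab) - 1, dim))  # one output vector per inner tree node
    _sg_train_hs(tokens, sent_off, syn0, syn1, code_flat, point_flat,
                 code_off, code_len, window, epochs, lr, (seed % (2 ** 31)) * 2 + 1)
    return EmbeddingTable(gene_ids=vocab, vectors=syn0)


# ---------------------------------------------------------------------------
# convenience: full structural-embedding chain on one network
# ---------------------------------------------------------------------------


def effective_diameter(net: GeneNetwork) -> int:
    """Largest finite eccentricity over connected components."""
    g = net.to_networkx()
    diam = 0
    for cc in nx.connected_components(g):
        if len(cc) > 1:
            diam = max(diam, nx.diameter(g.subgraph(cc)))
    return diam


def embed_network(
    net: GeneNetwork,
    k_max: int | None = None,
    k_cap: int = DEFAULT_K_CAP,
    num_walks: int = DEFAULT_NUM_WALKS,
    walk_length: int = DEFAULT_WALK_LENGTH,
    q: float = DEFAULT_STAY_PROB,
    dim: int = DEFAULT_DIM,
    window: int = DEFAULT_WINDOW,
    epochs: int = DEFAULT_EPOCHS,
    seed: int = 0,
    mode: str = "global",
) -> EmbeddingTable:
    """Degree sequences -> distances -> multilayer -> walks -> skip-gram."""
    if k_max is None:
        k_max = min(effective_diameter(net), k_cap)
    table = degree_sequences(net, k_max)
    dist = structural_distances(table, k_star=k_max, net=net, mode=mode)
    mlg = build_multilayer(dist)
    corpus = sample_walks(mlg, num_walks=num_walks, walk_length=walk_length, q=q, seed=seed)
    return train_skipgram(corpus, dim=dim, window=window, epochs=epochs, seed=seed)
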