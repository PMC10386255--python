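"""Network propagation of per-sample mutation profiles and the mutation
integration network.

Each sample's binary mutation indicator vector Y is diffused over the gene
interaction network by iterating

    F_t = alpha * W' @ F_{t-1} + (1 - alpha) * Y,   F_0 = Y,

where W' = D^{-1/2} A D^{-1/2} is the degree-adjusted (symmetrically
normalized) adjacency matrix. The iteration is a contraction for
alpha < 1 because the spectral radius of W' is at most 1, so it converges
to the unique fixed point (1 - alpha) (I - alpha W')^{-1} Y. Propagated
gene profiles are then compared across samples (Pearson correlation by
default) and the similarity matrix is thresholded (strict >) to give the
unweighted "mutation integration network".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .net_io import GeneNetwork, MutationMatrix

log = logging.getLogger("drivnet")

__all__ = [
    "DegreeAdjustedMatrix",
    "PropagatedMatrix",
    "SimilarityMatrix",
    "normalize_adjacency",
    "propagate_sample",
    "propagate_all",
    "gene_similarity",
    "threshold_network",
]

DEFAULT_ALPHA = 0.5
DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 10_000
DEFAULT_SIM_CUTOFF = 0.5


@dataclass
class DegreeAdjustedMatrix:
    """Symmetrically degree-normalized adjacency W' with its gene order."""

    gene_ids: list[str]
    W: sp.csr_matrix  # n x n, zero diagonal, spectral radius <= 1


@dataclass
class PropagatedMatrix:
    """Row-wise converged propagation F of a mutation matrix (m x n)."""

    sample_ids: list[str]
    gene_ids: list[str]
    F: np.ndarray
    alpha: float
    iterations_used: np.ndarray  # per-sample iteration counts


@dataclass
class SimilarityMatrix:
    """Symmetric gene-gene similarity of propagated profiles."""

    gene_ids: list[str]
    S: np.ndarray
    method: str


def normalize_adjacency(net: GeneNetwork) -> DegreeAdjustedMatrix:
    """W' = D^{-1/2} A D^{-1/2}; isolated nodes keep all-zero rows/columns."""
    if net.n_nodes == 0:
        raise ValueError("empty network")
    genes = sorted(net.nodes)
    index = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    rows, cols = [], []
    for a, b in net.edges:
        rows += [index[a], index[b]]
        cols += [index[b], index[a]]
    A = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    deg = np.asarray(A.sum(axis=1)).ravel()
    n_isolated = int((deg == 0).sum())
    if n_isolated:
        log.info("normalize_adjacency: %d isolated nodes (zero rows kept)", n_isolated)
    with np.errstate(divide="ignore"):
        d_inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.maximum(deg, 1e-300)), 0.0)
    Dh = sp.diags(d_inv_sqrt)
    W = (Dh @ A @ Dh).tocsr()
    return DegreeAdjustedMatrix(gene_ids=genes, W=W)


def propagate_sample(
    W: DegreeAdjustedMatrix,
    y: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> tuple[np.ndarray, int]:
    """Iterate F_t = alpha W' F_{t-1} + (1-alpha) y until ||F_t - F_{t-1}||_2 < tol."""
    y = np.asarray(y, dtype=np.float64)
    if y.shape != (len(W.gene_ids),):
        raise ValueError("seed vector length does not match gene universe")
    if not 0.0 <= alpha < 1.0:
        raise ValueError("alpha must lie in [0, 1)")
    if tol <= 0:
        raise ValueError("tol must be positive")
    if alpha == 0.0 or not y.any():
        return y.copy(), 1
    f_prev = y.copy()
    base = (1.0 - alpha) * y
    for it in range(1, max_iter + 1):
        f = alpha * (W.W @ f_prev) + base
        if np.linalg.norm(f - f_prev) < tol:
            return f, it
        f_prev = f
    residual = float(np.linalg.norm(f - f_prev))
    raise RuntimeError(
        f"propagation failed to converge in {max_iter} iterations (residual {residual:.3e})"
    )


def propagate_all(
    W: DegreeAdjustedMatrix,
    mat: MutationMatrix,
    alpha: float = DEFAULT_ALPHA,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> PropagatedMatrix:
    """Propagate every sample row independently (gene universes must be aligned)."""
    if list(mat.gene_ids) != list(W.gene_ids):
        raise ValueError("mutation matrix gene order does not match W'; align first")
    F = np.empty((mat.m, mat.n), dtype=np.float64)
    iters = np.empty(mat.m, dtype=np.int64)
    for i in range(mat.m):
        F[i], iters[i] = propagate_sample(W, mat.values[i].astype(np.float64), alpha, tol, max_iter)
    return PropagatedMatrix(
        sample_ids=list(mat.sample_ids),
        gene_ids=list(mat.gene_ids),
        F=F,
        alpha=alpha,
        iterations_used=iters,
    )


def gene_similarity(prop: PropagatedMatrix, method: str = "cosine") -> SimilarityMatrix:
    """Pairwise similarity between gene columns of the propagated matrix F.

    ``cosine`` (default) is bounded in [0, 1] on the non-negative propagated
    profiles and preserves mutation-recurrence magnitude, so recurrently
    mutated neighborhoods form the dense core of the thresholded network.
    ``pearson`` (needs >= 2 samples; constant columns get similarity 0 by
    convention) and raw ``dot`` are alternatives. Pearson centers each
    column, and because a gene's own mutation indicator dominates its
    propagated variance the correlation degenerates to roughly the local
    normalized-adjacency weight — mutation rates drop out, which defeats
    the purpose of the integration network (see docs/methods.md).
    """
    F = prop.F
    n = F.shape[1]
    if method == "pearson":
        if F.shape[0] < 2:
            raise ValueError("Pearson similarity needs at least 2 samples")
        centered = F - F.mean(axis=0)
        norms = np.linalg.norm(centered, axis=0)
        constant = norms == 0
        safe = np.where(constant, 1.0, norms)
        X = centered / safe
        S = X.T @ X
        S[constant, :] = 0.0
        S[:, constant] = 0.0
        np.clip(S, -1.0, 1.0, out=S)
    elif method == "cosine":
        norms = np.linalg.norm(F, axis=0)
        zero = norms == 0
        X = F / np.where(zero, 1.0, norms)
        S = X.T @ X
        S[zero, :] = 0.0
        S[:, zero] = 0.0
        np.clip(S, -1.0, 1.0, out=S)
    elif method == "dot":
        S = F.T @ F
    else:
        raise ValueError(f"unknown similarity method {method!r}")
    S = (S + S.T) / 2.0  # enforce exact symmetry against float noise
    return SimilarityMatrix(gene_ids=list(prop.gene_ids), S=S, method=method)


def threshold_network(sim: SimilarityMatrix, cutoff: float = DEFAULT_SIM_CUTOFF) -> GeneNetwork:
    """Keep edges with similarity strictly above ``cutoff``; drop isolated genes."""
    S = sim.S
    n = S.shape[0]
    iu = np.triu_indices(n, k=1)
    keep = S[iu] > cutoff
    edges = [
        tuple(sorted((sim.gene_ids[i], sim.gene_ids[j])))
        for i, j in zip(iu[0][keep], iu[1][keep])
    ]
    if not edges:
        raise ValueError(f"thresholding at {cutoff} leaves an empty network")
    net = GeneNetwork.from_edges(edges)
    dropped = n - net.n_nodes
    if dropped:
        log.info("threshold_network: dropped %d isolated genes of %d", dropped, n)
    return net
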