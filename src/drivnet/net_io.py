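"""Readers/writers for the external formats and gene-universe reconciliation.

Formats handled here:

* gene interaction networks as 2-column edge lists (TSV, optional SIF
  middle column, ``#`` comments),
* binary mutation matrices (TSV, samples x genes, header row of gene
  symbols, first column sample IDs),
* benchmark gene sets (one symbol per line),
* embeddings in word2vec text format (header ``<count> <dim>``).

Gene identifiers are uppercased strings compared exactly after case
folding; alias/synonym resolution is upstream curation and out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

log = logging.getLogger("drivnet")

__all__ = [
    "GeneNetwork",
    "MutationMatrix",
    "BenchmarkGeneSet",
    "EmbeddingTable",
    "read_edge_list",
    "write_edge_list",
    "read_mutation_matrix",
    "write_mutation_matrix",
    "read_gene_set",
    "write_gene_set",
    "align_universe",
    "read_embeddings",
    "write_embeddings",
]


class ParseError(ValueError):
    """Raised when an input file violates its documented format."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneNetwork:
    """Undirected, unweighted graph over uppercase gene identifiers.

    Invariants: no self-loops, no duplicate edges, every edge endpoint is a
    node. Edges are stored as sorted 2-tuples so (a, b) == (b, a).
    """

    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
            if a > b:
                raise ValueError(f"edge {(a, b)!r} not canonically ordered")
            if a not in self.nodes or b not in self.nodes:
                raise ValueError(f"edge {(a, b)!r} has endpoint outside node set")

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str]], extra_nodes: Iterable[str] = ()
    ) -> "GeneNetwork":
        """Build from raw pairs: uppercase, drop self-loops, collapse duplicates."""
        nodes: set[str] = {str(g).upper() for g in extra_nodes}
        canon: set[tuple[str, str]] = set()
        n_self = n_dup = 0
        for a, b in edges:
            a, b = str(a).upper(), str(b).upper()
            if a == b:
                n_self += 1
                nodes.add(a)
                continue
            e = (a, b) if a < b else (b, a)
            if e in canon:
                n_dup += 1
            canon.add(e)
            nodes.add(a)
            nodes.add(b)
        if n_self or n_dup:
            log.info("dropped %d self-loops, collapsed %d duplicate edges", n_self, n_dup)
        return cls(nodes=frozenset(nodes), edges=frozenset(canon))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(sorted(self.nodes))
        g.add_edges_from(sorted(self.edges))
        return g

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def subgraph(self, keep: Iterable[str]) -> "GeneNetwork":
        keep_set = set(keep)
        return GeneNetwork(
            nodes=frozenset(self.nodes & keep_set),
            edges=frozenset(e for e in self.edges if e[0] in keep_set and e[1] in keep_set),
        )


@dataclass
class MutationMatrix:
    """Binary samples x genes matrix A (m samples as rows, n genes as columns)."""

    sample_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray  # (m, n) int8 in {0, 1}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        m, n = self.values.shape
        if m != len(self.sample_ids) or n != len(self.gene_ids):
            raise ValueError("matrix shape does not match id lists")
        if len(set(self.sample_ids)) != m:
            raise ValueError("duplicate sample identifiers")
        if len(set(self.gene_ids)) != n:
            raise ValueError("duplicate gene identifiers")
        bad = ~np.isin(self.values, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"non-binary cell at sample {self.sample_ids[i]!r}, gene {self.gene_ids[j]!r}"
            )
        self.values = self.values.astype(np.int8)

    @property
    def m(self) -> int:
        return len(self.sample_ids)

    @property
    def n(self) -> int:
        return len(self.gene_ids)

    def restrict_genes(self, genes: Sequence[str]) -> "MutationMatrix":
        idx = {g: j for j, g in enumerate(self.gene_ids)}
        cols = [idx[g] for g in genes]
        return MutationMatrix(list(self.sample_ids), list(genes), self.values[:, cols])


@dataclass(frozen=True)
class BenchmarkGeneSet:
    """Named set of benchmark (known driver) gene identifiers."""

    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"benchmark gene set {self.name!r} is empty")
        if any(g != g.upper() for g in self.genes):
            raise ValueError("benchmark identifiers must be uppercase")


@dataclass
class EmbeddingTable:
    """gene -> d-dimensional real vector map, row-aligned to gene_ids."""

    gene_ids: list[str]
    vectors: np.ndarray  # (len(gene_ids), dim) float64

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.gene_ids):
            raise ValueError("one vector per gene required")
        if not np.isfinite(self.vectors).all():
            raise ValueError("non-finite embedding values")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene identifiers in embedding table")

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def vector(self, gene: str) -> np.ndarray:
        return self.vectors[self.gene_ids.index(gene)]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_edge_list(path: str | Path, delimiter: str | None = None, sif: bool = False) -> GeneNetwork:
    """Read a 2-column edge list (or 3-column SIF with ``sif=True``).

    Lines starting with ``#`` are comments. Identifiers are uppercased,
    self-loops dropped and duplicate/reversed edges collapsed; drop counts
    are logged.
    """
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split(delimiter) if delimiter else line.split()
            if sif:
                if len(fields) < 3:
                    raise ParseError(f"{path}:{lineno}: SIF line needs >=3 fields")
                a, b = fields[0], fields[2]
            else:
                if len(fields) != 2:
                    raise ParseError(
                        f"{path}:{lineno}: expected 2 fields, got {len(fields)}"
                    )
                a, b = fields
            pairs.append((a, b))
    if not pairs:
        raise ParseError(f"{path}: no edges found")
    net = GeneNetwork.from_edges(pairs)
    log.info("read %s: %d nodes, %d edges", path.name, net.n_nodes, net.n_edges)
    return net


def write_edge_list(net: GeneNetwork, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for a, b in sorted(net.edges):
            fh.write(f"{a}\t{b}\n")


def read_mutation_matrix(path: str | Path, orientation_hint: str = "samples_by_genes") -> MutationMatrix:
    """Read a binary mutation matrix from TSV.

    Header row holds gene identifiers, first column sample identifiers,
    cells are strictly "0"/"1". ``orientation_hint="genes_by_samples"``
    transposes after reading.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len({h.upper() for h in header}) != len(header):
        raise ParseError(f"{path}: duplicate gene column")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.empty:
        raise ParseError(f"{path}: empty matrix")
    if orientation_hint == "genes_by_samples":
        df = df.T
    genes = [str(g).upper() for g in df.columns]
    if len(set(genes)) != len(genes):
        raise ParseError(f"{path}: duplicate gene column")
    samples = [str(s) for s in df.index]
    raw = df.to_numpy()
    values = np.empty(raw.shape, dtype=np.int8)
    for (i, j), cell in np.ndenumerate(raw):
        cell = str(cell).strip()
        if cell not in ("0", "1"):
            raise ParseError(
                f"{path}: non-binary cell {cell!r} at row {samples[i]!r}, column {genes[j]!r}"
            )
        values[i, j] = int(cell)
    return MutationMatrix(samples, genes, values)


def write_mutation_matrix(mat: MutationMatrix, path: str | Path) -> None:
    df = pd.DataFrame(mat.values, index=mat.sample_ids, columns=mat.gene_ids)
    df.to_csv(path, sep="\t")


def read_gene_set(path: str | Path, name: str) -> BenchmarkGeneSet:
    """One identifier per line; blank lines skipped; uppercased and deduplicated."""
    genes = set()
    with Path(path).open() as fh:
        for line in fh:
            g = line.strip()
            if g and not g.startswith("#"):
                genes.add(g.upper())
    if not genes:
        raise ParseError(f"{path}: empty gene set")
    return BenchmarkGeneSet(name=name, genes=frozenset(genes))


def write_gene_set(bench: BenchmarkGeneSet, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for g in sorted(bench.genes):
            fh.write(g + "\n")


def align_universe(net: GeneNetwork, mat: MutationMatrix) -> tuple[GeneNetwork, MutationMatrix]:
    """Restrict network and matrix to their shared gene universe.

    Genes absent from either side are dropped; the network keeps only edges
    induced on the intersection. Matrix columns come back in canonical
    lexicographic order, which downstream stages rely on for determinism.
    """
    common = sorted(net.nodes & set(mat.gene_ids))
    if not common:
        raise ValueError("network and mutation matrix share no genes")
    log.info(
        "aligning universes: network %d genes, matrix %d genes -> intersection %d",
        net.n_nodes, mat.n, len(common),
    )
    return net.subgraph(common), mat.restrict_genes(common)


def write_embeddings(emb: EmbeddingTable, path: str | Path) -> None:
    """word2vec text format: header '<count> <dim>' then one gene per line."""
    with Path(path).open("w") as fh:
        fh.write(f"{len(emb.gene_ids)} {emb.dim}\n")
        for g, vec in zip(emb.gene_ids, emb.vectors):
            fh.write(g + " " + " ".join(repr(float(v)) for v in vec) + "\n")


def read_embeddings(path: str | Path) -> EmbeddingTable:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ParseError(f"{path}: malformed header")
        count, dim = int(header[0]), int(header[1])
        genes: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != dim + 1:
                raise ParseError(f"{path}:{lineno}: expected {dim + 1} fields")
            genes.append(fields[0])
            rows.append([float(v) for v in fields[1:]])
    if len(genes) != count:
        raise ParseError(f"{path}: header promises {count} vectors, found {len(genes)}")
    return EmbeddingTable(genes, np.array(rows, dtype=np.float64))
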