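"""Shared in-memory containers used across the pipeline.

The central objects are :class:`CountMatrix` (genes x cells UMI counts with
per-cell cluster labels), :class:`EdgeKey` (a canonical unordered gene
pair), and :class:`ClusterNetwork` (a thresholded per-cluster coexpression
network with edge ranks).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import scipy.sparse as sp


@dataclass(frozen=True, order=True)
class EdgeKey:
    """Canonical unordered gene pair: ``gene_a < gene_b`` lexicographically.

    Construction canonicalizes the order; self-pairs are rejected.
    """

    gene_a: str
    gene_b: str

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-edge not allowed: {self.gene_a!r}")
        if self.gene_a > self.gene_b:
            a, b = self.gene_a, self.gene_b
            object.__setattr__(self, "gene_a", b)
            object.__setattr__(self, "gene_b", a)

    def genes(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


def _as_int_csr(counts) -> sp.csr_matrix:
    m = sp.csr_matrix(counts)
    if m.nnz:
        data = m.data
        if not np.issubdtype(data.dtype, np.integer):
            if not np.allclose(data, np.round(data)):
                raise ValueError("counts must be integral")
        if data.min() < 0:
            raise ValueError("counts must be non-negative")
    return m.astype(np.int64)


@dataclass
class CountMatrix:
    """Genes x cells UMI count matrix with cluster labels.

    ``counts`` is stored sparse (CSR, int64).  Every cell must carry exactly
    one cluster label; ``mito_genes`` flags the mitochondrial gene subset
    used by the QC mitochondrial-fraction rule.
    """

    gene_ids: list[str]
    cell_ids: list[str]
    counts: sp.csr_matrix
    cluster_of: dict[str, str]
    mito_genes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.cell_ids = list(self.cell_ids)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell ids")
        self.counts = _as_int_csr(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        missing = [c for c in self.cell_ids if c not in self.cluster_of]
        if missing:
            raise ValueError(f"cells lacking a cluster label: {missing[:5]}")
        self.mito_genes = frozenset(self.mito_genes)
        unknown = self.mito_genes - set(self.gene_ids)
        if unknown:
            raise ValueError(f"mito genes not in gene_ids: {sorted(unknown)[:5]}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def cluster_labels(self) -> list[str]:
        """Sorted unique cluster labels among current cells."""
        return sorted({self.cluster_of[c] for c in self.cell_ids})

    def cell_indices_of(self, label: str) -> np.ndarray:
        return np.array(
            [i for i, c in enumerate(self.cell_ids) if self.cluster_of[c] == label],
            dtype=np.int64,
        )

    def cluster_submatrix(self, label: str) -> sp.csr_matrix:
        idx = self.cell_indices_of(label)
        if idx.size == 0:
            raise KeyError(f"no cells in cluster {label!r}")
        return self.counts[:, idx]

    def subset_cells(self, cell_indices: Iterable[int]) -> "CountMatrix":
        idx = np.asarray(list(cell_indices), dtype=np.int64)
        cells = [self.cell_ids[i] for i in idx]
        return CountMatrix(
            gene_ids=list(self.gene_ids),
            cell_ids=cells,
            counts=self.counts[:, idx],
            cluster_of={c: self.cluster_of[c] for c in cells},
            mito_genes=self.mito_genes,
        )

    def subset_genes(self, genes: Iterable[str]) -> "CountMatrix":
        genes = list(genes)
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        idx = np.array([pos[g] for g in genes], dtype=np.int64)
        return CountMatrix(
            gene_ids=genes,
            cell_ids=list(self.cell_ids),
            counts=self.counts[idx, :],
            cluster_of={c: self.cluster_of[c] for c in self.cell_ids},
            mito_genes=self.mito_genes & set(genes),
        )

    def copy(self) -> "CountMatrix":
        return CountMatrix(
            gene_ids=list(self.gene_ids),
            cell_ids=list(self.cell_ids),
            counts=self.counts.copy(),
            cluster_of=dict(self.cluster_of),
            mito_genes=self.mito_genes,
        )


@dataclass
class ZScoreTable:
    """Per-gene z-score profiles across subcluster comparisons.

    ``values`` has one row per gene and one column per unordered subcluster
    pair; a positive entry means the gene is higher in the lower-indexed
    subcluster of that comparison.
    """

    gene_ids: list[str]
    comparisons: list[tuple[int, int]]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.comparisons)):
            raise ValueError("z-score table shape mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite z-scores")


@dataclass
class CorrelationMatrix:
    """Symmetric gene-gene Pearson correlation matrix of z-score profiles."""

    gene_ids: list[str]
    values: np.ndarray
    zero_variance: np.ndarray  # boolean flag per gene

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (n, n):
            raise ValueError("correlation matrix shape mismatch")
        self.zero_variance = np.asarray(self.zero_variance, dtype=bool)


@dataclass(frozen=True)
class EdgeInfo:
    abs_corr: float
    rank: int


@dataclass
class ClusterNetwork:
    """Thresholded coexpression network of one cell cluster.

    ``edges`` maps each kept canonical pair to its |r| and global rank
    (1 = largest |r| among all pairs).  ``q`` is the kept top fraction.
    """

    label: str
    gene_ids: list[str]
    edges: dict[EdgeKey, EdgeInfo]
    q: float

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_set(self) -> set[EdgeKey]:
        return set(self.edges)

    def degrees(self) -> dict[str, int]:
        deg: dict[str, int] = {}
        for e in self.edges:
            deg[e.gene_a] = deg.get(e.gene_a, 0) + 1
            deg[e.gene_b] = deg.get(e.gene_b, 0) + 1
        return deg


@dataclass
class CommonalityTable:
    """Edge and gene commonality over N cluster networks.

    ``edge_k[e]`` is the number of cluster networks containing edge ``e``;
    ``gene_k[g]`` the number of clusters where gene ``g`` has >= 1 edge.
    """

    n_clusters: int
    edge_k: dict[EdgeKey, int]
    gene_k: dict[str, int]

    def histogram(self) -> np.ndarray:
        """Counts of edges at each commonality 0..N (index = k)."""
        h = np.zeros(self.n_clusters + 1, dtype=np.int64)
        for k in self.edge_k.values():
            h[k] += 1
        return h


@dataclass
class BinomialNull:
    """Analytic binomial null for edge commonality across N clusters."""

    n_clusters: int
    p: float
    pmf: np.ndarray

    def __post_init__(self) -> None:
        self.pmf = np.asarray(self.pmf, dtype=float)
        if self.pmf.shape != (self.n_clusters + 1,):
            raise ValueError("pmf length must be N+1")
        if abs(self.pmf.sum() - 1.0) > 1e-12:
            raise ValueError("pmf must sum to 1")


@dataclass
class RRAGroupResult:
    """Aggregated-rank significance of one edge-commonality group."""

    k: int
    sampled_edges: list[EdgeKey]
    p_raw: list[float]
    p_adj: list[float]
    fisher_chi2: float
    fisher_df: int
    fisher_p: float
    group_p_bonferroni: float


@dataclass
class SharedNetwork:
    """Edges whose commonality meets the rank-aggregation cutoff."""

    edges: set[EdgeKey]
    k_star: int | None
    label: str = "shared"

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for e in self.edges:
            out.add(e.gene_a)
            out.add(e.gene_b)
        return out

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class ModulePartition:
    """Community assignment of shared-network genes.

    Modules are indexed 1..M by decreasing size; genes belonging to
    communities smaller than ``min_size`` are collected in ``unassigned``.
    """

    assignment: dict[str, int]
    unassigned: set[str]
    min_size: int

    def modules(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for g, m in self.assignment.items():
            out.setdefault(m, set()).add(g)
        return out


@dataclass
class CoreNetwork:
    """Intersection of shared networks from several datasets."""

    edges: set[EdgeKey]
    provenance: list[str]

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for e in self.edges:
            out.add(e.gene_a)
            out.add(e.gene_b)
        return out


def edges_to_genes(edges: Iterable[EdgeKey]) -> set[str]:
    out: set[str] = set()
    for e in edges:
        out.add(e.gene_a)
        out.add(e.gene_b)
    return out
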