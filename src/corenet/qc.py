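"""Cell, gene, cluster-size, and sparsity quality-control filters.

Cells are dropped if they express too few genes, carry too few UMIs, or
have an excessive mitochondrial count fraction.  Clusters below the size
floor are dropped; within each kept cluster a gene counts as expressed if
its nonzero-cell count reaches ``max(abs floor, ceil(frac * n_cells))``.
The *commonly expressed* gene set is the intersection of per-cluster
expressed sets — fixed before the final sparsity exclusion, which removes
clusters whose common-gene submatrix is mostly zeros without recomputing
the common set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .containers import CountMatrix

__all__ = ["QCConfig", "CellFilterReport", "QCResult", "filter_cells", "gene_min_cells", "select_clusters_and_common_genes"]


@dataclass
class QCConfig:
    min_genes_per_cell: int = 200
    min_umi_per_cell: int = 500
    max_mito_fraction: float = 0.30
    min_cells_per_cluster: int = 200
    gene_min_cells_abs: int = 15
    gene_min_cells_frac: float = 0.005
    max_cluster_sparsity: float = 0.50

    def __post_init__(self) -> None:
        for name in ("min_genes_per_cell", "min_umi_per_cell", "min_cells_per_cluster", "gene_min_cells_abs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("max_mito_fraction", "gene_min_cells_frac", "max_cluster_sparsity"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class CellFilterReport:
    removed_low_gene: int = 0
    removed_low_umi: int = 0
    removed_high_mito: int = 0

    @property
    def removed_total(self) -> int:
        return self.removed_low_gene + self.removed_low_umi + self.removed_high_mito


def filter_cells(cm: CountMatrix, qc: QCConfig) -> tuple[CountMatrix, CellFilterReport]:
    """Retain cells passing all three per-cell rules; report removals per rule.

    A cell failing several rules is counted once under the first failed
    rule (genes, then UMI, then mito).  Raises if no cell survives.
    """
    counts = cm.counts
    expressed = np.asarray((counts > 0).sum(axis=0)).ravel()
    umi = np.asarray(counts.sum(axis=0)).ravel()
    mito_idx = [i for i, g in enumerate(cm.gene_ids) if g in cm.mito_genes]
    if mito_idx:
        mito_sum = np.asarray(counts[mito_idx, :].sum(axis=0)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_frac = np.where(umi > 0, mito_sum / np.maximum(umi, 1), 0.0)
    else:
        mito_frac = np.zeros(cm.n_cells)

    low_gene = expressed < qc.min_genes_per_cell
    low_umi = umi < qc.min_umi_per_cell
    high_mito = mito_frac > qc.max_mito_fraction
    keep = ~(low_gene | low_umi | high_mito)
    report = CellFilterReport(
        removed_low_gene=int(low_gene.sum()),
        removed_low_umi=int((low_umi & ~low_gene).sum()),
        removed_high_mito=int((high_mito & ~low_gene & ~low_umi).sum()),
    )
    if not keep.any():
        raise ValueError("all cells removed by QC filters")
    if keep.all():
        return cm, report
    return cm.subset_cells(np.flatnonzero(keep)), report


def gene_min_cells(n_cells_in_cluster: int, qc: QCConfig) -> int:
    """Expression floor: max(absolute count, ceil(fraction of cluster cells))."""
    if n_cells_in_cluster < 1:
        raise ValueError("cluster must contain at least one cell")
    return max(qc.gene_min_cells_abs, math.ceil(qc.gene_min_cells_frac * n_cells_in_cluster))


@dataclass
class QCResult:
    kept_clusters: list[str]
    expressed_genes: dict[str, set[str]]
    common_genes: list[str]
    sparsity: dict[str, float]
    dropped_small: list[str] = field(default_factory=list)
    dropped_sparse: list[str] = field(default_factory=list)


def select_clusters_and_common_genes(cm: CountMatrix, qc: QCConfig) -> QCResult:
    """Apply the cluster-size rule, define common genes, then exclude sparse clusters.

    Common genes are the intersection of per-cluster expressed gene sets
    over all size-passing clusters; they are *not* recomputed after the
    sparsity exclusion, so the gene universe is fixed before any cluster is
    dropped for sparsity.
    """
    labels = cm.cluster_labels()
    sizes = {lab: len(cm.cell_indices_of(lab)) for lab in labels}
    big = [lab for lab in labels if sizes[lab] >= qc.min_cells_per_cluster]
    dropped_small = [lab for lab in labels if lab not in set(big)]
    if not big:
        raise ValueError("no cluster passes the size rule")

    expressed: dict[str, set[str]] = {}
    for lab in big:
        sub = cm.cluster_submatrix(lab)
        floor = gene_min_cells(sub.shape[1], qc)
        n_nonzero = np.asarray((sub > 0).sum(axis=1)).ravel()
        expressed[lab] = {g for g, c in zip(cm.gene_ids, n_nonzero) if c >= floor}

    common = set.intersection(*(expressed[lab] for lab in big))
    if not common:
        raise ValueError("empty common gene set")
    common_genes = sorted(common)

    gene_pos = {g: i for i, g in enumerate(cm.gene_ids)}
    common_idx = np.array([gene_pos[g] for g in common_genes], dtype=np.int64)
    sparsity: dict[str, float] = {}
    for lab in big:
        sub = cm.cluster_submatrix(lab)[common_idx, :]
        sparsity[lab] = 1.0 - sub.nnz / (sub.shape[0] * sub.shape[1])

    kept = [lab for lab in big if sparsity[lab] <= qc.max_cluster_sparsity]
    dropped_sparse = [lab for lab in big if lab not in set(kept)]
    if not kept:
        raise ValueError("all clusters excluded by the sparsity rule")
    return QCResult(
        kept_clusters=kept,
        expressed_genes=expressed,
        common_genes=common_genes,
        sparsity=sparsity,
        dropped_small=dropped_small,
        dropped_sparse=dropped_sparse,
    )
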