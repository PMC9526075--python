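"""Per-cluster gene-gene correlation from sparse counts via z-score profiles.

Sparse UMI counts make cell-level Pearson correlation unreliable.  Instead,
cells of a cluster are first partitioned into homogeneous subclusters
(k-means on the top principal components of log1p CPM), then every gene
receives one differential-expression z-score per subcluster pair (Wilcoxon
rank-sum normal approximation with tie and continuity correction), and
genes are finally correlated through their z-score profiles.  Dropout zeros
enter only through the robust rank statistics, not through the correlation
itself.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.stats import rankdata
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .containers import CorrelationMatrix, ZScoreTable

__all__ = [
    "default_n_subclusters",
    "log_cpm",
    "subcluster_cells",
    "pairwise_zscores",
    "correlation_matrix",
    "cluster_correlation",
]


def default_n_subclusters(n_cells: int, low: int = 2, high: int = 10) -> int:
    """Default subcluster count: one per ~50 cells, clamped to [low, high]."""
    return int(np.clip(n_cells // 50, low, high))


def log_cpm(counts, pseudocount: float = 1.0, scale: float = 1e6) -> np.ndarray:
    """log(1 + CPM) with per-cell totals over the genes provided."""
    X = np.asarray(counts.todense() if sp.issparse(counts) else counts, dtype=float)
    totals = X.sum(axis=0)
    totals[totals == 0] = 1.0
    return np.log1p(X / totals[None, :] * scale)


def subcluster_cells(
    counts,
    n_sub: int | None = None,
    seed: int = 0,
    min_subcluster_size: int = 20,
    n_pcs: int = 10,
) -> np.ndarray:
    """Partition a cluster's cells into subclusters; returns labels 0..K-1.

    k-means runs on the top principal components of log1p CPM.  If k-means
    yields a subcluster below ``min_subcluster_size``, the subcluster count
    is lowered and, at K=2, deficient groups are topped up with the nearest
    cells of the larger group so that both satisfy the size floor.
    """
    X = log_cpm(counts)
    n_cells = X.shape[1]
    if n_cells < 2 * min_subcluster_size:
        raise ValueError(
            f"{n_cells} cells cannot form two subclusters of >= {min_subcluster_size}"
        )
    if n_sub is None:
        n_sub = default_n_subclusters(n_cells)
    if n_sub < 2:
        raise ValueError("n_sub must be >= 2")
    n_comp = int(min(n_pcs, X.shape[0], n_cells - 1))
    pcs = PCA(n_components=n_comp, svd_solver="full", random_state=0).fit_transform(X.T)

    k = int(n_sub)
    while True:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(pcs)
        labels = km.labels_.copy()
        sizes = np.bincount(labels, minlength=k)
        if sizes.min() >= min_subcluster_size:
            break
        if k > 2:
            k -= 1
            continue
        # K=2 rebalance: move the nearest cells of the big group into the small one
        small = int(np.argmin(sizes))
        big = 1 - small
        need = min_subcluster_size - sizes[small]
        d = np.linalg.norm(pcs - km.cluster_centers_[small], axis=1)
        candidates = np.flatnonzero(labels == big)
        move = candidates[np.argsort(d[candidates])[:need]]
        labels[move] = small
        break
    # relabel by subcluster mean position for determinism under label swaps
    order = np.argsort([pcs[labels == i, 0].mean() for i in range(labels.max() + 1)])
    remap = {int(old): new for new, old in enumerate(order)}
    return np.array([remap[int(l)] for l in labels], dtype=np.int64)


def _tie_term(row: np.ndarray) -> float:
    _, counts = np.unique(row, return_counts=True)
    t = counts[counts > 1].astype(float)
    return float((t**3 - t).sum())


def _ranksum_z(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorized Wilcoxon rank-sum z per gene (rows), positive when x > y.

    Normal approximation with tie correction and a 0.5 continuity
    correction; genes with all values tied get z = 0.
    """
    n1, n2 = x.shape[1], y.shape[1]
    n = n1 + n2
    combined = np.hstack([x, y])
    ranks = rankdata(combined, axis=1)
    r1 = ranks[:, :n1].sum(axis=1)
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    tie = np.array([_tie_term(row) for row in combined])
    var = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    z = np.zeros(x.shape[0])
    ok = var > 0
    diff = u1[ok] - mu
    z[ok] = (diff - 0.5 * np.sign(diff)) / np.sqrt(var[ok])
    return z


def pairwise_zscores(counts, subclusters: np.ndarray) -> tuple[ZScoreTable, None] | ZScoreTable:
    """Z-score table over all unordered subcluster pairs.

    ``counts`` is the genes x cells submatrix of one cluster; z-scores are
    computed on log1p CPM values.  Returns a table with C(K,2) columns.
    """
    labels = np.asarray(subclusters)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("need at least 2 subclusters")
    X = log_cpm(counts)
    gene_ids = [f"_row{i}" for i in range(X.shape[0])]
    cols = []
    comparisons = []
    for a_i in range(uniq.size):
        for b_i in range(a_i + 1, uniq.size):
            a, b = uniq[a_i], uniq[b_i]
            z = _ranksum_z(X[:, labels == a], X[:, labels == b])
            cols.append(z)
            comparisons.append((int(a), int(b)))
    return ZScoreTable(gene_ids=gene_ids, comparisons=comparisons, values=np.column_stack(cols))


def correlation_matrix(z: ZScoreTable, gene_ids: list[str] | None = None) -> CorrelationMatrix:
    """Pearson correlation of gene z-score profiles.

    Genes with zero variance across comparisons are flagged and given
    correlation 0 with every other gene.  Requires >= 3 comparisons.
    """
    V = z.values
    if V.shape[1] < 3:
        raise ValueError("need at least 3 comparisons to correlate profiles")
    genes = gene_ids if gene_ids is not None else z.gene_ids
    sd = V.std(axis=1)
    zero_var = sd == 0
    C = np.zeros((V.shape[0], V.shape[0]))
    ok = ~zero_var
    if ok.sum() >= 2:
        C[np.ix_(ok, ok)] = np.corrcoef(V[ok])
    np.clip(C, -1.0, 1.0, out=C)
    np.fill_diagonal(C, 1.0)
    return CorrelationMatrix(gene_ids=list(genes), values=C, zero_variance=zero_var)


def cluster_correlation(
    counts,
    gene_ids: list[str],
    n_sub: int | None = None,
    seed: int = 0,
    min_subcluster_size: int = 20,
    n_pcs: int = 10,
) -> CorrelationMatrix:
    """Full per-cluster recipe: subcluster -> z-scores -> correlation."""
    labels = subcluster_cells(
        counts, n_sub=n_sub, seed=seed, min_subcluster_size=min_subcluster_size, n_pcs=n_pcs
    )
    z = pairwise_zscores(counts, labels)
    return correlation_matrix(z, gene_ids=gene_ids)
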