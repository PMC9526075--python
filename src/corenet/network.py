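"""Thresholding correlation matrices into networks and choosing the threshold.

A cluster network keeps the top fraction ``q`` of gene pairs by absolute
correlation.  The fraction is chosen by a split-half signal-to-noise
criterion: at a good threshold, networks built from independent halves of
the cells overlap far more than the ``q^2 * C(n,2)`` pairs expected if the
two halves picked edges independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import coexpr
from .containers import ClusterNetwork, CorrelationMatrix, EdgeInfo, EdgeKey

__all__ = [
    "PairRanking",
    "rank_all_pairs",
    "threshold_network",
    "network_from_ranking",
    "snr_curve",
    "select_threshold",
    "n_edges_at",
]


def n_edges_at(q: float, n_genes: int) -> int:
    """Edge count kept at fraction q: round(q * C(n,2)), round half-to-even."""
    n_pairs = n_genes * (n_genes - 1) // 2
    return int(round(q * n_pairs))


@dataclass
class PairRanking:
    """Total order over all gene pairs of one cluster, by descending |r|.

    Ties are broken by the canonical (lexicographic) edge key so the order
    is deterministic.  ``a_idx``/``b_idx`` index into ``gene_ids`` in rank
    order (rank 1 first); ``normalized_rank[i] = (i+1)/C(n,2)``.
    """

    gene_ids: list[str]
    a_idx: np.ndarray
    b_idx: np.ndarray
    abs_corr: np.ndarray

    @property
    def n_pairs(self) -> int:
        return len(self.abs_corr)

    def normalized_ranks(self) -> np.ndarray:
        return np.arange(1, self.n_pairs + 1) / self.n_pairs

    def edge_at(self, i: int) -> EdgeKey:
        return EdgeKey(self.gene_ids[self.a_idx[i]], self.gene_ids[self.b_idx[i]])

    def rank_lookup(self) -> dict[EdgeKey, float]:
        """EdgeKey -> normalized rank in (0, 1] for every pair."""
        norm = self.normalized_ranks()
        return {self.edge_at(i): float(norm[i]) for i in range(self.n_pairs)}

    def top_edge_sets(self, qs: list[float]) -> dict[float, set[EdgeKey]]:
        out: dict[float, set[EdgeKey]] = {}
        n = len(self.gene_ids)
        for q in qs:
            e = n_edges_at(q, n)
            out[q] = {self.edge_at(i) for i in range(e)}
        return out


def rank_all_pairs(corr: CorrelationMatrix) -> PairRanking:
    """Rank every unordered gene pair by descending |r| (canonical tie-break)."""
    genes = corr.gene_ids
    n = len(genes)
    iu, ju = np.triu_indices(n, k=1)
    absr = np.abs(corr.values[iu, ju])
    ga = np.array(genes, dtype=object)
    # canonical pair: lexicographically smaller gene first
    a_names = np.where(ga[iu] < ga[ju], ga[iu], ga[ju])
    b_names = np.where(ga[iu] < ga[ju], ga[ju], ga[iu])
    order = np.lexsort((b_names, a_names, -absr))
    name_pos = {g: i for i, g in enumerate(genes)}
    a_sorted = np.array([name_pos[g] for g in a_names[order]], dtype=np.int64)
    b_sorted = np.array([name_pos[g] for g in b_names[order]], dtype=np.int64)
    return PairRanking(
        gene_ids=list(genes), a_idx=a_sorted, b_idx=b_sorted, abs_corr=absr[order]
    )


def network_from_ranking(ranking: PairRanking, q: float, label: str) -> ClusterNetwork:
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    n_edges = n_edges_at(q, len(ranking.gene_ids))
    if n_edges == 0:
        raise ValueError(f"q={q} keeps zero edges for {len(ranking.gene_ids)} genes")
    edges = {
        ranking.edge_at(i): EdgeInfo(abs_corr=float(ranking.abs_corr[i]), rank=i + 1)
        for i in range(n_edges)
    }
    return ClusterNetwork(label=label, gene_ids=list(ranking.gene_ids), edges=edges, q=q)


def threshold_network(corr: CorrelationMatrix, q: float, label: str = "") -> ClusterNetwork:
    """Keep the top round(q * C(n,2)) pairs of |r| as the cluster network."""
    return network_from_ranking(rank_all_pairs(corr), q, label)


def snr_curve(
    counts,
    gene_ids: list[str],
    candidate_qs: list[float],
    n_splits: int = 1,
    seed: int = 0,
    **coexpr_kwargs,
) -> dict[float, float]:
    """Split-half signal-to-noise ratio per candidate threshold.

    For each split, cells are halved at random and the full
    subcluster/z-score/threshold pipeline runs on each half.  SNR(q) is the
    observed edge overlap divided by the ``q^2 C(n,2)`` overlap expected if
    the halves chose edges independently, averaged over splits; 1 means no
    reproducible signal.
    """
    if n_splits < 1:
        raise ValueError("n_splits must be >= 1")
    import scipy.sparse as sp

    X = counts.tocsc() if sp.issparse(counts) else np.asarray(counts)
    n_cells = X.shape[1]
    n_pairs = len(gene_ids) * (len(gene_ids) - 1) // 2
    totals = {q: 0.0 for q in candidate_qs}
    for s in range(n_splits):
        rng = np.random.default_rng(np.random.SeedSequence((seed, s)))
        perm = rng.permutation(n_cells)
        halves = (perm[: n_cells // 2], perm[n_cells // 2 :])
        tops = []
        for h_i, idx in enumerate(halves):
            sub = X[:, np.sort(idx)]
            try:
                corr = coexpr.cluster_correlation(
                    sub, gene_ids, seed=int(rng.integers(2**31)), **coexpr_kwargs
                )
            except ValueError as err:
                raise ValueError(f"half {h_i + 1} of split {s} failed: {err}") from err
            tops.append(rank_all_pairs(corr).top_edge_sets(list(candidate_qs)))
        for q in candidate_qs:
            observed = len(tops[0][q] & tops[1][q])
            expected = q * q * n_pairs
            totals[q] += observed / expected
    return {q: totals[q] / n_splits for q in candidate_qs}


def select_threshold(curves: dict[str, dict[float, float]]) -> float:
    """Pick the q that is the per-cluster SNR argmax most often (mode).

    Ties — both within a cluster's curve and between candidate modes — are
    resolved toward the smaller q.
    """
    if not curves:
        raise ValueError("no SNR curves given")
    votes: dict[float, int] = {}
    for curve in curves.values():
        qs = sorted(curve)
        best = max(qs, key=lambda q: (curve[q], -q))
        votes[best] = votes.get(best, 0) + 1
    return min(votes, key=lambda q: (-votes[q], q))
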