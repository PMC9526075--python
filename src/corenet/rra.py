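"""Robust rank aggregation over sub-threshold edge ranks; shared-network call.

An edge seen in k of N cluster networks has a vector of N-k normalized
ranks in the clusters where it fell below the threshold.  If the edge is
truly coexpressed everywhere, these leftover ranks should sit unusually
close to the top.  Each vector is scored by the beta order-statistic
method: with sorted ranks r_(1) <= ... <= r_(m),

    beta_j = P(Binomial(m, r_(j)) >= j),   rho = min_j beta_j,
    p = min(1, m * rho),

which is a valid (conservative) p-value under uniform ranks.  Per-edge
p-values are Bonferroni-corrected within a commonality group, combined by
Fisher's method, and Bonferroni-corrected across groups; the cutoff on the
group-level p defines the commonality threshold k* of the shared network.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import binom, chi2

from .containers import (
    ClusterNetwork,
    CommonalityTable,
    EdgeKey,
    RRAGroupResult,
    SharedNetwork,
)

__all__ = [
    "rra_pvalue",
    "sample_group_edges",
    "fisher_combine",
    "group_scan_and_cutoff",
]

_P_FLOOR = 1e-300


def rra_pvalue(normalized_ranks) -> float:
    """Aggregated significance of one normalized rank vector (values in (0,1])."""
    r = np.sort(np.asarray(normalized_ranks, dtype=float))
    m = r.size
    if m == 0:
        raise ValueError("empty rank vector")
    if np.any((r <= 0) | (r > 1)):
        raise ValueError("normalized ranks must lie in (0, 1]")
    j = np.arange(1, m + 1)
    beta = binom.sf(j - 1, m, r)  # P(Binom(m, r_(j)) >= j)
    rho = float(beta.min())
    return min(1.0, rho * m)


def sample_group_edges(
    commonality: CommonalityTable,
    k: int,
    max_n: int = 100,
    seed: int = 0,
) -> list[EdgeKey]:
    """Up to ``max_n`` edges of commonality group k, sampled without replacement.

    Groups with at most ``max_n`` members are returned whole (sorted);
    larger groups are sampled uniformly, deterministically in the seed.
    """
    group = sorted(e for e, kk in commonality.edge_k.items() if kk == k)
    if not group:
        return []
    if len(group) <= max_n:
        return group
    rng = np.random.default_rng(np.random.SeedSequence((seed, k)))
    idx = rng.choice(len(group), size=max_n, replace=False)
    return [group[i] for i in sorted(idx)]


def fisher_combine(p_values) -> tuple[float, int, float]:
    """Fisher's method: chi2 = -2 sum(ln p), df = 2m, upper-tail p.

    p-values of exactly 1 contribute 0 to the statistic; p <= 0 is an
    error (underflow should be floored upstream).
    """
    ps = np.asarray(list(p_values), dtype=float)
    if ps.size == 0:
        raise ValueError("no p-values to combine")
    if np.any(ps <= 0):
        raise ValueError("p-values must be in (0, 1]")
    ps = np.clip(ps, _P_FLOOR, 1.0)
    stat = float(-2.0 * np.sum(np.log(ps[ps < 1.0])))
    df = 2 * ps.size
    return stat, df, float(chi2.sf(stat, df))


def group_scan_and_cutoff(
    networks: dict[str, ClusterNetwork],
    rank_lookups: dict[str, dict[EdgeKey, float]],
    commonality: CommonalityTable,
    alpha: float = 0.01,
    max_sample: int = 100,
    seed: int = 0,
    combine_adjusted: bool = False,
    require_all_above: bool = True,
) -> tuple[dict[int, RRAGroupResult], int | None, SharedNetwork]:
    """Scan every observed commonality group and call the shared network.

    For each observed commonality k: sample edges, collect each edge's
    normalized ranks in the clusters where it is below threshold, score by
    :func:`rra_pvalue`, Bonferroni-correct within the group, combine by
    Fisher's method, and Bonferroni-correct across scanned groups.

    By default Fisher combines the *raw* per-edge p-values.  With few
    clusters the alternative (``combine_adjusted=True``, combining the
    Bonferroni-adjusted values) makes groups with one or two leftover
    clusters structurally unable to pass: the smallest possible per-edge p
    is about the threshold fraction q raised to the number of leftover
    clusters, so the within-group correction pins every adjusted value at
    1.  Combining raw values keeps the group statistic informative at any
    cluster count while the across-group Bonferroni still controls the
    group-level error.

    k* is the smallest k such that the group at k and every larger
    non-empty group pass ``group_p < alpha`` (with ``require_all_above=False``,
    simply the smallest passing k).  A group at k = N has no leftover
    clusters and passes vacuously.  The shared network contains *all* edges
    (sampled or not) with commonality >= k*; if no k passes it is empty.
    """
    if commonality.n_clusters < 2:
        raise ValueError("commonality must cover at least 2 clusters")
    if set(networks) != set(rank_lookups):
        raise ValueError("networks and rank_lookups must cover the same clusters")
    N = commonality.n_clusters
    labels = sorted(networks)
    observed_ks = sorted(set(commonality.edge_k.values()))
    results: dict[int, RRAGroupResult] = {}
    for k in observed_ks:
        edges = sample_group_edges(commonality, k, max_n=max_sample, seed=seed)
        if k == N:
            results[k] = RRAGroupResult(
                k=k, sampled_edges=edges, p_raw=[], p_adj=[],
                fisher_chi2=float("inf"), fisher_df=0, fisher_p=0.0,
                group_p_bonferroni=0.0,
            )
            continue
        p_raw: list[float] = []
        for e in edges:
            below = [lab for lab in labels if e not in networks[lab].edges]
            if len(below) != N - k:
                raise RuntimeError(
                    f"edge {e} has {N - len(below)} occurrences but commonality {k}"
                )
            ranks = [rank_lookups[lab][e] for lab in below]
            p_raw.append(rra_pvalue(ranks))
        m = len(p_raw)
        p_adj = [min(1.0, p * m) for p in p_raw]
        to_combine = p_adj if combine_adjusted else p_raw
        chi2_stat, df, fisher_p = fisher_combine(
            [max(p, _P_FLOOR) for p in to_combine]
        )
        results[k] = RRAGroupResult(
            k=k, sampled_edges=edges, p_raw=p_raw, p_adj=p_adj,
            fisher_chi2=chi2_stat, fisher_df=df, fisher_p=fisher_p,
            group_p_bonferroni=fisher_p,  # corrected below once n_groups known
        )
    n_groups = len(results)
    for res in results.values():
        res.group_p_bonferroni = min(1.0, res.fisher_p * n_groups)

    def passes(k: int) -> bool:
        return alpha >= 1.0 or results[k].group_p_bonferroni < alpha

    k_star: int | None = None
    if require_all_above:
        for k in observed_ks:
            if all(passes(kk) for kk in observed_ks if kk >= k):
                k_star = k
                break
    else:
        passing = [k for k in observed_ks if passes(k)]
        k_star = min(passing) if passing else None

    if k_star is None:
        shared = SharedNetwork(edges=set(), k_star=None)
    else:
        shared = SharedNetwork(
            edges={e for e, kk in commonality.edge_k.items() if kk >= k_star},
            k_star=k_star,
        )
    return results, k_star, shared
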