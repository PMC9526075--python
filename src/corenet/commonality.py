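"""Edge/gene commonality across cluster networks, with two nulls.

The *commonality* of an edge is the number of cluster networks containing
it; the commonality of a gene is the number of clusters in which it has at
least one edge.  Two null models say how large commonality should be if
each cluster picked its top-``q`` edges independently: an analytic
Binomial(N, q) per-edge null, and an empirical ensemble obtained by
degree-preserving rewiring of every cluster network.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom

from .containers import (
    BinomialNull,
    ClusterNetwork,
    CommonalityTable,
    EdgeInfo,
    EdgeKey,
)

__all__ = [
    "edge_and_gene_commonality",
    "binomial_null_pmf",
    "expected_pairs_at_least_one",
    "rewire_degree_preserving",
    "randomized_commonality_null",
    "NullEnsemble",
]


def edge_and_gene_commonality(networks: list[ClusterNetwork]) -> CommonalityTable:
    """Exact per-edge and per-gene commonality counts over the networks."""
    if not networks:
        raise ValueError("no networks given")
    universe = set(networks[0].gene_ids)
    for net in networks[1:]:
        if set(net.gene_ids) != universe:
            raise ValueError(
                f"gene universe mismatch between {networks[0].label!r} and {net.label!r}"
            )
    edge_k: dict[EdgeKey, int] = {}
    gene_k: dict[str, int] = {}
    for net in networks:
        genes_here: set[str] = set()
        for e in net.edges:
            edge_k[e] = edge_k.get(e, 0) + 1
            genes_here.add(e.gene_a)
            genes_here.add(e.gene_b)
        for g in genes_here:
            gene_k[g] = gene_k.get(g, 0) + 1
    return CommonalityTable(n_clusters=len(networks), edge_k=edge_k, gene_k=gene_k)


def binomial_null_pmf(n_clusters: int, p: float) -> BinomialNull:
    """Binomial(N, p) pmf over commonality k = 0..N, computed in log space.

    Under random edge selection each pair enters any one cluster network
    independently with probability p (the threshold fraction), so its
    commonality is Binomial(N, p).
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    k = np.arange(n_clusters + 1)
    with np.errstate(divide="ignore"):
        pmf = np.exp(binom.logpmf(k, n_clusters, p))
    pmf /= pmf.sum()
    return BinomialNull(n_clusters=n_clusters, p=p, pmf=pmf)


def expected_pairs_at_least_one(
    n_genes: int,
    n_clusters: int,
    p: float,
    survival_decimals: int | None = 4,
) -> int:
    """Expected number of pairs with commonality >= 1 under the binomial null.

    ``C(n_genes, 2) * (1 - q0)`` with ``q0 = (1-p)^N``.  By default q0 is
    truncated to ``survival_decimals`` decimal places before use, matching
    the convention of quoting the miss probability to 4 decimals;
    ``survival_decimals=None`` uses full precision.
    """
    if n_genes < 2:
        raise ValueError("n_genes must be >= 2")
    q0 = (1.0 - p) ** n_clusters
    if survival_decimals is not None:
        scale = 10**survival_decimals
        q0 = math.floor(q0 * scale) / scale
    n_pairs = math.comb(n_genes, 2)
    return int(round(n_pairs * (1.0 - q0)))


def _rewire_edge_list(
    edges: list[tuple[int, int]],
    n_swaps: int,
    rng: np.random.Generator,
    max_attempt_factor: int = 100,
) -> tuple[list[tuple[int, int]], int]:
    """Double-edge-swap Markov chain on an integer edge list.

    Attempts that would create a self-loop or duplicate edge are rejected.
    Returns the rewired edge list and the number of accepted swaps.
    """
    E = len(edges)
    edge_list = [tuple(sorted(e)) for e in edges]
    edge_set = set(edge_list)
    accepted = 0
    attempts = 0
    max_attempts = max(max_attempt_factor * max(n_swaps, 1), 1000)
    while accepted < n_swaps and attempts < max_attempts:
        attempts += 1
        i, j = rng.integers(0, E, size=2)
        if i == j:
            continue
        a, b = edge_list[i]
        c, d = edge_list[j]
        if rng.random() < 0.5:
            c, d = d, c
        # proposed: (a, c), (b, d)
        if a == c or b == d:
            continue
        e1 = (a, c) if a < c else (c, a)
        e2 = (b, d) if b < d else (d, b)
        if e1 in edge_set or e2 in edge_set:
            continue
        edge_set.discard(edge_list[i])
        edge_set.discard(edge_list[j])
        edge_set.add(e1)
        edge_set.add(e2)
        edge_list[i] = e1
        edge_list[j] = e2
        accepted += 1
    return edge_list, accepted


def rewire_degree_preserving(
    network: ClusterNetwork,
    n_swaps: int | None = None,
    seed: int = 0,
) -> ClusterNetwork:
    """Randomize edges by double-edge swaps, keeping every gene's degree.

    Defaults to ``10 x |E|`` accepted swaps.  If no valid swap exists (e.g.
    a triangle), the input is returned unchanged with a warning.  The
    rewired network carries no meaningful correlations: edges get
    ``abs_corr = nan`` and ranks in canonical order.
    """
    edges = list(network.edges)
    if not edges:
        raise ValueError("cannot rewire an empty network")
    if n_swaps is None:
        n_swaps = 10 * len(edges)
    rng = np.random.default_rng(seed)
    pos = {g: i for i, g in enumerate(network.gene_ids)}
    int_edges = [(pos[e.gene_a], pos[e.gene_b]) for e in edges]
    rewired, accepted = _rewire_edge_list(int_edges, n_swaps, rng)
    if accepted == 0:
        warnings.warn(
            f"network {network.label!r}: no swappable edge pair found; returned unchanged"
        )
        return network
    genes = network.gene_ids
    new_edges = sorted(EdgeKey(genes[a], genes[b]) for a, b in rewired)
    return ClusterNetwork(
        label=network.label,
        gene_ids=list(genes),
        edges={
            e: EdgeInfo(abs_corr=float("nan"), rank=i + 1)
            for i, e in enumerate(new_edges)
        },
        q=network.q,
    )


@dataclass
class NullEnsemble:
    """Edge-commonality histograms from repeated rewiring of all networks."""

    n_clusters: int
    histograms: list[np.ndarray]
    mean_hist: np.ndarray = field(init=False)
    max_commonality: int = field(init=False)

    def __post_init__(self) -> None:
        H = np.vstack(self.histograms)
        self.mean_hist = H.mean(axis=0)
        nonzero = [int(np.max(np.nonzero(h)[0])) if h.any() else 0 for h in self.histograms]
        self.max_commonality = max(nonzero)

    def envelope(self) -> tuple[np.ndarray, np.ndarray]:
        H = np.vstack(self.histograms)
        return H.min(axis=0), H.max(axis=0)


def randomized_commonality_null(
    networks: list[ClusterNetwork],
    n_reps: int = 100,
    seed: int = 0,
    n_swaps: int | None = None,
) -> NullEnsemble:
    """Null commonality histograms: each rep rewires every network independently."""
    if len(networks) < 2:
        raise ValueError("need at least 2 networks")
    hists = []
    for rep in range(n_reps):
        rewired = []
        for i, net in enumerate(networks):
            child_seed = int(
                np.random.SeedSequence((seed, rep, i)).generate_state(1)[0] % (2**31)
            )
            rewired.append(rewire_degree_preserving(net, n_swaps=n_swaps, seed=child_seed))
        table = edge_and_gene_commonality(rewired)
        hists.append(table.histogram())
    return NullEnsemble(n_clusters=len(networks), histograms=hists)
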