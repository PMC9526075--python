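"""Topology of the shared network: clustering coefficient and modules.

The global clustering coefficient (transitivity) of the shared network is
compared against an ensemble of degree-preserving rewirings; communities
are found by short-random-walk (walktrap) agglomeration with a modularity
cut and a minimum module size.
"""

from __future__ import annotations

import igraph as ig
import networkx as nx
import numpy as np

from .commonality import rewire_degree_preserving
from .containers import ClusterNetwork, EdgeInfo, EdgeKey, ModulePartition, SharedNetwork

__all__ = [
    "to_networkx",
    "clustering_coefficient",
    "clustering_null_ensemble",
    "detect_modules",
]


def to_networkx(net: SharedNetwork | ClusterNetwork) -> nx.Graph:
    g = nx.Graph()
    edges = net.edges if isinstance(net.edges, set) else set(net.edges)
    g.add_edges_from((e.gene_a, e.gene_b) for e in edges)
    return g


def clustering_coefficient(net) -> float:
    """Global transitivity: 3 x triangles / connected triples (0 if none)."""
    g = net if isinstance(net, nx.Graph) else to_networkx(net)
    if g.number_of_nodes() < 3:
        raise ValueError("need at least 3 nodes")
    return float(nx.transitivity(g))


def mean_local_clustering(net) -> float:
    """Mean of per-node local clustering coefficients (alternative measure)."""
    g = net if isinstance(net, nx.Graph) else to_networkx(net)
    return float(nx.average_clustering(g))


def _as_cluster_network(net: SharedNetwork) -> ClusterNetwork:
    genes = sorted(net.genes)
    edges = sorted(net.edges)
    return ClusterNetwork(
        label=getattr(net, "label", "shared"),
        gene_ids=genes,
        edges={e: EdgeInfo(abs_corr=float("nan"), rank=i + 1) for i, e in enumerate(edges)},
        q=0.0,
    )


def clustering_null_ensemble(
    net: SharedNetwork | ClusterNetwork,
    n_reps: int = 100,
    seed: int = 0,
    n_swaps: int | None = None,
) -> dict:
    """Transitivity of degree-preserving rewirings of the network.

    Every rewired graph has the same gene set, edge count, and degree
    multiset as the input.  Returns the per-rep values plus summary stats.
    """
    cn = net if isinstance(net, ClusterNetwork) else _as_cluster_network(net)
    values = []
    for rep in range(n_reps):
        child_seed = int(np.random.SeedSequence((seed, rep)).generate_state(1)[0] % (2**31))
        rewired = rewire_degree_preserving(cn, n_swaps=n_swaps, seed=child_seed)
        values.append(clustering_coefficient(rewired))
    arr = np.array(values)
    return {
        "values": arr,
        "mean": float(arr.mean()),
        "min": float(arr.min()),
        "max": float(arr.max()),
    }


def detect_modules(
    net: SharedNetwork | ClusterNetwork,
    steps: int = 4,
    min_size: int = 5,
) -> ModulePartition:
    """Walktrap community detection with a modularity cut, per component.

    Modules are re-indexed 1..M by decreasing size; genes in communities
    smaller than ``min_size`` land in the unassigned bucket.  Deterministic
    for a given network (the random-walk distances are computed exactly).
    """
    g = to_networkx(net)
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    communities: list[set[str]] = []
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        nodes = sorted(sub.nodes())
        if len(nodes) == 1:
            communities.append(set(nodes))
            continue
        idx = {n: i for i, n in enumerate(nodes)}
        igg = ig.Graph(
            n=len(nodes),
            edges=[(idx[u], idx[v]) for u, v in sorted(sub.edges())],
            directed=False,
        )
        clustering = igg.community_walktrap(steps=steps).as_clustering()
        for block in clustering:
            communities.append({nodes[i] for i in block})
    communities.sort(key=lambda c: (-len(c), min(c)))
    assignment: dict[str, int] = {}
    unassigned: set[str] = set()
    next_id = 1
    for comm in communities:
        if len(comm) >= min_size:
            for gname in comm:
                assignment[gname] = next_id
            next_id += 1
        else:
            unassigned |= comm
    return ModulePartition(assignment=assignment, unassigned=unassigned, min_size=min_size)
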