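"""Core network: the edge-set intersection of shared networks across datasets."""

from __future__ import annotations

from .containers import CoreNetwork, SharedNetwork

__all__ = ["intersect_networks"]


def intersect_networks(networks: list[SharedNetwork], min_datasets: int | None = None) -> CoreNetwork:
    """Intersect shared-network edge sets; genes are induced from surviving edges.

    By default an edge must occur in every input.  ``min_datasets`` relaxes
    this to edges present in at least that many inputs (partial core).
    """
    if not networks:
        raise ValueError("need at least one shared network")
    if len(networks) < 2:
        raise ValueError("need at least 2 shared networks to intersect")
    if min_datasets is None:
        edges = set.intersection(*(set(n.edges) for n in networks))
    else:
        if not 1 <= min_datasets <= len(networks):
            raise ValueError("min_datasets out of range")
        counts: dict = {}
        for n in networks:
            for e in n.edges:
                counts[e] = counts.get(e, 0) + 1
        edges = {e for e, c in counts.items() if c >= min_datasets}
    return CoreNetwork(edges=edges, provenance=[n.label for n in networks])
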