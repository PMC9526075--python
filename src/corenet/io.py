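"""Plain-text readers/writers for every on-disk artifact.

Count matrices use the 10x-style triplet (Matrix Market ``matrix.mtx`` +
``features.tsv`` + ``barcodes.tsv``; ``.gz`` accepted) with cluster labels
in a separate two-column TSV.  Networks, commonality tables, and results
travel as TSV with full-precision floats so every read/write round trip is
exact.
"""

from __future__ import annotations

import gzip
import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import (
    ClusterNetwork,
    CommonalityTable,
    CountMatrix,
    EdgeInfo,
    EdgeKey,
    SharedNetwork,
)

__all__ = [
    "read_counts",
    "write_counts",
    "read_edge_list",
    "write_edge_list",
    "read_shared_network",
    "write_shared_network",
    "read_commonality",
    "write_commonality",
]

_FLOAT_FMT = "%.17g"


def _open_maybe_gz(path):
    path = os.fspath(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _read_lines(path, what: str) -> list[str]:
    with _open_maybe_gz(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty {what} file")
    return lines


def read_counts(
    matrix_path,
    features_path,
    barcodes_path,
    clusters_path,
    mito_path=None,
    mito_prefix: tuple[str, ...] = ("mt:", "MT-", "mt-"),
) -> CountMatrix:
    """Assemble a CountMatrix from the 10x-style triplet plus cluster labels.

    ``features.tsv`` may have extra columns (10x id/name/type); the first
    column is the gene id.  ``clusters.tsv`` needs header columns
    ``cell_id`` and ``cluster`` covering every barcode exactly.  The
    mitochondrial subset comes from ``mito_path`` (one gene per line) when
    given, else from gene-id prefix matching.
    """
    try:
        mat = scipy.io.mmread(os.fspath(matrix_path))
    except Exception as err:
        raise ValueError(f"{matrix_path}: not a readable Matrix Market file: {err}") from err
    mat = sp.coo_matrix(mat)
    if mat.nnz:
        if np.any(mat.data < 0):
            raise ValueError(f"{matrix_path}: negative count entries")
        if not np.allclose(mat.data, np.round(mat.data)):
            raise ValueError(f"{matrix_path}: non-integer count entries")

    gene_ids = [ln.split("\t")[0] for ln in _read_lines(features_path, "features")]
    cell_ids = [ln.split("\t")[0] for ln in _read_lines(barcodes_path, "barcodes")]
    if mat.shape != (len(gene_ids), len(cell_ids)):
        raise ValueError(
            f"{matrix_path}: header says {mat.shape[0]} x {mat.shape[1]} but "
            f"features/barcodes list {len(gene_ids)} genes and {len(cell_ids)} cells"
        )

    clusters = pd.read_csv(clusters_path, sep="\t", dtype=str)
    for col in ("cell_id", "cluster"):
        if col not in clusters.columns:
            raise ValueError(f"{clusters_path}: missing column {col!r}")
    if clusters["cell_id"].duplicated().any():
        dup = clusters.loc[clusters["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise ValueError(f"{clusters_path}: duplicate cell id {dup!r}")
    cluster_of = dict(zip(clusters["cell_id"], clusters["cluster"]))
    unlabeled = [c for c in cell_ids if c not in cluster_of]
    if unlabeled:
        raise ValueError(
            f"{clusters_path}: {len(unlabeled)} cells lack a cluster label "
            f"(first: {unlabeled[0]!r})"
        )
    unknown = set(cluster_of) - set(cell_ids)
    if unknown:
        raise ValueError(
            f"{clusters_path}: labels for unknown cells (first: {sorted(unknown)[0]!r})"
        )

    if mito_path is not None:
        mito = frozenset(_read_lines(mito_path, "mito gene")) if os.path.getsize(mito_path) else frozenset()
    else:
        mito = frozenset(g for g in gene_ids if g.startswith(mito_prefix))
    return CountMatrix(
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        counts=sp.csr_matrix(mat.astype(np.int64)),
        cluster_of=cluster_of,
        mito_genes=mito,
    )


def write_counts(cm: CountMatrix, out_dir) -> dict[str, Path]:
    """Write the triplet + clusters.tsv + mito_genes.txt into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "matrix.mtx",
        "features": out / "features.tsv",
        "barcodes": out / "barcodes.tsv",
        "clusters": out / "clusters.tsv",
        "mito": out / "mito_genes.txt",
    }
    scipy.io.mmwrite(os.fspath(paths["matrix"]), sp.coo_matrix(cm.counts), field="integer")
    paths["features"].write_text("".join(f"{g}\t{g}\tGene Expression\n" for g in cm.gene_ids))
    paths["barcodes"].write_text("".join(f"{c}\n" for c in cm.cell_ids))
    with open(paths["clusters"], "w") as fh:
        fh.write("cell_id\tcluster\n")
        for c in cm.cell_ids:
            fh.write(f"{c}\t{cm.cluster_of[c]}\n")
    paths["mito"].write_text("".join(f"{g}\n" for g in sorted(cm.mito_genes)))
    return paths


def read_counts_dir(dir_path) -> CountMatrix:
    d = Path(dir_path)
    return read_counts(
        d / "matrix.mtx", d / "features.tsv", d / "barcodes.tsv", d / "clusters.tsv",
        mito_path=(d / "mito_genes.txt") if (d / "mito_genes.txt").exists() else None,
    )


def write_edge_list(network: ClusterNetwork, path) -> None:
    """TSV: gene_a, gene_b, abs_corr (full precision), rank."""
    edges = sorted(network.edges.items(), key=lambda kv: kv[1].rank)
    with open(path, "w") as fh:
        fh.write(f"# label={network.label}\tq={_FLOAT_FMT % network.q}\tn_genes={network.n_genes}\n")
        fh.write("gene_a\tgene_b\tabs_corr\trank\n")
        for e, info in edges:
            fh.write(f"{e.gene_a}\t{e.gene_b}\t{_FLOAT_FMT % info.abs_corr}\t{info.rank}\n")


def read_edge_list(path, gene_ids: list[str] | None = None) -> ClusterNetwork:
    """Read a cluster network written by :func:`write_edge_list`.

    Rows with a non-canonical pair order (gene_a >= gene_b) are rejected
    with their line number.
    """
    label, q, n_genes = "", float("nan"), None
    edges: dict[EdgeKey, EdgeInfo] = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    start = 0
    if lines and lines[0].startswith("#"):
        meta = dict(
            item.split("=", 1) for item in lines[0][1:].strip().split("\t") if "=" in item
        )
        label = meta.get("label", "")
        q = float(meta.get("q", "nan"))
        n_genes = int(meta["n_genes"]) if "n_genes" in meta else None
        start = 1
    if start >= len(lines) or lines[start].split("\t") != ["gene_a", "gene_b", "abs_corr", "rank"]:
        raise ValueError(f"{path}: missing edge-list header")
    for ln, line in enumerate(lines[start + 1 :], start + 2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise ValueError(f"{path}:{ln}: expected 4 columns")
        a, b, r, rank = parts
        if a >= b:
            raise ValueError(f"{path}:{ln}: non-canonical pair ({a!r}, {b!r})")
        key = EdgeKey(a, b)
        if key in edges:
            raise ValueError(f"{path}:{ln}: duplicate edge ({a!r}, {b!r})")
        edges[key] = EdgeInfo(abs_corr=float(r), rank=int(rank))
    if gene_ids is None:
        genes = sorted({g for e in edges for g in e.genes()})
    else:
        genes = list(gene_ids)
    return ClusterNetwork(label=label, gene_ids=genes, edges=edges, q=q)


def write_shared_network(net: SharedNetwork, path) -> None:
    with open(path, "w") as fh:
        k = "" if net.k_star is None else str(net.k_star)
        fh.write(f"# label={net.label}\tk_star={k}\n")
        fh.write("gene_a\tgene_b\n")
        for e in sorted(net.edges):
            fh.write(f"{e.gene_a}\t{e.gene_b}\n")


def read_shared_network(path) -> SharedNetwork:
    with open(path) as fh:
        lines = fh.read().splitlines()
    label, k_star = "shared", None
    start = 0
    if lines and lines[0].startswith("#"):
        meta = dict(
            item.split("=", 1) for item in lines[0][1:].strip().split("\t") if "=" in item
        )
        label = meta.get("label", "shared")
        k_star = int(meta["k_star"]) if meta.get("k_star") else None
        start = 1
    if start >= len(lines) or lines[start].split("\t") != ["gene_a", "gene_b"]:
        raise ValueError(f"{path}: missing shared-network header")
    edges = set()
    for ln, line in enumerate(lines[start + 1 :], start + 2):
        if not line.strip():
            continue
        a, b = line.split("\t")
        if a >= b:
            raise ValueError(f"{path}:{ln}: non-canonical pair ({a!r}, {b!r})")
        edges.add(EdgeKey(a, b))
    return SharedNetwork(edges=edges, k_star=k_star, label=label)


def write_commonality(table: CommonalityTable, edge_path, gene_path) -> None:
    with open(edge_path, "w") as fh:
        fh.write(f"# n_clusters={table.n_clusters}\n")
        fh.write("gene_a\tgene_b\tk\n")
        for e in sorted(table.edge_k):
            fh.write(f"{e.gene_a}\t{e.gene_b}\t{table.edge_k[e]}\n")
    with open(gene_path, "w") as fh:
        fh.write(f"# n_clusters={table.n_clusters}\n")
        fh.write("gene\tk\n")
        for g in sorted(table.gene_k):
            fh.write(f"{g}\t{table.gene_k[g]}\n")


def read_commonality(edge_path, gene_path) -> CommonalityTable:
    def _meta_n(path) -> int:
        with open(path) as fh:
            first = fh.readline()
        if not first.startswith("# n_clusters="):
            raise ValueError(f"{path}: missing n_clusters header")
        return int(first.split("=", 1)[1])

    n = _meta_n(edge_path)
    if _meta_n(gene_path) != n:
        raise ValueError("edge and gene tables disagree on n_clusters")
    edges = pd.read_csv(edge_path, sep="\t", comment="#")
    genes = pd.read_csv(gene_path, sep="\t", comment="#")
    edge_k = {
        EdgeKey(a, b): int(k) for a, b, k in zip(edges.gene_a, edges.gene_b, edges.k)
    }
    gene_k = {g: int(k) for g, k in zip(genes.gene, genes.k)}
    return CommonalityTable(n_clusters=n, edge_k=edge_k, gene_k=gene_k)
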