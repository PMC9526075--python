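"""Synthetic multi-cluster UMI count data with planted coexpression.

The generator emulates the statistical structure of droplet single-cell
atlases: many cell clusters, overdispersed sparse counts, per-cell library
size variation, a mitochondrial gene subset, and gene-gene correlation
induced by latent per-cell module activities.  A set of *shared* modules is
planted identically in every cluster (the ground-truth "core"), and each
cluster additionally carries its own cluster-specific modules.

Counts for gene g in cell j of cluster c are drawn as

    mu_gj = exp(b_g + lambda * a_m(j)) * L_j        (g in module m)
    mu_gj = exp(b_g) * L_j                          (otherwise)
    x_gj ~ NegativeBinomial(mean=mu_gj, dispersion=r)

with b_g ~ Normal(baseline_log_mean, baseline_log_sd) drawn once per
dataset, module activity a_m(j) ~ Normal(0,1) per cell, and library factor
L_j log-normal.  Sparsity is controlled by ``baseline_log_mean``;
within-module correlation by ``loading_strength``.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import scipy.sparse as sp

from .containers import CountMatrix, EdgeKey

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "generate_dataset",
    "inject_qc_violations",
]


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic dataset generator (defaults = study conditions)."""

    n_clusters: int = 10
    cells_per_cluster: int = 300
    n_genes: int = 300
    n_shared_modules: int = 4
    n_specific_modules_per_cluster: int = 2
    module_size: int = 10
    loading_strength: float = 1.2
    baseline_log_mean: float = 0.3
    baseline_log_sd: float = 0.4
    nb_dispersion: float = 2.0
    library_size_log_sd: float = 0.3
    mito_fraction_mean: float = 0.05
    n_mito_genes: int = 5
    seed: int = 1

    def validate(self) -> None:
        if self.n_clusters < 1 or self.cells_per_cluster < 1 or self.n_genes < 2:
            raise ValueError("n_clusters, cells_per_cluster >= 1 and n_genes >= 2 required")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.loading_strength < 0:
            raise ValueError("loading_strength must be >= 0")
        if not 0 <= self.mito_fraction_mean <= 1:
            raise ValueError("mito_fraction_mean must be in [0,1]")
        if self.n_mito_genes < 0 or self.n_mito_genes >= self.n_genes:
            raise ValueError("n_mito_genes must be in [0, n_genes)")
        n_mod = self.n_shared_modules + self.n_specific_modules_per_cluster
        if self.module_size * n_mod > self.n_genes - self.n_mito_genes:
            raise ValueError(
                "module_size x (n_shared_modules + n_specific_modules_per_cluster) "
                "exceeds the available (non-mitochondrial) gene pool"
            )

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Ground truth of one generated dataset."""

    shared_edges: set[EdgeKey]
    specific_edges: dict[str, set[EdgeKey]]
    config: GeneratorConfig
    zero_fraction: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for c, es in self.specific_edges.items():
            if self.shared_edges & es:
                raise ValueError(f"shared and specific edges overlap in cluster {c}")

    def to_json(self, path) -> None:
        payload = {
            "shared_edges": sorted([e.genes() for e in self.shared_edges]),
            "specific_edges": {
                c: sorted([e.genes() for e in es])
                for c, es in sorted(self.specific_edges.items())
            },
            "config": asdict(self.config),
            "zero_fraction": self.zero_fraction,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            shared_edges={EdgeKey(a, b) for a, b in payload["shared_edges"]},
            specific_edges={
                c: {EdgeKey(a, b) for a, b in es}
                for c, es in payload["specific_edges"].items()
            },
            config=GeneratorConfig.from_dict(payload["config"]),
            zero_fraction=payload.get("zero_fraction", {}),
        )


def _module_edges(genes: list[str]) -> set[EdgeKey]:
    return {EdgeKey(a, b) for a, b in itertools.combinations(genes, 2)}


def _cluster_rng(seed: int, cluster_index: int) -> np.random.Generator:
    # substream 0 is reserved for dataset-level draws
    return np.random.default_rng(np.random.SeedSequence((seed, 1 + cluster_index)))


def generate_dataset(config: GeneratorConfig) -> tuple[CountMatrix, SyntheticTruth]:
    """Generate a multi-cluster count matrix plus its planted ground truth.

    Deterministic given ``config.seed``; per-cluster draws come from
    substreams derived from the seed and the cluster index.
    """
    config.validate()
    G, M = config.n_genes, config.n_mito_genes
    n_body = G - M
    gene_ids = [f"g{i:04d}" for i in range(n_body)] + [
        f"mt:g{n_body + i:04d}" for i in range(M)
    ]
    mito_genes = frozenset(gene_ids[n_body:])

    rng0 = np.random.default_rng(np.random.SeedSequence((config.seed, 0)))
    baseline = rng0.normal(config.baseline_log_mean, config.baseline_log_sd, G)

    # shared modules occupy the first genes of the non-mito pool
    s = config.module_size
    shared_members = [
        list(range(m * s, (m + 1) * s)) for m in range(config.n_shared_modules)
    ]
    shared_gene_idx = [i for mem in shared_members for i in mem]
    pool = np.array(
        [i for i in range(n_body) if i not in set(shared_gene_idx)], dtype=np.int64
    )

    # mito baselines chosen so mito genes carry ~mito_fraction_mean of counts
    lam2 = 0.5 * config.loading_strength**2
    exp_mean = np.exp(baseline[:n_body]).copy()
    exp_mean[shared_gene_idx] *= np.exp(lam2)
    if M:
        f = config.mito_fraction_mean
        target = (f / (1.0 - f)) * exp_mean.sum() if f < 1 else exp_mean.sum() * 1e6
        baseline[n_body:] = np.log(max(target, 1e-12) / M)

    cluster_labels = [f"cluster{c:02d}" for c in range(config.n_clusters)]
    blocks: list[np.ndarray] = []
    cell_ids: list[str] = []
    cluster_of: dict[str, str] = {}
    specific_edges: dict[str, set[EdgeKey]] = {}
    zero_fraction: dict[str, float] = {}

    for c, label in enumerate(cluster_labels):
        rng = _cluster_rng(config.seed, c)
        n = config.cells_per_cluster
        # cluster-specific modules drawn from the non-shared, non-mito pool
        n_spec = config.n_specific_modules_per_cluster
        spec_idx = rng.choice(pool, size=n_spec * s, replace=False) if n_spec else np.array([], int)
        spec_members = [list(spec_idx[m * s : (m + 1) * s]) for m in range(n_spec)]
        specific_edges[label] = set().union(
            *(_module_edges([gene_ids[i] for i in mem]) for mem in spec_members)
        ) if n_spec else set()

        members = shared_members + spec_members
        log_mu = np.tile(baseline[:, None], (1, n))
        for mem in members:
            activity = rng.normal(0.0, 1.0, n)
            log_mu[mem, :] += config.loading_strength * activity[None, :]
        lib = np.exp(rng.normal(0.0, config.library_size_log_sd, n))
        mu = np.exp(log_mu) * lib[None, :]
        r = config.nb_dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
        blocks.append(counts)
        zero_fraction[label] = float(np.mean(counts == 0))
        for j in range(n):
            cid = f"{label}_c{j:04d}"
            cell_ids.append(cid)
            cluster_of[cid] = label

    counts_all = sp.csr_matrix(np.hstack(blocks))
    cm = CountMatrix(
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        counts=counts_all,
        cluster_of=cluster_of,
        mito_genes=mito_genes,
    )
    shared = set().union(
        *(_module_edges([gene_ids[i] for i in mem]) for mem in shared_members)
    ) if shared_members else set()
    truth = SyntheticTruth(
        shared_edges=shared,
        specific_edges=specific_edges,
        config=config,
        zero_fraction=zero_fraction,
    )
    return cm, truth


def inject_qc_violations(
    cm: CountMatrix,
    n_low_gene_cells: int = 0,
    n_low_umi_cells: int = 0,
    n_high_mito_cells: int = 0,
    seed: int = 0,
    min_genes: int = 200,
    min_umi: int = 500,
    mito_fraction: float = 0.35,
) -> tuple[CountMatrix, dict[str, list[str]]]:
    """Mutate randomly chosen cells so each violates exactly one QC rule.

    Returns a modified copy and a mapping rule -> mutated cell ids.  Cells
    that cannot be made to violate the requested rule (e.g. too few genes in
    the dataset for a low-gene mutation to apply) are skipped with a warning.
    """
    total = n_low_gene_cells + n_low_umi_cells + n_high_mito_cells
    if total > cm.n_cells:
        raise ValueError("requested more violations than available cells")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(cm.n_cells, size=total, replace=False)
    groups = {
        "low_gene": chosen[:n_low_gene_cells],
        "low_umi": chosen[n_low_gene_cells : n_low_gene_cells + n_low_umi_cells],
        "high_mito": chosen[n_low_gene_cells + n_low_umi_cells :],
    }
    dense = np.asarray(cm.counts.todense())
    mito_idx = np.array(
        [i for i, g in enumerate(cm.gene_ids) if g in cm.mito_genes], dtype=np.int64
    )
    body_idx = np.array(
        [i for i in range(cm.n_genes) if i not in set(mito_idx.tolist())], dtype=np.int64
    )
    report: dict[str, list[str]] = {"low_gene": [], "low_umi": [], "high_mito": []}

    for j in groups["low_gene"]:
        col = dense[:, j]
        nz = np.flatnonzero(col)
        if nz.size < min_genes:
            warnings.warn(f"cell {cm.cell_ids[j]} already below the gene threshold; skipped")
            continue
        keep_n = min_genes - 1
        keep = nz[np.argsort(col[nz])[::-1][:keep_n]]
        keep = np.array([i for i in keep if i not in set(mito_idx.tolist())], dtype=np.int64)
        new = np.zeros_like(col)
        new[keep] = col[keep]
        deficit = min_umi - int(new.sum())
        if deficit > 0 and keep.size:
            new[keep[0]] += deficit
        dense[:, j] = new
        report["low_gene"].append(cm.cell_ids[j])

    for j in groups["low_umi"]:
        if body_idx.size < min_genes or min_genes >= min_umi:
            warnings.warn(f"cannot build a low-UMI violation for cell {cm.cell_ids[j]}; skipped")
            continue
        new = np.zeros(cm.n_genes, dtype=np.int64)
        new[body_idx[:min_genes]] = 1
        dense[:, j] = new
        report["low_umi"].append(cm.cell_ids[j])

    for j in groups["high_mito"]:
        if mito_idx.size == 0 or body_idx.size < min_genes:
            warnings.warn(f"cannot build a high-mito violation for cell {cm.cell_ids[j]}; skipped")
            continue
        per_gene = int(np.ceil(min_umi * (1 - mito_fraction) / min_genes))
        new = np.zeros(cm.n_genes, dtype=np.int64)
        new[body_idx[:min_genes]] = per_gene
        body_total = int(new.sum())
        m_total = int(np.round(mito_fraction / (1 - mito_fraction) * body_total))
        while m_total / (m_total + body_total) <= mito_fraction:
            m_total += 1
        base, extra = divmod(m_total, mito_idx.size)
        new[mito_idx] = base
        new[mito_idx[:extra]] += 1
        dense[:, j] = new
        report["high_mito"].append(cm.cell_ids[j])

    out = CountMatrix(
        gene_ids=list(cm.gene_ids),
        cell_ids=list(cm.cell_ids),
        counts=sp.csr_matrix(dense),
        cluster_of=dict(cm.cluster_of),
        mito_genes=cm.mito_genes,
    )
    return out, report
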