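"""Gene-set and gene-age enrichment for network modules.

Gene-set enrichment is an exact one-sided hypergeometric test per set with
Bonferroni correction over the sets tested for one module.  Evolutionary
age enrichment uses a permutation scheme: module-sized gene samples are
drawn uniformly from the background, and the empirical p per age stratum
is the fraction of permutations whose stratum count strictly exceeds the
observed one.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "PHYLOSTRATA",
    "hypergeom_enrichment",
    "age_permutation_enrichment",
    "read_gene_sets",
    "read_age_table",
]

# ordered oldest -> youngest
PHYLOSTRATA = [
    "CellLife",
    "Eukaryota",
    "Opisthokonta",
    "Metazoa",
    "Eumetazoa",
    "Bilateria",
    "Protostomia",
    "Arthropoda",
    "Pancrustacea",
    "Insecta",
    "Diptera",
    "Drosophila",
]


def hypergeom_enrichment(
    module_genes,
    gene_sets: dict[str, set[str]],
    background,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of each set in the module.

    Sets are intersected with the background before testing; the module
    must be a subset of the background.  Bonferroni correction multiplies
    by the number of sets tested for this module.
    """
    background = set(background)
    if not background:
        raise ValueError("empty background")
    module = set(module_genes)
    if not module <= background:
        raise ValueError("module genes must be a subset of the background")
    B, m = len(background), len(module)
    rows = []
    n_tests = len(gene_sets)
    for name in sorted(gene_sets):
        members = set(gene_sets[name]) & background
        obs = len(module & members)
        # P(X >= obs) for X ~ Hypergeom(B, |set|, m)
        p = float(hypergeom.sf(obs - 1, B, len(members), m)) if members else 1.0
        p = min(1.0, p)
        p_adj = min(1.0, p * n_tests)
        rows.append(
            {
                "unit": name,
                "observed": obs,
                "set_size": len(members),
                "module_size": m,
                "background_size": B,
                "p": p,
                "p_adj": p_adj,
                "significant": p_adj < alpha,
            }
        )
    return pd.DataFrame(rows)


def age_permutation_enrichment(
    module_genes,
    ages: dict[str, str],
    background,
    n_perm: int = 1000,
    alpha: float = 0.01,
    seed: int = 0,
    strict: bool = True,
) -> pd.DataFrame:
    """Permutation enrichment of evolutionary age strata in a module.

    Unannotated genes are excluded from both the observed counts and the
    null draws.  Each permutation samples (number of annotated module
    genes) genes uniformly without replacement from the annotated
    background; the empirical p per stratum is the fraction of
    permutations with a *strictly larger* count than observed
    (``strict=False`` uses >=, the conservative convention).
    """
    background = set(background)
    module = set(module_genes)
    if not module <= background:
        raise ValueError("module genes must be a subset of the background")
    ann_bg = sorted(g for g in background if g in ages)
    if not ann_bg:
        raise ValueError("no annotated genes in the background")
    strata = [s for s in PHYLOSTRATA if any(ages[g] == s for g in ann_bg)]
    extra = sorted({ages[g] for g in ann_bg} - set(PHYLOSTRATA))
    strata += extra
    code = {s: i for i, s in enumerate(strata)}
    bg_codes = np.array([code[ages[g]] for g in ann_bg], dtype=np.int64)
    ann_mod = [g for g in module if g in ages]
    m = len(ann_mod)
    if m == 0:
        raise ValueError("no annotated genes in the module")
    obs = np.bincount([code[ages[g]] for g in ann_mod], minlength=len(strata))

    rng = np.random.default_rng(seed)
    B = len(ann_bg)
    keys = rng.random((n_perm, B))
    picks = np.argpartition(keys, m - 1, axis=1)[:, :m]
    perm_codes = bg_codes[picks]
    null_counts = np.stack(
        [np.bincount(row, minlength=len(strata)) for row in perm_codes]
    )
    if strict:
        exceed = (null_counts > obs[None, :]).sum(axis=0)
    else:
        exceed = (null_counts >= obs[None, :]).sum(axis=0)
    p = exceed / n_perm
    rows = []
    for s in strata:
        i = code[s]
        rows.append(
            {
                "unit": s,
                "observed": int(obs[i]),
                "module_size": m,
                "background_size": B,
                "null_mean": float(null_counts[:, i].mean()),
                "p": float(p[i]),
                "significant": bool(p[i] < alpha),
            }
        )
    return pd.DataFrame(rows)


def read_gene_sets(path) -> dict[str, set[str]]:
    """GMT-like TSV: set name, description, then member genes."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: expected name, description, genes")
            name = parts[0]
            if name in sets:
                raise ValueError(f"{path}:{ln}: duplicate set name {name!r}")
            sets[name] = {g for g in parts[2:] if g}
    return sets


def read_age_table(path) -> dict[str, str]:
    """Two-column TSV gene -> age stratum (header optional)."""
    ages: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected 2 columns")
            gene, stratum = parts
            if ln == 1 and gene.lower() in {"gene", "gene_id"}:
                continue
            if gene in ages:
                raise ValueError(f"{path}:{ln}: duplicate gene {gene!r}")
            ages[gene] = stratum
    return ages
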