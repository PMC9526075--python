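"""End-to-end pipeline: counts -> QC -> networks -> commonality -> shared net.

A single YAML/dict config drives every stage; each stochastic stage must
declare its own seed, and a manifest records parameters, seeds, and sha256
checksums of every artifact so a rerun with the same config is bit
identical for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import commonality as cstats
from . import coexpr, core, io, network, qc, rra, topology
from .containers import CountMatrix, SharedNetwork
from .simulate import GeneratorConfig, generate_dataset

__all__ = ["PipelineConfig", "ConfigError", "run_pipeline"]

log = logging.getLogger("corenet")


class ConfigError(ValueError):
    pass


_STOCHASTIC_STAGES = ("coexpression", "commonality", "rra", "topology")


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (round-trips to YAML)."""

    simulate: dict | None = None
    input_dir: str | None = None
    qc: dict = field(default_factory=dict)
    coexpression: dict = field(default_factory=dict)
    threshold: dict = field(default_factory=lambda: {"q": 0.05})
    commonality: dict = field(default_factory=lambda: {"null_reps": 20})
    rra: dict = field(default_factory=lambda: {"alpha": 0.01, "max_sample": 100})
    modules: dict = field(default_factory=lambda: {"steps": 4, "min_size": 5})
    topology: dict = field(default_factory=lambda: {"null_reps": 100})

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.input_dir is None):
            raise ConfigError("exactly one of 'simulate' and 'input_dir' must be given")
        if self.simulate is not None and "seed" not in self.simulate:
            raise ConfigError("stage 'simulate' is missing an explicit seed")
        for stage in _STOCHASTIC_STAGES:
            section = getattr(self, stage)
            if "seed" not in section:
                raise ConfigError(f"stage {stage!r} is missing an explicit seed")
        if "grid" in self.threshold and "seed" not in self.threshold:
            raise ConfigError("threshold selection over a grid needs a seed")
        if "grid" not in self.threshold and "q" not in self.threshold:
            raise ConfigError("threshold needs either a fixed 'q' or a 'grid'")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {
            "simulate", "input_dir", "qc", "coexpression", "threshold",
            "commonality", "rra", "modules", "topology",
        }
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config sections: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _substream(seed: int, *key) -> int:
    ints = tuple(
        zlib.crc32(k.encode()) if isinstance(k, str) else int(k) for k in key
    )
    return int(np.random.SeedSequence((seed, *ints)).generate_state(1)[0] % (2**31))


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run every stage, writing artifacts and a checksum manifest to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": []}

    def record(stage: str, outputs: list[Path], params: dict) -> None:
        manifest["stages"].append(
            {
                "stage": stage,
                "outputs": {p.name: _sha256(p) for p in outputs},
                "params": params,
            }
        )

    def timed(stage: str):
        t0 = time.time()

        def done():
            log.info("stage %-12s %6.1fs", stage, time.time() - t0)

        return done

    # 1. counts
    done = timed("counts")
    if config.simulate is not None:
        gen_cfg = GeneratorConfig.from_dict(config.simulate)
        cm, truth = generate_dataset(gen_cfg)
        counts_dir = out / "counts"
        paths = io.write_counts(cm, counts_dir)
        truth.to_json(counts_dir / "truth.json")
        record(
            "counts",
            sorted(counts_dir.iterdir()),
            {"source": "simulate", **asdict(gen_cfg)},
        )
    else:
        cm = io.read_counts_dir(config.input_dir)
        record("counts", [], {"source": str(config.input_dir)})
    done()

    # 2. qc
    done = timed("qc")
    qc_cfg = qc.QCConfig(**config.qc)
    cm_f, cell_report = qc.filter_cells(cm, qc_cfg)
    sel = qc.select_clusters_and_common_genes(cm_f, qc_cfg)
    cm_common = cm_f.subset_genes(sel.common_genes)
    qc_dir = out / "qc"
    qc_dir.mkdir(exist_ok=True)
    (qc_dir / "common_genes.txt").write_text("".join(g + "\n" for g in sel.common_genes))
    with open(qc_dir / "qc_report.json", "w") as fh:
        json.dump(
            {
                "removed_cells": asdict(cell_report),
                "kept_clusters": sel.kept_clusters,
                "dropped_small": sel.dropped_small,
                "dropped_sparse": sel.dropped_sparse,
                "sparsity": sel.sparsity,
                "n_common_genes": len(sel.common_genes),
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    record("qc", sorted(qc_dir.iterdir()), asdict(qc_cfg))
    done()

    coexpr_seed = config.coexpression["seed"]
    coexpr_kwargs = {
        k: v for k, v in config.coexpression.items() if k != "seed"
    }

    # 3. threshold
    done = timed("threshold")
    if "grid" in config.threshold:
        grid = [float(x) for x in config.threshold["grid"]]
        n_splits = int(config.threshold.get("n_splits", 1))
        curves = {}
        for lab in sel.kept_clusters:
            curves[lab] = network.snr_curve(
                cm_common.cluster_submatrix(lab),
                cm_common.gene_ids,
                grid,
                n_splits=n_splits,
                seed=_substream(config.threshold["seed"], lab),
                **coexpr_kwargs,
            )
        q = network.select_threshold(curves)
        thresh_payload = {"q": q, "curves": {l: {str(k): v for k, v in c.items()} for l, c in curves.items()}}
    else:
        q = float(config.threshold["q"])
        thresh_payload = {"q": q}
    with open(out / "threshold.json", "w") as fh:
        json.dump(thresh_payload, fh, indent=1, sort_keys=True)
    record("threshold", [out / "threshold.json"], dict(config.threshold))
    done()

    # 4. per-cluster networks
    done = timed("networks")
    net_dir = out / "networks"
    net_dir.mkdir(exist_ok=True)
    networks: dict[str, object] = {}
    rank_lookups: dict[str, dict] = {}
    for lab in sel.kept_clusters:
        corr = coexpr.cluster_correlation(
            cm_common.cluster_submatrix(lab),
            cm_common.gene_ids,
            seed=_substream(coexpr_seed, lab),
            **coexpr_kwargs,
        )
        ranking = network.rank_all_pairs(corr)
        networks[lab] = network.network_from_ranking(ranking, q, lab)
        rank_lookups[lab] = ranking.rank_lookup()
        io.write_edge_list(networks[lab], net_dir / f"edges_{lab}.tsv")
    record("networks", sorted(net_dir.iterdir()), {"q": q, **coexpr_kwargs})
    done()

    # 5. commonality
    done = timed("commonality")
    table = cstats.edge_and_gene_commonality([networks[l] for l in sel.kept_clusters])
    io.write_commonality(table, out / "edge_commonality.tsv", out / "gene_commonality.tsv")
    record(
        "commonality",
        [out / "edge_commonality.tsv", out / "gene_commonality.tsv"],
        {"n_clusters": table.n_clusters},
    )
    done()

    # 6. randomization null
    done = timed("null")
    n_reps = int(config.commonality.get("null_reps", 20))
    null_path = out / "null_ensemble.tsv"
    if n_reps > 0:
        ensemble = cstats.randomized_commonality_null(
            [networks[l] for l in sel.kept_clusters],
            n_reps=n_reps,
            seed=config.commonality["seed"],
        )
        with open(null_path, "w") as fh:
            fh.write("rep\t" + "\t".join(f"k{k}" for k in range(table.n_clusters + 1)) + "\n")
            for i, h in enumerate(ensemble.histograms):
                fh.write(f"{i}\t" + "\t".join(str(int(x)) for x in h) + "\n")
    else:
        ensemble = None
        null_path.write_text("rep\n")
    record("null", [null_path], {"n_reps": n_reps, "seed": config.commonality["seed"]})
    done()

    # 7. shared network via rank aggregation
    done = timed("shared")
    alpha = float(config.rra.get("alpha", 0.01))
    results, k_star, shared = rra.group_scan_and_cutoff(
        networks,
        rank_lookups,
        table,
        alpha=alpha,
        max_sample=int(config.rra.get("max_sample", 100)),
        seed=config.rra["seed"],
    )
    scan_path = out / "group_scan.tsv"
    with open(scan_path, "w") as fh:
        fh.write("k\tn_sampled\tfisher_chi2\tfisher_df\tfisher_p\tgroup_p_bonferroni\n")
        for k in sorted(results):
            r = results[k]
            fh.write(
                f"{k}\t{len(r.sampled_edges)}\t{r.fisher_chi2:.17g}\t{r.fisher_df}"
                f"\t{r.fisher_p:.17g}\t{r.group_p_bonferroni:.17g}\n"
            )
    io.write_shared_network(shared, out / "shared_network.tsv")
    record(
        "shared",
        [scan_path, out / "shared_network.tsv"],
        {"alpha": alpha, "k_star": k_star, "seed": config.rra["seed"]},
    )
    done()

    # 8. modules
    done = timed("modules")
    mod_path = out / "modules.tsv"
    if shared.edges:
        partition = topology.detect_modules(
            shared,
            steps=int(config.modules.get("steps", 4)),
            min_size=int(config.modules.get("min_size", 5)),
        )
        with open(mod_path, "w") as fh:
            fh.write("gene\tmodule\n")
            for g in sorted(partition.assignment):
                fh.write(f"{g}\t{partition.assignment[g]}\n")
            for g in sorted(partition.unassigned):
                fh.write(f"{g}\tunassigned\n")
    else:
        partition = None
        mod_path.write_text("gene\tmodule\n")
    record("modules", [mod_path], dict(config.modules))
    done()

    # 9. topology
    done = timed("topology")
    topo_path = out / "topology.json"
    topo: dict = {"n_genes": len(shared.genes), "n_edges": shared.n_edges, "k_star": k_star}
    if shared.edges and len(shared.genes) >= 3:
        topo["clustering_coefficient"] = topology.clustering_coefficient(shared)
        n_topo_reps = int(config.topology.get("null_reps", 100))
        if n_topo_reps > 0:
            null = topology.clustering_null_ensemble(
                shared, n_reps=n_topo_reps, seed=config.topology["seed"]
            )
            topo["null_mean"] = null["mean"]
            topo["null_min"] = null["min"]
            topo["null_max"] = null["max"]
    with open(topo_path, "w") as fh:
        json.dump(topo, fh, indent=1, sort_keys=True)
    record("topology", [topo_path], dict(config.topology))
    done()

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
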