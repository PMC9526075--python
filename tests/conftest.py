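import numpy as np
import pytest

from corenet import io
from corenet.pipeline import PipelineConfig, run_pipeline
from corenet.simulate import GeneratorConfig, SyntheticTruth, generate_dataset

# QC thresholds scaled to the 300-gene synthetic panel (the atlas defaults
# of 200 genes / 500 UMI per cell assume ~17k-gene data)
SYNTH_QC = {"min_genes_per_cell": 100, "min_umi_per_cell": 200}


def synth_pipeline_config(loading: float, seed: int) -> PipelineConfig:
    return PipelineConfig.from_dict(
        {
            "simulate": {"seed": seed, "loading_strength": loading},
            "qc": dict(SYNTH_QC),
            "coexpression": {"seed": 11},
            "threshold": {"q": 0.05},
            "commonality": {"seed": 5, "null_reps": 0},
            "rra": {"seed": 7, "alpha": 0.01},
            "topology": {"seed": 3, "null_reps": 20},
        }
    )


def build_cluster_networks(cm, q=0.05, seed=11):
    """Coexpression + thresholding for every cluster (no QC, all genes)."""
    from corenet import coexpr, network

    networks, lookups = {}, {}
    for lab in cm.cluster_labels():
        corr = coexpr.cluster_correlation(
            cm.cluster_submatrix(lab), cm.gene_ids, seed=seed
        )
        ranking = network.rank_all_pairs(corr)
        networks[lab] = network.network_from_ranking(ranking, q, lab)
        lookups[lab] = ranking.rank_lookup()
    return networks, lookups


@pytest.fixture(scope="session")
def default_dataset():
    """One dataset at generator defaults (seed 1), shared across tests."""
    return generate_dataset(GeneratorConfig())


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """Full pipeline on the default planted-structure dataset (seed 1)."""
    out = tmp_path_factory.mktemp("pipeline_default")
    manifest = run_pipeline(synth_pipeline_config(loading=1.2, seed=1), out)
    shared = io.read_shared_network(out / "shared_network.tsv")
    truth = SyntheticTruth.from_json(out / "counts" / "truth.json")
    return {"out": out, "manifest": manifest, "shared": shared, "truth": truth}


@pytest.fixture
def small_counts():
    """Tiny deterministic CountMatrix: 4 genes x 6 cells in 2 clusters."""
    from corenet.containers import CountMatrix

    counts = np.array(
        [
            [5, 0, 2, 1, 0, 3],
            [1, 1, 0, 0, 2, 0],
            [0, 4, 1, 2, 1, 1],
            [2, 0, 0, 1, 0, 0],
        ]
    )
    cells = [f"c{i}" for i in range(6)]
    return CountMatrix(
        gene_ids=["gA", "gB", "gC", "mt:gD"],
        cell_ids=cells,
        counts=counts,
        cluster_of={c: ("left" if i < 3 else "right") for i, c in enumerate(cells)},
        mito_genes=frozenset({"mt:gD"}),
    )
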