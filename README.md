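# corenet

Tools for asking whether diverse cell types of an organism share a *core*
gene coexpression network, using sparse single-cell RNA-seq UMI counts.

Single-cell atlases partition cells into tens of clusters (cell types).
Within each cluster, gene–gene coexpression can be estimated and
thresholded into a cluster-specific network; a gene pair that is then
"coexpressed" in many clusters is a candidate member of a core network
shared by all cells. `corenet` implements that entire chain:

1. **QC filters** — remove cells with too few expressed genes, too few
   UMIs, or excessive mitochondrial fraction; drop small clusters; define
   the *commonly expressed* gene set (genes passing a per-cluster
   expression floor in every retained cluster); exclude overly sparse
   clusters.
2. **Per-cluster coexpression** — cells of a cluster are grouped into
   subclusters (k-means on top principal components of log1p CPM); each
   gene gets a Wilcoxon rank-sum z-score for every subcluster pair; genes
   are correlated through their z-score profiles (Pearson).  Rank
   statistics make the correlations robust to dropout zeros.
3. **Thresholding** — the top fraction *q* of pairs by |r| forms the
   cluster network; *q* can be chosen by a split-half signal-to-noise
   criterion (SNR = observed split overlap / `q²·C(n,2)` expected).
4. **Commonality statistics** — for each edge, the number of cluster
   networks containing it, compared against the analytic Binomial(*N*, *q*)
   null `P(k) = C(N,k) q^k (1−q)^{N−k}` and against an ensemble of
   degree-preserving rewirings of every cluster network.
5. **Robust rank aggregation** — for each commonality group *k*, the
   edges' normalized ranks in the *N−k* clusters where they fell below
   threshold are scored by beta order statistics
   (`ρ = min_j P(Binom(m, r_(j)) ≥ j)`, Bonferroni over *j*), combined with
   Fisher's method and Bonferroni-corrected across groups.  The smallest
   *k\** whose group (and every larger group) passes the cutoff defines the
   **shared network**: all edges with commonality ≥ *k\**.
6. **Characterization** — global clustering coefficient against a
   degree-preserving null ensemble, walktrap community modules,
   hypergeometric gene-set enrichment, and permutation-based enrichment of
   phylostratigraphic gene-age classes.
7. **Core intersection** — shared networks from several datasets intersect
   into a core network.

A synthetic-data generator produces multi-cluster negative-binomial UMI
counts with planted shared and cluster-specific coexpression modules plus
ground truth, so the whole pipeline is testable end to end without any
download.

## Worked example

Run the full pipeline on synthetic data with planted structure (10
clusters × 300 cells, 300 genes, 4 shared modules of 10 genes):

```python
from corenet import io
from corenet.pipeline import PipelineConfig, run_pipeline
from corenet.simulate import SyntheticTruth

config = PipelineConfig.from_dict({
    "simulate": {"seed": 1, "loading_strength": 1.2},
    "qc": {"min_genes_per_cell": 100, "min_umi_per_cell": 200},
    "coexpression": {"seed": 11},
    "threshold": {"q": 0.05},
    "commonality": {"seed": 5, "null_reps": 0},
    "rra": {"seed": 7, "alpha": 0.01},
    "topology": {"seed": 3, "null_reps": 20},
})
run_pipeline(config, "run1")

shared = io.read_shared_network("run1/shared_network.tsv")
truth = SyntheticTruth.from_json("run1/counts/truth.json")
tp = len(shared.edges & truth.shared_edges)
print(f"k* = {shared.k_star}")
print(f"shared network: {len(shared.genes)} genes, {len(shared.edges)} edges")
print(f"precision = {tp / len(shared.edges):.3f}, recall = {tp / len(truth.shared_edges):.3f}")
```

prints

```
k* = 5
shared network: 40 genes, 177 edges
precision = 0.989, recall = 0.972
```

The rank-aggregation scan settles on commonality cutoff *k\** = 5 and the
selected edge set recovers the 180 planted shared-module pairs almost
exactly, while the cluster-specific planted modules and noise edges stay
out.  On data generated with `loading_strength: 0` (no planted
coexpression) the same pipeline returns an **empty** shared network — no
false core.  The analytic null at the published scale is available
directly:

```python
from corenet.commonality import binomial_null_pmf, expected_pairs_at_least_one
null = binomial_null_pmf(67, 0.05)       # P(k) for 67 clusters at the top 5%
expected_pairs_at_least_one(2088, 67, 0.05)   # -> 2,108,888 pairs
```

The same stages are available from a shell via `corenet simulate`,
`corenet qc`, `corenet coexpression`, `corenet commonality`,
`corenet modules`, `corenet core`, and `corenet run --config cfg.yaml`.

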