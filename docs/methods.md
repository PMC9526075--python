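# Methods

This note documents the models, statistics, and numerical choices behind
`corenet`, and what the synthetic benchmark does and does not demonstrate.

## Synthetic data generator

`corenet.simulate.generate_dataset` emulates the statistical structure of
droplet-based single-cell atlases: many cell clusters, overdispersed sparse
counts, per-cell library-size variation, a mitochondrial gene subset, and
gene–gene correlation induced by latent factors.

For gene *g* in cell *j* of cluster *c*:

- a dataset-level baseline `b_g ~ Normal(baseline_log_mean, baseline_log_sd)`;
- per cell, each module *m* (shared or cluster-specific) has an activity
  `a_m(j) ~ Normal(0, 1)`; member genes get `log μ = b_g + λ·a_m(j)` with
  loading strength λ;
- a log-normal library factor `L_j` multiplies all means;
- counts are `NegativeBinomial(mean = μ·L_j, dispersion = r)`.

Shared modules use the same genes in every cluster (the planted "core");
each cluster additionally draws its own specific modules from the
remaining gene pool, disjoint within a cluster.  Dropout arises solely
from NB sampling — there is no separate zero-inflation knob — and sparsity
is controlled by `baseline_log_mean`.

Defaults (10 clusters × 300 cells, 300 genes, 4 shared modules of 10
genes, 2 specific modules per cluster, λ = 1.2, r = 2,
`baseline_log_mean = 0.3`, library log-SD 0.3, ~5 mitochondrial genes
carrying ~5% of counts) give per-cluster zero fractions of ~37%, inside
the <48% regime of the atlases this emulates, at a problem size where the
full pipeline runs in seconds.  Randomness is one seed; per-cluster draws
come from substreams keyed by (seed, cluster index), so adding clusters
does not perturb earlier ones.

What the generator does *not* emulate: real gene-id vocabularies, batch
effects, doublets, ambient RNA, cell-type hierarchies, or non-factor
correlation structure.  Passing the recovery benchmark therefore shows the
statistical chain is sound under a known factor model, not that any
particular biological dataset will yield a core.

## QC filters

Per-cell rules (defaults match atlas-scale data: ≥200 expressed genes,
≥500 UMIs, mitochondrial fraction ≤30%); clusters need ≥200 cells.  A gene
is "expressed" in a cluster when its nonzero-cell count reaches
`max(15, ceil(0.005 · n_cells))`; *common* genes are the intersection of
expressed sets over all size-passing clusters.  Sparsity (zero fraction of
the common-gene submatrix) then excludes clusters above 0.50, and the
common set is deliberately **not** recomputed afterwards — the gene
universe is fixed before the sparsity exclusion, so excluding a sparse
cluster cannot enlarge it.

The per-cell gene/UMI floors scale with the size of the gene panel: on the
300-gene synthetic panel the benchmark configs use 100 genes / 200 UMIs,
which are the same fractions of a typical cell's content as the atlas
defaults are at ~17k genes.

## Per-cluster coexpression

Raw per-cell Pearson correlation is unreliable at ~40% zeros, so
correlations are computed on differential-expression z-score profiles:

1. **Subclustering**: k-means on the top 10 principal components of
   log1p CPM (CPM uses per-cell totals over the common genes; pseudocount
   1 before the log).  The default subcluster count is one per ~50 cells,
   clamped to [2, 10].  One per ~100 cells was tried first but leaves a
   300-cell cluster with only 3 subclusters and hence 3 comparison
   columns; correlations from 3 points are so heavy-tailed (for bivariate
   normal data, P(|r| > 0.95) ≈ 0.20 at 3 points) that the top-5% cut is
   dominated by noise.  At one per 50 cells a 300-cell cluster yields 15
   comparisons and the planted-module |r| separates cleanly from
   background.  Subclusters must hold ≥20 cells; if k-means undershoots,
   the count is lowered, and at K = 2 the nearest cells of the larger
   group top up the smaller one.
2. **Z-scores**: for every subcluster pair, each gene receives a Wilcoxon
   rank-sum z (normal approximation with tie correction and 0.5 continuity
   correction) on log1p CPM, signed positive when the gene is higher in
   the lower-indexed subcluster.  Genes constant in both groups get z = 0.
   A rank-based score was chosen over a parametric noise model because it
   is robust to dropout while serving the same role — quantifying the
   likelihood of an expression change between subclusters.
3. **Correlation**: Pearson over the z-score profiles (≥3 comparisons
   required).  Zero-variance genes are flagged and assigned correlation 0.

## Thresholding and the SNR criterion

A cluster network keeps the top `round(q · C(n,2))` pairs by |r|
(round-half-to-even, so counts are exactly reproducible); ties in |r|
break by the canonical lexicographic pair key — determinism is preferred
to randomization at machine-precision ties.  Edge nesting across q holds
by construction.

The split-half SNR for threshold selection: cells are halved at random,
the full subcluster→z-score→threshold recipe runs on each half, and
SNR(q) = |E₁ ∩ E₂| / (q²·C(n,2)), averaged over splits.  Under
independence SNR = 1; reproducible coexpression pushes it above 1, most
strongly at small q.  The global q* is the per-cluster argmax chosen most
often, ties toward smaller q.

## Commonality nulls

With edges chosen independently per cluster at fraction q, an edge's
commonality k over N clusters is Binomial(N, q).  At the published scale
(N = 67, q = 0.05) this pmf evaluates to 0.1970 / 0.2247 / 0.1892 at
k = 2/3/4 and 0.0321 (truncated to 4 decimals) at k = 0; with 2,088 genes
the expected number of pairs appearing at least once is 2,108,888 when the
miss probability is truncated to 4 decimals before use, and 2,108,730 at
full precision.  Both conventions are exposed
(`expected_pairs_at_least_one(..., survival_decimals=4 | None)`) because
the quoted integer is reproducible only under truncation.

The empirical null rewires every cluster network by double-edge swaps
(default 10·|E| accepted swaps; proposals creating self-loops or
multi-edges are rejected), preserving each gene's degree exactly, and
recomputes the commonality histogram; 100 independent ensembles form the
null.  Swap intensity is configurable since mixing time depends on the
graph.

## Rank aggregation and the shared network

An edge with commonality k has m = N − k leftover normalized ranks (rank
among all C(n,2) pairs divided by C(n,2); normalization is by the full
pair universe).  The aggregated p is the beta order-statistic score: with
sorted ranks r₍₁₎…r₍ₘ₎, `β_j = P(Binomial(m, r_(j)) ≥ j)`,
ρ = min_j β_j, p = min(1, m·ρ) — a valid, slightly conservative p-value
under uniform ranks (verified by simulation: null rejection ≈ 0.04 at
nominal 0.05).

Group scan: per observed k, up to 100 edges are sampled (smaller groups
used whole); per-edge p-values are Bonferroni-corrected within the group;
the group statistic is Fisher's method with Bonferroni over scanned
groups.  **Fisher combines the raw per-edge p-values by default.**  The
alternative — combining the within-group-adjusted values — collapses for
small cluster counts: with one leftover cluster the smallest possible
per-edge p is ≈ q, so a group of s sampled edges has every adjusted value
pinned at min(1, q·s) ≥ 1 once s ≥ 1/q, Fisher's statistic becomes exactly
0, and groups at k = N−1 or N−2 can never pass regardless of signal.
Combining raw values keeps the statistic informative at any N while the
across-group Bonferroni still controls the group-level error; the adjusted
variant remains available (`combine_adjusted=True`).

The cutoff k* is the smallest k such that the group at k **and every
larger non-empty group** pass `group_p < α` (α = 0.01); a laxer
first-passing-k rule is available.  A group at k = N has no leftover
ranks and passes vacuously — edges present in every cluster need no
sub-threshold evidence.  The shared network is all edges (sampled or not)
with commonality ≥ k*; if no k passes, it is empty, which is the expected
outcome on data without planted structure.  Underflowing p-values are
floored at 1e-300 before logs.

## Topology and modules

Clustering coefficient = global transitivity (3·triangles / connected
triples), matching the default of the standard graph library; mean-local
clustering is available separately.  The null ensemble reuses the
degree-preserving rewiring.  Communities come from walktrap (random-walk
length 4, the cited implementation's default) with a modularity cut, run
per connected component; modules are indexed 1..M by decreasing size and
communities smaller than 5 genes land in an "unassigned" bucket.  Edge
weights are ignored — the thresholded network is unweighted.

## Enrichment

Gene-set enrichment is the exact one-sided hypergeometric upper tail with
Bonferroni over the sets tested per module; sets are intersected with the
background first, and the module must be a subset of the background.  Gene
sets come from GMT-like TSV files; no ontology traversal or redundancy
reduction is performed.

Age enrichment assigns genes to 12 ordered phylostrata (CellLife …
Drosophila) and compares each stratum's observed module count against
counts in module-sized uniform draws from the background (default 1,000
permutations).  Genes without an age annotation are excluded from both the
observed counts and the null draws.  The default empirical p counts
permutations with a *strictly larger* count (the stated convention); on
discrete counts this discards the tie mass P(X = x_obs) and is therefore
anti-conservative — measured false-positive rate ≈ 0.019 at nominal 0.01
under null modules — whereas the `strict=False` (≥) variant is calibrated
(rate ≤ α, verified over 200 trials).  Calibration tests use the ≥
convention; users wanting guaranteed error control should too.

## Determinism and problem sizes

Every stochastic stage takes an explicit seed (the pipeline refuses
configs without one), and all derived streams use SeedSequence spawning,
so reruns are bit-identical — the pipeline manifest records sha256
checksums of every artifact to make this checkable.  The test suite and
the acceptance script run the full pipeline at the generator defaults
(10 × 300 cells, 300 genes), where one end-to-end pass takes a few
seconds; null calibration uses 10,000 rank vectors, 100 rewirings, and
200 permutation trials.  These sizes were chosen so the complete benchmark
executes in minutes while every statistic retains enough resolution to
detect the failure modes it guards against.

## Known limitations

- The z-score recipe is a self-contained reimplementation of the
  pseudocell idea, not a port of any specific tool; absolute |r| values
  are not comparable across recipes, only ranks are used downstream.
- The SNR threshold criterion is defined here as split-half overlap over
  its independence expectation; other definitions exist.
- Combining Fisher across groups assumes independence between sampled
  edges within a group, which planted or biological modules violate;
  the across-group Bonferroni and the all-larger-groups rule compensate
  conservatively.
- The binomial null treats pairs independently; correlated gene modules
  inflate high-commonality counts under the alternative, which is exactly
  the signal sought, but the null itself is approximate.
- The age permutation test conditions on module size only, not on degree
  or expression level.
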