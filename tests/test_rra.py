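import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2

from conftest import build_cluster_networks
from corenet import rra
from corenet.commonality import edge_and_gene_commonality
from corenet.containers import CommonalityTable, EdgeKey
from corenet.simulate import GeneratorConfig, generate_dataset


class TestRRAPvalue:
    def test_single_rank_identity(self):
        assert rra.rra_pvalue([0.3]) == pytest.approx(0.3)

    def test_two_ranks_closed_form(self):
        # beta_1 = 1 - 0.9^2 = 0.19, beta_2 = 0.2^2 = 0.04 -> rho 0.04, p 0.08
        assert rra.rra_pvalue([0.1, 0.2]) == pytest.approx(0.08, abs=1e-12)

    def test_three_ranks_closed_form(self):
        r1, r2, r3 = 0.05, 0.30, 0.90
        b1 = 1 - (1 - r1) ** 3
        b2 = 3 * r2**2 * (1 - r2) + r2**3
        b3 = r3**3
        expected = min(1.0, 3 * min(b1, b2, b3))
        assert rra.rra_pvalue([r1, r2, r3]) == pytest.approx(expected, abs=1e-12)

    def test_rejects_out_of_range_ranks(self):
        with pytest.raises(ValueError):
            rra.rra_pvalue([0.0, 0.5])
        with pytest.raises(ValueError):
            rra.rra_pvalue([0.5, 1.2])
        with pytest.raises(ValueError):
            rra.rra_pvalue([])

    def test_super_uniform_under_null(self):
        """Null rejection rate at alpha=0.05 stays at or below 0.05
        (within 3 Monte-Carlo SEs) for m=5 uniform rank vectors."""
        rng = np.random.default_rng(123)
        n_sim, m = 10_000, 5
        R = np.sort(rng.random((n_sim, m)), axis=1)
        j = np.arange(1, m + 1)
        # vectorized copy of the beta order-statistic score
        from scipy.stats import binom

        beta = binom.sf(j[None, :] - 1, m, R)
        p = np.minimum(1.0, beta.min(axis=1) * m)
        rate = float((p <= 0.05).mean())
        se = np.sqrt(0.05 * 0.95 / n_sim)
        assert rate <= 0.05 + 3 * se
        # spot-check the vectorization against the scalar implementation
        for row in R[:50]:
            expected = rra.rra_pvalue(row)
            got = min(1.0, float(binom.sf(j - 1, m, np.sort(row)).min()) * m)
            assert got == pytest.approx(expected, abs=1e-12)

    @given(
        ranks=st.lists(st.floats(0.01, 1.0), min_size=1, max_size=8),
        idx=st.integers(0, 7),
        factor=st.floats(0.1, 0.99),
    )
    @settings(max_examples=200, deadline=None)
    def test_improving_a_rank_never_raises_p(self, ranks, idx, factor):
        idx = idx % len(ranks)
        p_before = rra.rra_pvalue(ranks)
        improved = list(ranks)
        improved[idx] = improved[idx] * factor
        assert rra.rra_pvalue(improved) <= p_before + 1e-12


class TestSampleGroupEdges:
    def _table(self, n_edges, k=2, n_clusters=5):
        genes = [f"g{i:03d}" for i in range(60)]
        pairs = [(a, b) for i, a in enumerate(genes) for b in genes[i + 1 :]]
        edge_k = {EdgeKey(a, b): k for a, b in pairs[:n_edges]}
        return CommonalityTable(n_clusters=n_clusters, edge_k=edge_k, gene_k={})

    def test_small_group_returned_whole(self):
        t = self._table(40)
        assert len(rra.sample_group_edges(t, 2, max_n=100, seed=0)) == 40

    def test_large_group_sampled_to_max(self):
        t = self._table(500)
        sample = rra.sample_group_edges(t, 2, max_n=100, seed=0)
        assert len(sample) == len(set(sample)) == 100

    def test_deterministic_in_seed(self):
        t = self._table(500)
        assert rra.sample_group_edges(t, 2, seed=7) == rra.sample_group_edges(t, 2, seed=7)

    def test_empty_group_returns_empty(self):
        t = self._table(10, k=3)
        assert rra.sample_group_edges(t, 4) == []


class TestFisherCombine:
    def test_single_p_identity(self):
        _, _, p = rra.fisher_combine([0.05])
        assert p == pytest.approx(0.05, rel=1e-12)

    def test_two_equal_ps_against_chi2_oracle(self):
        stat, df, p = rra.fisher_combine([0.05, 0.05])
        assert stat == pytest.approx(-4 * np.log(0.05), rel=1e-12)
        assert df == 4
        assert p == pytest.approx(float(chi2.sf(-4 * np.log(0.05), 4)), rel=1e-12)
        assert p == pytest.approx(0.0175, abs=5e-4)

    def test_all_ones_combine_to_one(self):
        stat, df, p = rra.fisher_combine([1.0, 1.0, 1.0])
        assert stat == 0.0
        assert p == 1.0

    def test_nonpositive_p_is_error(self):
        with pytest.raises(ValueError):
            rra.fisher_combine([0.5, 0.0])


class TestGroupScan:
    def test_planted_modules_recovered(self, pipeline_run):
        """End-to-end: the shared network recovers the planted shared edges
        with high precision and recall (generator defaults, seed 1)."""
        shared = pipeline_run["shared"]
        truth = pipeline_run["truth"]
        tp = len(shared.edges & truth.shared_edges)
        assert shared.k_star is not None
        assert tp / len(shared.edges) >= 0.7
        assert tp / len(truth.shared_edges) >= 0.7

    def test_alpha_one_accepts_smallest_observed_k(self, default_dataset):
        cm, _ = default_dataset
        networks, lookups = build_cluster_networks(cm)
        table = edge_and_gene_commonality(list(networks.values()))
        _, k_star, shared = rra.group_scan_and_cutoff(
            networks, lookups, table, alpha=1.0, seed=0
        )
        assert k_star == min(table.edge_k.values())
        assert len(shared.edges) == len(table.edge_k)

    def test_group_p_invariant_to_sample_order(self, default_dataset):
        cm, _ = default_dataset
        networks, lookups = build_cluster_networks(cm)
        table = edge_and_gene_commonality(list(networks.values()))
        res1, _, _ = rra.group_scan_and_cutoff(networks, lookups, table, seed=1)
        res2, _, _ = rra.group_scan_and_cutoff(networks, lookups, table, seed=1)
        for k in res1:
            assert res1[k].group_p_bonferroni == res2[k].group_p_bonferroni

    def test_shared_edges_all_meet_cutoff(self, pipeline_run):
        from corenet import io

        shared = pipeline_run["shared"]
        table = io.read_commonality(
            pipeline_run["out"] / "edge_commonality.tsv",
            pipeline_run["out"] / "gene_commonality.tsv",
        )
        assert all(table.edge_k[e] >= shared.k_star for e in shared.edges)
        # and every edge at or above k* is included
        assert shared.edges == {e for e, k in table.edge_k.items() if k >= shared.k_star}
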