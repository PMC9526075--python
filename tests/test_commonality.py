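import math

import numpy as np
import pytest

from conftest import build_cluster_networks
from corenet import commonality as cstats
from corenet.containers import ClusterNetwork, EdgeInfo, EdgeKey
from corenet.simulate import GeneratorConfig, generate_dataset


def _net(label, genes, edges, q=0.5):
    return ClusterNetwork(
        label=label,
        gene_ids=list(genes),
        edges={
            EdgeKey(a, b): EdgeInfo(abs_corr=1.0 - 0.01 * i, rank=i + 1)
            for i, (a, b) in enumerate(edges)
        },
        q=q,
    )


GENES = ["a", "b", "c", "d"]


class TestEdgeAndGeneCommonality:
    def test_counting_example(self):
        nets = [
            _net("1", GENES, [("a", "b"), ("b", "c")]),
            _net("2", GENES, [("a", "b")]),
            _net("3", GENES, [("a", "b"), ("c", "d")]),
        ]
        t = cstats.edge_and_gene_commonality(nets)
        assert t.edge_k == {EdgeKey("a", "b"): 3, EdgeKey("b", "c"): 1, EdgeKey("c", "d"): 1}
        assert t.gene_k == {"a": 3, "b": 3, "c": 2, "d": 1}

    def test_identical_networks_give_k_equal_n(self):
        nets = [_net(str(i), GENES, [("a", "b"), ("c", "d")]) for i in range(4)]
        t = cstats.edge_and_gene_commonality(nets)
        assert set(t.edge_k.values()) == {4}

    def test_disjoint_networks_conserve_edge_count(self):
        nets = [
            _net("1", GENES, [("a", "b")]),
            _net("2", GENES, [("c", "d")]),
            _net("3", GENES, [("a", "c"), ("b", "d")]),
        ]
        t = cstats.edge_and_gene_commonality(nets)
        assert set(t.edge_k.values()) == {1}
        assert sum(t.edge_k.values()) == sum(n.n_edges for n in nets)

    def test_gene_universe_mismatch_is_error(self):
        nets = [_net("1", GENES, [("a", "b")]), _net("2", ["a", "b", "x"], [("a", "b")])]
        with pytest.raises(ValueError, match="universe"):
            cstats.edge_and_gene_commonality(nets)


class TestBinomialNull:
    def test_matches_printed_probabilities_for_67_clusters(self):
        null = cstats.binomial_null_pmf(67, 0.05)
        assert round(null.pmf[2], 4) == 0.1970
        assert round(null.pmf[3], 4) == 0.2247
        assert round(null.pmf[4], 4) == 0.1892
        assert math.floor(null.pmf[0] * 1e4) / 1e4 == 0.0321
        assert null.pmf[14] < 1e-4

    def test_degenerate_p_zero(self):
        null = cstats.binomial_null_pmf(5, 0.0)
        assert null.pmf[0] == 1.0
        assert null.pmf[1:].sum() == 0.0

    def test_pmf_sums_to_one(self):
        null = cstats.binomial_null_pmf(67, 0.05)
        assert abs(null.pmf.sum() - 1.0) < 1e-12


class TestExpectedPairs:
    def test_printed_value_with_truncated_survival(self):
        assert cstats.expected_pairs_at_least_one(2088, 67, 0.05, 4) == 2_108_888

    def test_full_precision_value(self):
        # independent arithmetic: C(2088,2) x (1 - 0.95^67)
        oracle = round(math.comb(2088, 2) * (1 - 0.95**67))
        assert oracle == 2_108_730
        assert cstats.expected_pairs_at_least_one(2088, 67, 0.05, None) == oracle

    def test_p_zero_gives_zero(self):
        assert cstats.expected_pairs_at_least_one(2, 10, 0.0) == 0


class TestRewireDegreePreserving:
    def test_triangle_is_rigid(self):
        tri = _net("t", ["a", "b", "c"], [("a", "b"), ("b", "c"), ("a", "c")])
        with pytest.warns(UserWarning, match="no swappable"):
            out = cstats.rewire_degree_preserving(tri, seed=0)
        assert out.edge_set() == tri.edge_set()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_degree_multiset_preserved(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"g{i:02d}" for i in range(30)]
        pairs = {(a, b) for i, a in enumerate(genes) for b in genes[i + 1 :]}
        chosen = sorted(pairs)
        idx = rng.choice(len(chosen), size=120, replace=False)
        net = _net("r", genes, [chosen[i] for i in idx])
        out = cstats.rewire_degree_preserving(net, seed=seed + 100)
        assert sorted(net.degrees().values()) == sorted(out.degrees().values())
        assert out.edge_set() != net.edge_set()  # it actually moved

    def test_path_visits_both_realizations(self):
        # degree sequence (1,2,2,1) on labeled nodes has exactly 2 simple graphs
        path = _net("p", ["a", "b", "c", "d"], [("a", "b"), ("b", "c"), ("c", "d")])
        seen = set()
        for seed in range(100):
            # both swap-count parities, since each accepted swap toggles
            # between the two labeled realizations
            out = cstats.rewire_degree_preserving(path, n_swaps=1 + seed % 4, seed=seed)
            seen.add(frozenset(out.edge_set()))
        expected = {
            frozenset({EdgeKey("a", "b"), EdgeKey("b", "c"), EdgeKey("c", "d")}),
            frozenset({EdgeKey("a", "c"), EdgeKey("b", "c"), EdgeKey("b", "d")}),
        }
        assert seen == expected


class TestRandomizedCommonalityNull:
    def test_single_rep_deterministic(self):
        nets = [
            _net("1", GENES, [("a", "b"), ("c", "d"), ("a", "c")]),
            _net("2", GENES, [("a", "d"), ("b", "c"), ("a", "b")]),
        ]
        e1 = cstats.randomized_commonality_null(nets, n_reps=1, seed=3)
        e2 = cstats.randomized_commonality_null(nets, n_reps=1, seed=3)
        assert np.array_equal(e1.histograms[0], e2.histograms[0])

    def test_edge_count_conserved_in_every_rep(self, default_dataset):
        cm, _ = default_dataset
        networks, _ = build_cluster_networks(cm)
        nets = list(networks.values())
        total = sum(n.n_edges for n in nets)
        ens = cstats.randomized_commonality_null(nets, n_reps=5, seed=2)
        ks = np.arange(len(nets) + 1)
        for h in ens.histograms:
            assert int((h * ks).sum()) == total

    def test_planted_core_exceeds_null_commonality(self, default_dataset):
        """With planted shared modules the observed max commonality beats
        every rewiring rep (the randomizations never reach it)."""
        cm, _ = default_dataset
        networks, _ = build_cluster_networks(cm)
        nets = list(networks.values())
        obs = cstats.edge_and_gene_commonality(nets).histogram()
        obs_max = int(np.max(np.nonzero(obs)[0]))
        ens = cstats.randomized_commonality_null(nets, n_reps=20, seed=8)
        assert obs_max > ens.max_commonality

    def test_no_signal_stays_inside_null_envelope(self):
        """Without planted structure the observed histogram sits within the
        rewiring-null envelope at every commonality level (no false core)."""
        cfg = GeneratorConfig(loading_strength=0.0, seed=6)
        cm, _ = generate_dataset(cfg)
        networks, _ = build_cluster_networks(cm)
        nets = list(networks.values())
        obs = cstats.edge_and_gene_commonality(nets).histogram()
        ens = cstats.randomized_commonality_null(nets, n_reps=20, seed=9)
        lo, hi = ens.envelope()
        assert (obs >= lo).all() and (obs <= hi).all()
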