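import itertools
import math

import numpy as np
import pytest

from corenet.enrichment import (
    PHYLOSTRATA,
    age_permutation_enrichment,
    hypergeom_enrichment,
    read_age_table,
    read_gene_sets,
)


def _genes(n, prefix="g"):
    return [f"{prefix}{i:03d}" for i in range(n)]


class TestHypergeomEnrichment:
    def test_perfect_overlap_closed_form(self):
        # background 20, set 5, module 5, overlap 5 -> p = 1/C(20,5)
        bg = _genes(20)
        rows = hypergeom_enrichment(bg[:5], {"s": set(bg[:5])}, bg)
        assert rows.loc[0, "p"] == pytest.approx(1 / math.comb(20, 5), rel=1e-12)

    def test_zero_overlap_gives_p_one(self):
        bg = _genes(20)
        rows = hypergeom_enrichment(bg[:5], {"s": set(bg[10:15])}, bg)
        assert rows.loc[0, "p"] == pytest.approx(1.0)

    def test_bonferroni_multiplies_by_set_count(self):
        bg = _genes(30)
        sets = {f"s{i}": set(bg[i : i + 5]) for i in range(10)}
        rows = hypergeom_enrichment(bg[:5], sets, bg)
        for _, row in rows.iterrows():
            assert row.p_adj == pytest.approx(min(1.0, row.p * 10))

    def test_matches_brute_force_enumeration(self):
        """Exact tail from enumerating every module of the background."""
        bg = _genes(12)
        rng = np.random.default_rng(5)
        for trial in range(5):
            set_size = int(rng.integers(2, 8))
            mod_size = int(rng.integers(2, 8))
            members = set(rng.choice(bg, size=set_size, replace=False))
            module = list(rng.choice(bg, size=mod_size, replace=False))
            obs = len(set(module) & members)
            total = 0
            hits = 0
            for combo in itertools.combinations(bg, mod_size):
                total += 1
                if len(set(combo) & members) >= obs:
                    hits += 1
            rows = hypergeom_enrichment(module, {"s": members}, bg)
            assert rows.loc[0, "p"] == pytest.approx(hits / total, rel=1e-10)

    def test_module_outside_background_is_error(self):
        with pytest.raises(ValueError):
            hypergeom_enrichment(["x"], {"s": {"x"}}, _genes(5))

    def test_empty_background_is_error(self):
        with pytest.raises(ValueError):
            hypergeom_enrichment([], {"s": set()}, [])


class TestAgePermutationEnrichment:
    def _ages(self, bg, rng, strata=None):
        strata = strata or PHYLOSTRATA[:4]
        return {g: strata[int(rng.integers(len(strata)))] for g in bg}

    def test_deterministic_in_seed(self):
        rng = np.random.default_rng(0)
        bg = _genes(100)
        ages = self._ages(bg, rng)
        module = bg[:20]
        r1 = age_permutation_enrichment(module, ages, bg, n_perm=200, seed=42)
        r2 = age_permutation_enrichment(module, ages, bg, n_perm=200, seed=42)
        assert r1.equals(r2)

    def test_whole_stratum_module_has_p_zero(self):
        # module = every CellLife gene; no permutation can exceed the max count
        bg = _genes(60)
        ages = {g: ("CellLife" if i < 20 else "Metazoa") for i, g in enumerate(bg)}
        rows = age_permutation_enrichment(bg[:20], ages, bg, n_perm=500, seed=1)
        cell_life = rows[rows.unit == "CellLife"].iloc[0]
        assert cell_life.observed == 20
        assert cell_life.p == 0.0
        assert cell_life.significant

    def test_p_values_live_on_permutation_grid(self):
        rng = np.random.default_rng(3)
        bg = _genes(80)
        ages = self._ages(bg, rng)
        rows = age_permutation_enrichment(bg[:15], ages, bg, n_perm=250, seed=9)
        for p in rows.p:
            assert abs(p * 250 - round(p * 250)) < 1e-9

    def test_unannotated_genes_excluded(self):
        bg = _genes(50)
        ages = {g: "Eukaryota" for g in bg[:30]}  # 20 genes unannotated
        rows = age_permutation_enrichment(bg[:10], ages, bg, n_perm=100, seed=2)
        assert (rows.background_size == 30).all()

    def test_null_calibration_with_tie_inclusive_convention(self):
        """Random modules reject each age stratum at ~alpha under the >=
        tie convention (the convention for which calibration is exact)."""
        rng = np.random.default_rng(2024)
        bg = _genes(300)
        ages = self._ages(bg, rng, strata=PHYLOSTRATA[:6])
        n_trials, alpha = 200, 0.01
        hits = 0
        total = 0
        for t in range(n_trials):
            module = list(rng.choice(bg, size=30, replace=False))
            rows = age_permutation_enrichment(
                module, ages, bg, n_perm=500, alpha=alpha, seed=10_000 + t, strict=False
            )
            hits += int((rows.p < alpha).sum())
            total += len(rows)
        rate = hits / total
        se = math.sqrt(alpha * (1 - alpha) / total)
        assert rate <= alpha + 3 * se

    def test_strict_convention_is_anti_conservative_on_ties(self):
        """The strict > convention yields p-values no larger than the >=
        convention (it drops the tie mass), so its rejection rate is higher."""
        rng = np.random.default_rng(7)
        bg = _genes(120)
        ages = self._ages(bg, rng)
        module = list(rng.choice(bg, size=20, replace=False))
        strict = age_permutation_enrichment(module, ages, bg, n_perm=300, seed=5, strict=True)
        loose = age_permutation_enrichment(module, ages, bg, n_perm=300, seed=5, strict=False)
        assert (strict.p <= loose.p).all()
        assert (strict.p < loose.p).any()


class TestReaders:
    def test_gene_sets_gmt_round_trip(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("alpha\tdesc\tg1\tg2\tg3\nbeta\tdesc\tg2\tg4\n")
        sets = read_gene_sets(path)
        assert sets == {"alpha": {"g1", "g2", "g3"}, "beta": {"g2", "g4"}}

    def test_age_table_reader(self, tmp_path):
        path = tmp_path / "ages.tsv"
        path.write_text("gene\tstratum\ng1\tCellLife\ng2\tDrosophila\n")
        assert read_age_table(path) == {"g1": "CellLife", "g2": "Drosophila"}

    def test_duplicate_gene_rejected(self, tmp_path):
        path = tmp_path / "ages.tsv"
        path.write_text("g1\tCellLife\ng1\tMetazoa\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_age_table(path)
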