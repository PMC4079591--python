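"""Differentiation tests, FDR, Venn partitioning and diversity ranking."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from metaland import popgen
from metaland.datatypes import GenotypeMatrix
from metaland.snp_calling import SnpPanel, call_snps, score_genotypes


def _panel(ref_by_pop, alt_by_pop):
    pops = list(ref_by_pop)
    n = len(next(iter(ref_by_pop.values())))
    ids = pd.Index([f"snp{i}" for i in range(n)], name="snp")
    return SnpPanel(
        snp_ids=ids,
        populations=pops,
        ref_alleles=pd.DataFrame(ref_by_pop, index=ids),
        alt_alleles=pd.DataFrame(alt_by_pop, index=ids),
        filters=pd.DataFrame(index=ids),
    )


def _genotypes(dosage, populations):
    dosage = np.asarray(dosage, dtype=float)
    ids = pd.Index([f"snp{i}" for i in range(dosage.shape[0])], name="snp")
    pops = pd.Series(
        populations, index=pd.Index([f"i{j}" for j in range(dosage.shape[1])], name="individual")
    )
    return GenotypeMatrix(snp_ids=ids, populations=pops, dosage=dosage)


class TestFisher:
    def test_equal_proportions_give_p_one(self):
        panel = _panel({"A": [10], "B": [10]}, {"A": [10], "B": [10]})
        assert popgen.fisher_pairwise(panel, ["A"], ["B"]).iloc[0] == 1.0

    def test_extreme_table_matches_hypergeometric_enumeration(self):
        # [[20,0],[0,20]]: only the two extreme tables are as or more extreme
        panel = _panel({"A": [20], "B": [0]}, {"A": [0], "B": [20]})
        p = popgen.fisher_pairwise(panel, ["A"], ["B"]).iloc[0]
        assert p == pytest.approx(2.0 / comb(40, 20), rel=1e-9)

    def test_invariant_to_group_swap_and_allele_swap(self, small_study):
        panel = call_snps(small_study.allele_counts)
        sub = panel.snp_ids[:50]
        panel = SnpPanel(
            sub, panel.populations,
            panel.ref_alleles.loc[sub], panel.alt_alleles.loc[sub], panel.filters.loc[sub],
        )
        p1 = popgen.fisher_pairwise(panel, ["AL", "UP"], ["SA", "OL"])
        p2 = popgen.fisher_pairwise(panel, ["SA", "OL"], ["AL", "UP"])
        swapped = SnpPanel(
            panel.snp_ids, panel.populations, panel.alt_alleles, panel.ref_alleles, panel.filters
        )
        p3 = popgen.fisher_pairwise(swapped, ["AL", "UP"], ["SA", "OL"])
        np.testing.assert_allclose(p1, p2, rtol=1e-12)
        np.testing.assert_allclose(p1, p3, rtol=1e-12)

    def test_zero_count_group_is_missing(self):
        panel = _panel({"A": [0], "B": [10]}, {"A": [0], "B": [10]})
        assert np.isnan(popgen.fisher_pairwise(panel, ["A"], ["B"]).iloc[0])


class TestBhFdr:
    def test_single_test_unchanged(self):
        assert popgen.bh_fdr([0.01])[0] == pytest.approx(0.01)

    def test_step_up_by_hand(self):
        # q_i = min over j>=i of p_j * n / j: all become 0.04
        np.testing.assert_allclose(popgen.bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_all_ones(self):
        assert (popgen.bh_fdr([1.0, 1.0, 1.0]) == 1.0).all()

    def test_nan_propagates(self):
        q = popgen.bh_fdr([0.01, np.nan, 0.5])
        assert np.isnan(q[1]) and not np.isnan(q[0])

    def test_q_at_least_p(self, small_study):
        panel = call_snps(small_study.allele_counts)
        p = popgen.fisher_pairwise(panel, ["AL", "UP"], ["SA", "OL"]).to_numpy()
        q = popgen.bh_fdr(p)
        ok = ~np.isnan(p)
        assert (q[ok] >= p[ok] - 1e-12).all()


class TestLandscapePermutation:
    def test_zero_difference_gives_p_one(self):
        d = np.tile([0, 1, 2, 1], (3, 6))  # identical composition in both groups
        g = _genotypes(d, ["P1"] * 12 + ["P2"] * 12)
        land = g.populations.map({"P1": "fragmented", "P2": "continuous"})
        out = popgen.landscape_permutation_test(g, land, n_perm=200, seed=0)
        assert (out["p"] == 1.0).all()

    def test_reproducible_and_floor(self, small_study):
        called = score_genotypes(small_study.allele_counts)
        sub = called.snp_ids[:80]
        a = popgen.landscape_permutation_test(
            called, small_study.metadata.landscape, n_perm=300, seed=5, snp_ids=sub
        )
        b = popgen.landscape_permutation_test(
            called, small_study.metadata.landscape, n_perm=300, seed=5, snp_ids=sub
        )
        pd.testing.assert_frame_equal(a, b)
        assert (a["p"] >= 1.0 / 301).all()

    def test_null_p_uniformity(self):
        """With zero drift individuals are exchangeable, so permutation
        p-values are uniform.  (With drift > 0 the populations genuinely
        differ and individual-level permutation is anti-conservative.)"""
        from scipy.stats import kstest

        from metaland.simulate import StudyConfig, simulate_study

        cfg = StudyConfig(
            n_snps=500, n_genes=50, n_individuals_per_population=(15, 15, 15, 15),
            population_drift={p: 0.0 for p in ("AL", "UP", "SA", "OL")},
            n_landscape_snps=0, n_landscape_de_genes=0, n_sex_de_genes=0,
            n_eqtl_pairs=0, n_mixture_genes=0, mean_coverage_per_snp=40.0, seed=17,
        )
        study = simulate_study(cfg)
        called = score_genotypes(study.allele_counts)
        panel = call_snps(study.allele_counts, genotypes=called)
        out = popgen.landscape_permutation_test(
            called, study.metadata.landscape, n_perm=1000, seed=11, snp_ids=panel.snp_ids
        )
        p = out["p"].dropna()
        # the |freq difference| statistic is discrete with an atom at 0, so
        # p-values are super-uniform (conservative): check no excess of
        # small p-values and calibrated rejection rates
        assert kstest(p, "uniform", alternative="greater").pvalue > 0.01
        for alpha in (0.01, 0.05, 0.10):
            assert (p < alpha).mean() <= alpha + 3 * np.sqrt(alpha * (1 - alpha) / len(p))

    def test_permutation_flags_cover_most_fisher_flags(self, small_study):
        """Fisher is the more conservative of the two tests on the same data."""
        called = score_genotypes(small_study.allele_counts)
        panel = call_snps(small_study.allele_counts, genotypes=called)
        fisher_q = pd.Series(
            popgen.bh_fdr(popgen.fisher_pairwise(panel, ["AL", "UP"], ["SA", "OL"])),
            index=panel.snp_ids,
        )
        perm = popgen.landscape_permutation_test(
            called, small_study.metadata.landscape, n_perm=2000, seed=1, snp_ids=panel.snp_ids
        )
        fisher_hits = set(panel.snp_ids[fisher_q < 0.05])
        perm_hits = set(perm.index[perm["q"] < 0.05])
        assert len(fisher_hits) > 0
        assert len(fisher_hits & perm_hits) / len(fisher_hits) > 0.8


class TestVenn:
    def test_no_significant_snps(self):
        ids = pd.Index(["a", "b"], name="snp")
        res = {f"pair{k}": pd.Series([0.9, 0.8], index=ids) for k in range(3)}
        venn = popgen.venn_partition(res)
        assert venn.union_size() == 0

    def test_center_region(self):
        ids = pd.Index(["a"], name="snp")
        res = {f"pair{k}": pd.Series([0.001], index=ids) for k in range(3)}
        venn = popgen.venn_partition(res)
        assert venn.regions[("pair0", "pair1", "pair2")] == 1
        assert venn.union_size() == 1

    def test_mismatched_snp_sets_rejected(self):
        res = {
            "a": pd.Series([0.5], index=pd.Index(["x"], name="snp")),
            "b": pd.Series([0.5], index=pd.Index(["y"], name="snp")),
        }
        with pytest.raises(ValueError, match="mismatched"):
            popgen.venn_partition(res)

    def test_landscape_pairing_dominates_on_shifted_data(self, small_study):
        panel = call_snps(small_study.allele_counts)
        pairings = popgen.pair_partitions(["AL", "UP", "SA", "OL"])
        qv = {}
        for pairing in pairings:
            name = popgen.pairing_name(pairing)
            p = popgen.fisher_pairwise(panel, list(pairing[0]), list(pairing[1]))
            qv[name] = pd.Series(popgen.bh_fdr(p), index=p.index)
        venn = popgen.venn_partition(qv)
        land = "AL+UP|SA+OL"
        others = [n for n in qv if n != land]
        assert venn.set_size(land) > max(venn.set_size(n) for n in others)


class TestDiversity:
    def test_rank_counts_sum_to_reps(self, small_study):
        called = score_genotypes(small_study.allele_counts)
        tally = popgen.diversity_ranking(called, subsample=10, reps=20, seed=0)
        assert (tally.sum(axis=1) == 20).all()

    def test_single_rep_deterministic(self, small_study):
        called = score_genotypes(small_study.allele_counts)
        a = popgen.diversity_ranking(called, subsample=10, reps=1, seed=4)
        b = popgen.diversity_ranking(called, subsample=10, reps=1, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_high_diversity_population_ranks_first(self):
        rng = np.random.default_rng(8)
        n_snps, per_pop = 400, 15
        # P1 polymorphic at every SNP; others monomorphic at half the SNPs
        freqs = {
            "P1": rng.uniform(0.3, 0.7, n_snps),
            "P2": np.where(rng.random(n_snps) < 0.5, 0.0, rng.uniform(0.3, 0.7, n_snps)),
            "P3": np.where(rng.random(n_snps) < 0.5, 0.0, rng.uniform(0.3, 0.7, n_snps)),
        }
        dosage = np.hstack(
            [rng.binomial(2, freqs[p][:, None], (n_snps, per_pop)).astype(float) for p in freqs]
        )
        g = _genotypes(dosage, ["P1"] * 15 + ["P2"] * 15 + ["P3"] * 15)
        tally = popgen.diversity_ranking(g, subsample=10, reps=100, seed=1)
        assert tally.loc["P1", 1] > 80

    def test_insufficient_individuals_rejected(self):
        g = _genotypes(np.ones((5, 8)), ["P1"] * 4 + ["P2"] * 4)
        with pytest.raises(ValueError, match="fewer"):
            popgen.diversity_ranking(g, subsample=10)


class TestDissimilarity:
    def test_identical_zero_discordant_one_symmetric(self):
        d = np.array([[0, 0, 2], [1, 1, 0], [2, 2, 1]], dtype=float)
        g = _genotypes(d, ["P1"] * 3)
        assert popgen.genotype_dissimilarity(g, "i0", "i1") == 0.0
        assert popgen.genotype_dissimilarity(g, "i0", "i2") == 1.0
        assert popgen.genotype_dissimilarity(g, "i1", "i2") == popgen.genotype_dissimilarity(
            g, "i2", "i1"
        )

    def test_no_shared_snps_flagged(self):
        d = np.array([[0, np.nan], [np.nan, 1]])
        g = _genotypes(d, ["P1"] * 2)
        with pytest.raises(ValueError, match="share"):
            popgen.genotype_dissimilarity(g, "i0", "i1")

    def test_matrix_matches_pairwise(self, small_study):
        from metaland.snp_calling import score_genotypes

        called = score_genotypes(small_study.allele_counts)
        inds = called.individuals[:6]
        sub = GenotypeMatrix(
            snp_ids=called.snp_ids,
            populations=called.populations[inds],
            dosage=called.dosage[:, :6],
        )
        mat = popgen.dissimilarity_matrix(sub)
        for i in inds:
            for j in inds:
                if i != j:
                    assert mat.loc[i, j] == pytest.approx(
                        popgen.genotype_dissimilarity(sub, i, j)
                    )
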