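"""TMM normalization, NB-GLM LRT and the consistency permutation test."""

import subprocess

import numpy as np
import pandas as pd
import pytest

from metaland.datatypes import ExpressionMatrix
from metaland.expression import (
    consistency_permutation_test,
    landscape_de_genes,
    nb_glm_lrt,
    normalize,
    run_de,
    tmm_factors,
)

LANDSCAPE = {"AL": "fragmented", "UP": "fragmented", "SA": "continuous", "OL": "continuous"}


def _pops(per=3):
    idx = pd.Index(
        [f"{p}_{i}" for p in ("AL", "UP", "SA", "OL") for i in range(per)], name="individual"
    )
    return pd.Series([s.split("_")[0] for s in idx], index=idx)


class TestTmm:
    def test_identical_libraries_factor_one(self):
        counts = pd.DataFrame({"a": [10, 20, 30, 5], "b": [10, 20, 30, 5]})
        np.testing.assert_allclose(tmm_factors(counts), 1.0)

    def test_pure_depth_difference_absorbed(self):
        a = np.array([10, 20, 30, 5, 100, 7])
        counts = pd.DataFrame({"a": a, "b": 2 * a})
        np.testing.assert_allclose(tmm_factors(counts), 1.0, atol=1e-12)

    def test_scaling_one_individual_leaves_factors_invariant(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(rng.poisson(50, size=(200, 4)), columns=list("abcd"))
        f1 = tmm_factors(counts)
        scaled = counts.copy()
        scaled["c"] = scaled["c"] * 7
        f2 = tmm_factors(scaled)
        # M-values are depth-normalized, so factors move only through the
        # count-dependent precision weights: near-invariant, not exact
        np.testing.assert_allclose(f1, f2, atol=5e-3)

    def test_matches_edger_reference_implementation(self):
        """Cross-check against the published TMM implementation, including a
        5% spike-in that drags the spiked individual's factor below 1."""
        rng = np.random.default_rng(5)
        counts = pd.DataFrame(
            rng.negative_binomial(5, 0.01, size=(300, 6)),
            index=[f"g{i}" for i in range(300)],
            columns=[f"i{j}" for j in range(6)],
        )
        spike = rng.choice(300, 15, replace=False)
        counts.iloc[spike, 0] *= 8
        mine = tmm_factors(counts)
        assert mine.iloc[0] < 1.0
        script = (
            "suppressMessages(library(edgeR));"
            "x <- as.matrix(read.delim('stdin', row.names=1));"
            "cat(sprintf('%.8f', calcNormFactors(x, method='TMM')), sep='\\n')"
        )
        proc = subprocess.run(
            ["Rscript", "-e", script],
            input=counts.to_csv(sep="\t"),
            capture_output=True,
            text=True,
            check=True,
        )
        edger = np.array([float(v) for v in proc.stdout.split()])
        np.testing.assert_allclose(mine.to_numpy(), edger, atol=5e-4)

    def test_all_zero_individual_rejected(self):
        counts = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(ValueError, match="all-zero"):
            tmm_factors(counts)


def _expr_from(counts: np.ndarray, pops: pd.Series) -> ExpressionMatrix:
    genes = pd.Index([f"g{i}" for i in range(counts.shape[0])], name="gene")
    e = ExpressionMatrix(counts=pd.DataFrame(counts, index=genes, columns=pops.index))
    e.tmm = pd.Series(1.0, index=pops.index)
    return e


class TestNbGlmLrt:
    def test_constant_gene_has_zero_statistic(self):
        pops = _pops(3)
        counts = np.vstack(
            [np.full(12, 50), np.random.default_rng(0).poisson(30, 12)]
        )
        expr = _expr_from(counts, pops)
        res = nb_glm_lrt(expr, pops, LANDSCAPE)
        # equal library sizes here, so a constant gene carries no contrast
        assert res.loc["g0", "log2fc"] == 0.0
        assert res.loc["g0", "p"] == 1.0
        assert res.loc["g0", "lrt_stat"] == 0.0

    def test_all_zero_gene_gets_missing_p(self):
        pops = _pops(3)
        counts = np.vstack([np.zeros(12, dtype=int), np.full(12, 20)])
        expr = _expr_from(counts, pops)
        res = nb_glm_lrt(expr, pops, LANDSCAPE)
        assert np.isnan(res.loc["g0", "p"])

    def test_lrt_statistic_nonnegative_and_p_monotone(self, small_study):
        normalize(small_study.expression)
        res = nb_glm_lrt(
            small_study.expression,
            small_study.metadata.populations,
            small_study.config.landscape_of_population,
        )
        ok = res.dropna(subset=["lrt_stat"])
        assert (ok["lrt_stat"] >= 0).all()
        srt = ok.sort_values("lrt_stat")
        assert (np.diff(srt["p"]) <= 1e-12).all()

    def test_null_type_one_error_calibrated(self, null_study):
        normalize(null_study.expression)
        res = nb_glm_lrt(
            null_study.expression,
            null_study.metadata.populations,
            null_study.config.landscape_of_population,
        )
        p = res["p"].dropna()
        rate = (p < 0.05).mean()
        assert 0.01 <= rate <= 0.09  # 400 genes: wide binomial band around 0.05

    def test_recovers_planted_log2_effect(self, small_study):
        normalize(small_study.expression)
        res = nb_glm_lrt(
            small_study.expression,
            small_study.metadata.populations,
            small_study.config.landscape_of_population,
        )
        tr = small_study.truth["landscape_de"].set_index("gene")
        oriented = res.loc[tr.index, "log2fc"] * tr["sign"]
        assert np.median(oriented) == pytest.approx(1.0, abs=0.2)


class TestConsistencyPermutation:
    def test_interleaved_means_are_inconsistent(self):
        pops = _pops(4)
        # fragmented pop means 5 and 4; continuous 4.5 and 3 -> interleaved
        means = {"AL": 5.0, "UP": 4.0, "SA": 4.5, "OL": 3.0}
        log_counts = pd.DataFrame(
            [[means[p] for p in pops]], index=pd.Index(["g0"], name="gene"), columns=pops.index
        )
        out = consistency_permutation_test(log_counts, pops, LANDSCAPE, n_perm=200, seed=0)
        assert not out.loc["g0", "consistent"]
        assert out.loc["g0", "p"] == 1.0

    def test_equal_means_give_p_one(self):
        pops = _pops(4)
        log_counts = pd.DataFrame(
            np.full((2, 16), 3.0), index=pd.Index(["g0", "g1"], name="gene"), columns=pops.index
        )
        out = consistency_permutation_test(log_counts, pops, LANDSCAPE, n_perm=200, seed=0)
        assert (out["p"] == 1.0).all()

    def test_null_rejection_at_most_alpha(self, null_study):
        normalize(null_study.expression)
        out = consistency_permutation_test(
            null_study.expression.log_cpm(),
            null_study.metadata.populations,
            null_study.config.landscape_of_population,
            n_perm=1000,
            seed=2,
        )
        n = len(out)
        assert (out["p"] < 0.05).mean() <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n)

    def test_seeded_reproducibility_and_floor(self, small_study):
        normalize(small_study.expression)
        args = (
            small_study.expression.log_cpm().iloc[:50],
            small_study.metadata.populations,
            small_study.config.landscape_of_population,
        )
        a = consistency_permutation_test(*args, n_perm=500, seed=9)
        b = consistency_permutation_test(*args, n_perm=500, seed=9)
        pd.testing.assert_frame_equal(a, b)
        assert (a["p"] >= 1.0 / 501).all()


class TestIntersection:
    def test_empty_input(self):
        de = pd.DataFrame(columns=["q", "perm_q", "log2fc"])
        assert len(landscape_de_genes(de)) == 0

    def test_lrt_only_gene_excluded(self):
        de = pd.DataFrame(
            {"q": [0.01, 0.01], "perm_q": [0.5, 0.01], "log2fc": [1.0, -2.0]},
            index=["g0", "g1"],
        )
        hits = landscape_de_genes(de)
        assert list(hits.index) == ["g1"]
        assert hits.loc["g1", "direction"] == -1

    def test_monotone_in_alpha(self, small_study):
        de = run_de(
            small_study.expression,
            small_study.metadata.populations,
            small_study.config.landscape_of_population,
            n_perm=500,
            seed=0,
        )
        sets = [set(landscape_de_genes(de, alpha=a).index) for a in (0.01, 0.05, 0.10)]
        assert sets[0] <= sets[1] <= sets[2]

    def test_recovered_genes_all_match_truth_direction(self, small_study):
        de = run_de(
            small_study.expression,
            small_study.metadata.populations,
            small_study.config.landscape_of_population,
            n_perm=1000,
            seed=0,
        )
        tr = small_study.truth["landscape_de"].set_index("gene")
        hits = landscape_de_genes(de)
        recovered = hits.index.intersection(tr.index)
        assert len(recovered) / len(tr) > 0.5
        assert (hits.loc[recovered, "direction"] == tr.loc[recovered, "sign"]).all()
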