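"""Generator behaviour: drift structure, read model, expression effects,
round-trip I/O and reproducibility."""

import numpy as np
import pandas as pd
import pytest

from metaland import io
from metaland.simulate import (
    StudyConfig,
    simulate_allele_reads,
    simulate_expression,
    simulate_genotypes,
    simulate_study,
)

from conftest import weir_cockerham_fst


def _config(**kw):
    base = dict(
        n_snps=200,
        n_genes=150,
        n_individuals_per_population=(12, 12, 12, 12),
        n_landscape_snps=0,
        n_landscape_de_genes=0,
        n_sex_de_genes=0,
        n_eqtl_pairs=0,
        n_mixture_genes=0,
        seed=1,
    )
    base.update(kw)
    return StudyConfig(**base)


class TestGenotypes:
    def test_zero_drift_recovers_ancestral_frequency(self):
        cfg = _config(population_drift={p: 0.0 for p in ("AL", "UP", "SA", "OL")})
        _, freqs, _, _ = simulate_genotypes(cfg)
        spread = freqs.max(axis=1) - freqs.min(axis=1)
        assert (spread == 0).all()

    def test_zero_landscape_shift_is_null(self):
        cfg = _config(n_snps=3000, landscape_freq_shift=0.0, n_landscape_snps=0)
        _, freqs, _, _ = simulate_genotypes(cfg)
        diff = freqs[["AL", "UP"]].mean(axis=1) - freqs[["SA", "OL"]].mean(axis=1)
        # Monte-Carlo error of a mean of 3000 i.i.d. drift deviations
        assert abs(diff.mean()) < 3 * diff.std() / np.sqrt(len(diff))

    def test_fst_matches_drift_parameter(self):
        cfg = _config(
            n_snps=10_000,
            n_individuals_per_population=(50, 50, 50, 50),
            population_drift={p: 0.05 for p in ("AL", "UP", "SA", "OL")},
        )
        genotypes, _, _, _ = simulate_genotypes(cfg)
        fst = weir_cockerham_fst(genotypes.dosage, genotypes.populations)
        assert fst == pytest.approx(0.05, abs=0.02)

    def test_degenerate_drift_rejected(self):
        with pytest.raises(ValueError, match="drift"):
            _config(population_drift={"AL": 1.0, "UP": 0.05, "SA": 0.05, "OL": 0.05})

    def test_landscape_map_must_cover_both_types(self):
        with pytest.raises(ValueError, match="landscape"):
            _config(landscape_of_population={p: "fragmented" for p in ("AL", "UP", "SA", "OL")})


class TestAlleleReads:
    def test_dosage_zero_gives_no_alt_reads(self):
        cfg = _config()
        genotypes, _, snp_table, _ = simulate_genotypes(cfg)
        genotypes.dosage[:] = 0.0
        reads = simulate_allele_reads(genotypes, cfg, snp_table=snp_table)
        assert (reads.alt_count == 0).all()
        assert (reads.ref_count == reads.depth()).all()

    def test_zero_coverage_means_zero_depth(self):
        cfg = _config(mean_coverage_per_snp=0.0)
        genotypes, _, snp_table, _ = simulate_genotypes(cfg)
        reads = simulate_allele_reads(genotypes, cfg, snp_table=snp_table)
        assert (reads.depth() == 0).all()

    def test_het_allele_fraction_converges_to_half(self):
        cfg = _config(n_snps=50, mean_coverage_per_snp=20_000.0)
        genotypes, _, snp_table, _ = simulate_genotypes(cfg)
        genotypes.dosage[:] = 1.0
        reads = simulate_allele_reads(genotypes, cfg, snp_table=snp_table)
        frac = reads.alt_count / reads.depth()
        # binomial error at depth 2e4 is ~0.0035; average over entries
        assert np.abs(frac.mean() - 0.5) < 0.001
        assert np.abs(frac - 0.5).max() < 0.03

    def test_negative_coverage_rejected(self):
        with pytest.raises(ValueError, match="coverage"):
            _config(mean_coverage_per_snp=-1.0)


class TestExpression:
    def test_nb_tends_to_poisson_at_small_dispersion(self):
        cfg = _config(
            n_genes=40,
            n_individuals_per_population=(250, 250, 250, 250),
            nb_dispersion_range=(1e-6, 2e-6),
            library_size_range=(1_000_000, 1_000_000),
        )
        genotypes, *_ = simulate_genotypes(cfg)
        expr, _, _ = simulate_expression(cfg, genotypes)
        counts = expr.counts.to_numpy(float)
        mean = counts.mean(axis=1)
        ratio = counts.var(axis=1) / mean
        ok = mean > 10
        assert np.median(np.abs(ratio[ok] - 1.0)) < 0.15

    def test_landscape_effect_doubles_group_mean_cpm(self):
        cfg = _config(
            n_genes=300,
            n_individuals_per_population=(125, 125, 125, 125),
            n_landscape_de_genes=40,
            landscape_log2_effect=1.0,
            nb_dispersion_range=(0.05, 0.2),
        )
        genotypes, *_ = simulate_genotypes(cfg)
        expr, metadata, truth = simulate_expression(cfg, genotypes)
        cpm = expr.counts / expr.counts.sum(axis=0).to_numpy()[None, :] * 1e6
        frag = metadata.landscape == "fragmented"
        de = truth["landscape_de"].set_index("gene")
        ratio = (
            cpm.loc[de.index, frag.index[frag]].mean(axis=1)
            / cpm.loc[de.index, frag.index[~frag]].mean(axis=1)
        ) ** de["sign"]
        assert np.median(ratio) == pytest.approx(2.0, rel=0.1)

    def test_zero_eqtl_beta_recovers_null_slope(self):
        cfg = _config(n_genes=200, n_snps=300, n_eqtl_pairs=10, eqtl_beta=0.0,
                      n_landscape_snps=50)
        study = simulate_study(cfg)
        truth = study.truth["eqtl"]
        assert len(truth) > 0
        log_e = np.log1p(study.expression.counts)
        betas = []
        for _, row in truth.iterrows():
            snp_i = study.truth_genotypes.snp_ids.get_loc(row["snp"])
            d = study.truth_genotypes.dosage[snp_i]
            y = log_e.loc[row["gene"]].to_numpy()
            betas.append(np.polyfit(d, y, 1)[0])
        assert np.abs(np.mean(betas)) < 0.15

    def test_nonpositive_dispersion_rejected(self):
        with pytest.raises(ValueError, match="dispersion"):
            _config(nb_dispersion_range=(0.0, 0.1))


class TestRoundTrip:
    def test_write_read_identical(self, small_study, tmp_path):
        io.write_study(small_study, tmp_path)
        back = io.read_study(tmp_path)
        assert np.array_equal(back["allele_counts"].ref_count, small_study.allele_counts.ref_count)
        assert np.array_equal(back["allele_counts"].alt_count, small_study.allele_counts.alt_count)
        assert np.array_equal(
            back["genotypes"].dosage, small_study.truth_genotypes.dosage, equal_nan=True
        )
        assert back["expression"].counts.equals(small_study.expression.counts)
        assert back["metadata"].table.equals(small_study.metadata.table)

    def test_empty_study_yields_header_only_vcf(self, tmp_path):
        cfg = _config(n_snps=0)
        study = simulate_study(cfg)
        io.write_study(study, tmp_path)
        lines = (tmp_path / "genotypes.vcf").read_text().splitlines()
        assert all(l.startswith("#") for l in lines)

    def test_missing_genotype_written_as_dot_slash_dot(self, tmp_path):
        snps = pd.DataFrame(
            {"scaffold": ["s1"], "pos": [10], "ref": ["A"], "alt": ["G"]},
            index=pd.Index(["snp1"], name="snp"),
        )
        inds = pd.Index(["i1", "i2"], name="individual")
        io.write_vcf(tmp_path / "x.vcf", snps, inds, dosage=np.array([[np.nan, 1.0]]))
        body = [l for l in (tmp_path / "x.vcf").read_text().splitlines() if not l.startswith("#")]
        assert "./." in body[0] and "0/1" in body[0]

    def test_same_seed_reproduces_byte_identical_files(self, tmp_path):
        cfg = _config(n_snps=80, n_genes=60)
        a, b = tmp_path / "a", tmp_path / "b"
        io.write_study(simulate_study(cfg), a)
        io.write_study(simulate_study(cfg), b)
        for f in a.iterdir():
            assert f.read_bytes() == (b / f.name).read_bytes()
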