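"""End-to-end orchestration of the analysis stages.

``run_pipeline`` executes the enabled stages in dependency order on either
a simulated study or files on disk, writing per-stage TSV/JSON outputs and
a manifest that records parameters, seeds and per-stage row counts.  The
manifest deliberately excludes wall-clock information so two runs with the
same config and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import bayes_cluster, eqtl, expression, integrate, io, popgen, snp_calling
from . import vb_gmm as vbg
from .simulate import StudyConfig, SyntheticStudy, simulate_study

ALL_STAGES = ("simulate", "snps", "popgen", "de", "partitions", "gmm", "eqtl", "integrate")


@dataclass
class PipelineConfig:
    out_dir: str = "metaland_run"
    input_dir: Optional[str] = None  # read a study from disk instead of simulating
    stages: List[str] = field(default_factory=lambda: list(ALL_STAGES))
    seed: int = 0
    alpha: float = 0.05
    n_perm_de: int = 10_000
    n_perm_af: int = 1_000
    dispersion_prior_df: float = 10.0
    min_individuals_per_pop: int = 10
    mac_fraction: float = 0.05
    het_min_each: int = 3
    hom_min: int = 10
    diversity_subsample: int = 10
    diversity_reps: int = 100
    gmm_k_max: int = 5
    gmm_max_genes: int = 100
    gmm_min_logcpm: float = 1.0
    eqtl_max_snps: int = 500
    cpm_floor: float = 1.0
    ratio_floor: float = 1.0
    simulation: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def demo_config(out_dir: str = "metaland_demo", seed: int = 0) -> PipelineConfig:
    """A desk-scale configuration exercising every stage in minutes."""
    return PipelineConfig(
        out_dir=out_dir,
        seed=seed,
        n_perm_de=2_000,
        n_perm_af=500,
        gmm_max_genes=40,
        eqtl_max_snps=200,
        diversity_reps=25,
        simulation={
            "n_snps": 2_000,
            "n_genes": 1_000,
            "n_individuals_per_population": (15, 15, 15, 15),
            "n_landscape_snps": 200,
            "n_landscape_de_genes": 60,
            "n_sex_de_genes": 20,
            "n_eqtl_pairs": 10,
            "n_mixture_genes": 15,
            "mean_coverage_per_snp": 25.0,
        },
    )


def validate_inputs(paths: Dict[str, str]) -> Dict[str, object]:
    """Check ID concordance and value sanity across study files.

    ``paths`` carries ``vcf``, ``expression`` and ``metadata`` entries.
    Returns ``{"violations": [...], "fatal": bool}``.
    """
    violations: List[str] = []
    try:
        metadata = io.read_metadata_tsv(paths["metadata"])
    except Exception as exc:  # noqa: BLE001 - reported, not raised
        return {"violations": [f"metadata unreadable: {exc}"], "fatal": True}
    if metadata.individuals.duplicated().any():
        violations.append("duplicate individual ids in metadata")
    try:
        expr = io.read_expression_tsv(paths["expression"])
        if (expr.counts.to_numpy() < 0).any():
            violations.append("negative expression counts")
        missing = set(expr.individuals) - set(metadata.individuals)
        if missing:
            violations.append(f"expression individuals missing from metadata: {sorted(missing)}")
        if expr.genes.duplicated().any():
            violations.append("duplicate gene ids in expression matrix")
    except ValueError as exc:
        violations.append(f"expression matrix invalid: {exc}")
    try:
        counts, _ = io.read_vcf(paths["vcf"], metadata.populations)
        if counts.snp_ids.duplicated().any():
            violations.append("duplicate SNP ids in VCF")
    except ValueError as exc:
        violations.append(f"VCF invalid: {exc}")
    return {"violations": violations, "fatal": bool(violations)}


class StageError(RuntimeError):
    def __init__(self, stage: str, error: Exception):
        super().__init__(f"stage {stage!r} failed: {error}")
        self.record = {"stage": stage, "error": str(error)}


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (pd.Index, np.ndarray)):
        return list(o)
    raise TypeError(f"unserializable {type(o)}")


def run_pipeline(config: PipelineConfig, study: Optional[SyntheticStudy] = None) -> Dict[str, object]:
    """Execute the enabled stages; returns the manifest dict.

    Outputs land under ``config.out_dir``; failures abort with a
    :class:`StageError` naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: Dict[str, object] = {
        "config": dataclasses.asdict(config),
        "stages": {},
    }
    stages = list(config.stages)

    counts = genotypes_truth = expr = metadata = gene_table = None
    truth: Dict[str, pd.DataFrame] = {}

    def record(stage: str, **info):
        manifest["stages"][stage] = info

    # --- data acquisition ---------------------------------------------
    try:
        if study is not None:
            pass
        elif config.input_dir is not None:
            loaded = io.read_study(config.input_dir)
            counts = loaded["allele_counts"]
            genotypes_truth = loaded["genotypes"]
            expr = loaded["expression"]
            metadata = loaded["metadata"]
            gene_table = loaded["gene_table"]
            truth = loaded["truth"]
        elif "simulate" in stages:
            sim_cfg = StudyConfig(seed=config.seed, **config.simulation)
            study = simulate_study(sim_cfg)
        if study is not None:
            counts = study.allele_counts
            genotypes_truth = study.truth_genotypes
            expr = study.expression
            metadata = study.metadata
            gene_table = study.gene_table
            truth = study.truth
            if "simulate" in stages:
                io.write_study(study, out / "study")
                record(
                    "simulate",
                    n_snps=counts.n_snps,
                    n_genes=len(expr.genes),
                    n_individuals=counts.n_individuals,
                )
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("simulate", exc) from exc

    landscape_map = metadata.landscape_of_populations() if metadata is not None else {}

    panel = called = None
    if "snps" in stages:
        try:
            called = snp_calling.score_genotypes(
                counts, het_min_each=config.het_min_each, hom_min=config.hom_min
            )
            panel = snp_calling.call_snps(
                counts,
                min_individuals_per_pop=config.min_individuals_per_pop,
                mac_fraction=config.mac_fraction,
                genotypes=called,
            )
            panel.to_frame().to_csv(out / "snp_panel.tsv", sep="\t", index_label="snp")
            record("snps", n_input=counts.n_snps, n_retained=panel.n_snps)
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError("snps", exc) from exc

    landscape_hits: List[str] = []
    if "popgen" in stages:
        try:
            pairings = popgen.pair_partitions(list(pd.unique(metadata.populations)))
            qvals = {}
            for pairing in pairings:
                name = popgen.pairing_name(pairing)
                p = popgen.fisher_pairwise(panel, list(pairing[0]), list(pairing[1]))
                qvals[name] = pd.Series(popgen.bh_fdr(p), index=p.index)
            venn = popgen.venn_partition(qvals, alpha_fdr=config.alpha)
            with open(out / "venn.json", "w") as fh:
                json.dump(
                    {"|".join(k): v for k, v in venn.regions.items()}, fh, indent=1, sort_keys=True
                )
            perm = popgen.landscape_permutation_test(
                called,
                metadata.landscape,
                n_perm=config.n_perm_af,
                seed=config.seed,
                snp_ids=panel.snp_ids,
            )
            perm.to_csv(out / "landscape_af_permutation.tsv", sep="\t", index_label="snp")
            landscape_hits = perm.index[perm["q"] < config.alpha].tolist()
            ranking = popgen.diversity_ranking(
                called,
                subsample=config.diversity_subsample,
                reps=config.diversity_reps,
                seed=config.seed,
            )
            ranking.to_csv(out / "diversity_ranking.tsv", sep="\t")
            record(
                "popgen",
                n_panel_snps=panel.n_snps,
                n_landscape_significant=len(landscape_hits),
                venn_union=venn.union_size(),
            )
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError("popgen", exc) from exc

    de = None
    if "de" in stages:
        try:
            de = expression.run_de(
                expr,
                metadata.populations,
                landscape_map,
                alpha=config.alpha,
                n_perm=config.n_perm_de,
                seed=config.seed,
                prior_df=config.dispersion_prior_df,
            )
            de.to_csv(out / "differential_expression.tsv", sep="\t", index_label="gene")
            record("de", n_genes=len(de), n_de=int(de["de"].sum()))
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError("de", exc) from exc

    z = None
    if "partitions" in stages:
        try:
            z = bayes_cluster.standardize_expression(expr)
            scores = bayes_cluster.score_partitions(z, metadata.populations)
            with open(out / "partition_scores.json", "w") as fh:
                json.dump([s.to_dict() for s in scores], fh, indent=1)
            record("partitions", n_partitions=len(scores), best=scores[0].to_dict())
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError("partitions", exc) from exc

    if "gmm" in stages:
        try:
            if z is None:
                z = bayes_cluster.standardize_expression(expr)
            mean_logcpm = expr.log_cpm().mean(axis=1)
            eligible = mean_logcpm[mean_logcpm > config.gmm_min_logcpm].index
            eligible = [g for g in eligible if g in z.index][: config.gmm_max_genes]
            screen = vbg.screen_heterogeneity(
                z.loc[eligible], k_max=config.gmm_k_max, seed=config.seed
            )
            screen.to_csv(out / "gmm_screen.tsv", sep="\t")
            bimodal = screen.index[screen["best_k"] == 2]
            assoc_rows = 0
            if len(bimodal):
                labels = {}
                for i, gene in enumerate(bimodal):
                    sel = vbg.select_components(
                        z.loc[gene].to_numpy(),
                        k_max=config.gmm_k_max,
                        seed=vbg.child_seed(config.seed, list(z.index).index(gene)),
                    )
                    labels[gene] = vbg.classify_components(sel["best_fit"])
                label_df = pd.DataFrame.from_dict(labels, orient="index", columns=z.columns)
                assoc = vbg.association_screen(label_df, metadata.table["sex"])
                assoc.to_csv(out / "gmm_sex_association.tsv", sep="\t", index_label="gene")
                assoc_rows = len(assoc)
            record(
                "gmm",
                n_screened=len(screen),
                n_unimodal=int((screen["best_k"] == 1).sum()),
                n_bimodal=int((screen["best_k"] == 2).sum()),
                n_associations=assoc_rows,
            )
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError("gmm", exc) from exc

    if "eqtl" in stages:
        try:
            snp_ids = panel.snp_ids[: config.eqtl_max_snps]
            rows = called.snp_ids.get_indexer(snp_ids)
            sub = type(called)(
                snp_ids=snp_ids, populations=called.populations, dosage=called.dosage[rows]
            )
            snp_map = eqtl.nearest_gene_map(counts.snps.loc[snp_ids], gene_table)
            kinship = eqtl.relatedness_matrix(sub)
            hits = eqtl.screen_eqtl(
                expr,
                sub,
                snp_map,
                kinship=kinship,
                landscape_snps=landscape_hits or None,
                alpha=config.alpha,
            )
            hits.to_csv(out / "eqtl.tsv", sep="\t", index=False)
            record("eqtl", n_tested=len(hits), n_accepted=int(hits["accepted"].sum()) if len(hits) else 0)
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError("eqtl", exc) from exc

    if "integrate" in stages:
        try:
            if de is None:
                raise ValueError("integrate requires the de stage")
            de_genes = de.index[de["de"]]
            background = len(de_genes) / len(de)
            log_cpm = expr.log_cpm()
            mean_logcpm = log_cpm.mean(axis=1)
            new_old = _age_class_delta(expr, metadata)
            land_delta = integrate.landscape_log2_delta(expr, metadata.landscape)
            filt = integrate.filter_concordance_genes(
                de_genes,
                {"study": mean_logcpm, "study2": mean_logcpm},
                land_delta,
                cpm_floor=config.cpm_floor,
                ratio_floor=config.ratio_floor,
            )
            conc = None
            if len(filt["genes"]) >= 3 and new_old is not None:
                try:
                    res = integrate.concordance_test(
                        new_old.reindex(filt["genes"]), land_delta.reindex(filt["genes"])
                    )
                    conc = {"r": res.correlation, "p": res.p, "n": len(res.genes)}
                except ValueError:
                    conc = None
            summary = {
                "n_de": int(len(de_genes)),
                "background_rate": background,
                "filter_steps": filt["steps"],
                "new_vs_old_concordance": conc,
            }
            with open(out / "integration.json", "w") as fh:
                json.dump(summary, fh, indent=1, default=_json_default)
            record("integrate", **summary)
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError("integrate", exc) from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=_json_default)
    return manifest


def _age_class_delta(expr, metadata) -> Optional[pd.Series]:
    """New-vs-old population contrast inside the fragmented landscape."""
    table = metadata.table
    frag = table["landscape"] == "fragmented"
    new = table.index[frag & (table["age_class"] == "new")]
    old = table.index[frag & (table["age_class"] == "old")]
    if len(new) == 0 or len(old) == 0:
        return None
    log_cpm = expr.log_cpm()
    return log_cpm[new].mean(axis=1) - log_cpm[old].mean(axis=1)
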