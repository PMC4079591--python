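"""Reading and writing study files.

Genotype/read-count data travel as VCF 4.2 with GT and AD FORMAT fields
(read back through cyvcf2); expression and metadata as TSV.  ``write_study``
/ ``read_study`` round-trip a :class:`~metaland.simulate.SyntheticStudy`
losslessly apart from the simulation truth's dtypes.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .datatypes import AlleleCountMatrix, ExpressionMatrix, GenotypeMatrix, StudyMetadata

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=metaland
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths for the ref and alt alleles">
"""

_GT_BY_DOSAGE = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(
    path: os.PathLike,
    snps: pd.DataFrame,
    individuals: pd.Index,
    dosage: Optional[np.ndarray] = None,
    ref_count: Optional[np.ndarray] = None,
    alt_count: Optional[np.ndarray] = None,
) -> None:
    """Write SNPs as VCF 4.2 with GT (from dosage) and AD (from read counts).

    Missing dosages (NaN) become ``./.``; absent read counts become ``.,.``.
    """
    path = Path(path)
    try:
        with open(path, "w") as fh:
            fh.write(_VCF_HEADER)
            for scaf in pd.unique(snps["scaffold"]):
                fh.write(f"##contig=<ID={scaf}>\n")
            cols = "\t".join(individuals)
            fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{cols}\n")
            n = len(individuals)
            for row, (snp_id, rec) in enumerate(snps.iterrows()):
                fields = [
                    str(rec["scaffold"]),
                    str(int(rec["pos"])),
                    str(snp_id),
                    str(rec["ref"]),
                    str(rec["alt"]),
                    ".",
                    "PASS",
                    ".",
                    "GT:AD",
                ]
                for j in range(n):
                    if dosage is None or np.isnan(dosage[row, j]):
                        gt = "./."
                    else:
                        gt = _GT_BY_DOSAGE[float(dosage[row, j])]
                    if ref_count is None:
                        ad = ".,."
                    else:
                        ad = f"{int(ref_count[row, j])},{int(alt_count[row, j])}"
                    fields.append(f"{gt}:{ad}")
                fh.write("\t".join(fields) + "\n")
    except OSError as exc:
        raise OSError(f"failed writing VCF to {path}: {exc}") from exc


def read_vcf(path: os.PathLike, populations: pd.Series) -> Tuple[AlleleCountMatrix, GenotypeMatrix]:
    """Read GT and AD fields back into count and genotype matrices.

    ``populations`` must be indexed by the individual ids that appear in the
    VCF sample columns (any order; it is aligned to the file order).
    """
    path = str(path)
    vcf = VCF(path)
    samples = pd.Index(vcf.samples, name="individual")
    pops = populations.reindex(samples)
    if pops.isna().any():
        missing = samples[pops.isna()].tolist()
        raise ValueError(f"no population label for individuals {missing} in {path}")

    ids, scaffolds, positions, refs, alts = [], [], [], [], []
    dosages, refc, altc = [], [], []
    for v in vcf:
        ids.append(v.ID)
        scaffolds.append(v.CHROM)
        positions.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0] if v.ALT else ".")
        gts = np.array(v.genotypes, dtype=object)
        dos = np.full(len(samples), np.nan)
        for j, g in enumerate(gts):
            a, b = int(g[0]), int(g[1])
            if a >= 0 and b >= 0:
                dos[j] = a + b
        dosages.append(dos)
        ad = v.format("AD")
        if ad is None:
            refc.append(np.zeros(len(samples), dtype=int))
            altc.append(np.zeros(len(samples), dtype=int))
        else:
            ad = np.asarray(ad)
            ad = np.where(ad < 0, 0, ad)  # cyvcf2 encodes missing as negative
            refc.append(ad[:, 0].astype(int))
            altc.append(ad[:, 1].astype(int) if ad.shape[1] > 1 else np.zeros(len(samples), int))
    vcf.close()

    snps = pd.DataFrame(
        {"scaffold": scaffolds, "pos": positions, "ref": refs, "alt": alts},
        index=pd.Index(ids, name="snp"),
    )
    n_snps = len(snps)
    counts = AlleleCountMatrix(
        snps=snps,
        populations=pops,
        ref_count=np.array(refc).reshape(n_snps, len(samples)),
        alt_count=np.array(altc).reshape(n_snps, len(samples)),
    )
    genotypes = GenotypeMatrix(
        snp_ids=snps.index,
        populations=pops,
        dosage=np.array(dosages).reshape(n_snps, len(samples)),
    )
    return counts, genotypes


def write_expression_tsv(path: os.PathLike, expr: ExpressionMatrix) -> None:
    expr.counts.to_csv(path, sep="\t", index_label="gene")


def read_expression_tsv(path: os.PathLike) -> ExpressionMatrix:
    counts = pd.read_csv(path, sep="\t", index_col="gene")
    counts.columns.name = "individual"
    return ExpressionMatrix(counts=counts.astype(np.int64))


def write_metadata_tsv(path: os.PathLike, metadata: StudyMetadata) -> None:
    metadata.table.to_csv(path, sep="\t", index_label="individual")


def read_metadata_tsv(path: os.PathLike) -> StudyMetadata:
    table = pd.read_csv(path, sep="\t", index_col="individual")
    return StudyMetadata(table=table)


def write_study(study, directory: os.PathLike) -> Dict[str, Path]:
    """Emit a synthetic study as VCF + TSV files; returns path map."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": directory / "genotypes.vcf",
        "expression": directory / "expression.tsv",
        "metadata": directory / "metadata.tsv",
        "gene_table": directory / "genes.tsv",
    }
    write_vcf(
        paths["vcf"],
        study.allele_counts.snps,
        study.allele_counts.individuals,
        dosage=study.truth_genotypes.dosage,
        ref_count=study.allele_counts.ref_count,
        alt_count=study.allele_counts.alt_count,
    )
    write_expression_tsv(paths["expression"], study.expression)
    write_metadata_tsv(paths["metadata"], study.metadata)
    study.gene_table.to_csv(paths["gene_table"], sep="\t", index_label="gene")
    for name, df in study.truth.items():
        p = directory / f"truth_{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[f"truth_{name}"] = p
    return paths


def read_study(directory: os.PathLike):
    """Read back the files written by :func:`write_study`.

    Returns a dict with keys ``allele_counts``, ``genotypes``,
    ``expression``, ``metadata``, ``gene_table`` and ``truth``.
    """
    directory = Path(directory)
    metadata = read_metadata_tsv(directory / "metadata.tsv")
    counts, genotypes = read_vcf(directory / "genotypes.vcf", metadata.populations)
    expr = read_expression_tsv(directory / "expression.tsv")
    gene_table = pd.read_csv(directory / "genes.tsv", sep="\t", index_col="gene")
    truth = {}
    for p in sorted(directory.glob("truth_*.tsv")):
        truth[p.stem.removeprefix("truth_")] = pd.read_csv(p, sep="\t")
    return {
        "allele_counts": counts,
        "genotypes": genotypes,
        "expression": expr,
        "metadata": metadata,
        "gene_table": gene_table,
        "truth": truth,
    }
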