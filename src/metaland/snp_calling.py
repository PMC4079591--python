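"""SNP panel derivation and genotype scoring from allele read counts.

The filters reproduce the study design for RNA-seq-derived SNPs: keep
biallelic sites covered in at least ``min_individuals_per_pop`` individuals
of every population, with a pooled minor-allele count of at least 5% of the
individuals (ceiling).  Genotype calls use read-count rules: heterozygous
when both alleles have >= 3 reads, homozygous when a single allele has
>= 10 reads, otherwise the call is missing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .datatypes import AlleleCountMatrix, GenotypeMatrix


@dataclass
class SnpPanel:
    """Retained SNPs with per-population allele counts and filter provenance.

    ``allele_counts`` holds genotype-backed counts: per SNP and population,
    the number of ref and alt alleles among scored genotypes (2 per called
    individual).  ``filters`` records, for every input SNP, which filters it
    passed; dropped SNPs carry the name of the first filter that removed
    them in ``dropped_by``.
    """

    snp_ids: pd.Index
    populations: List[str]
    ref_alleles: pd.DataFrame  # retained SNP x population
    alt_alleles: pd.DataFrame
    filters: pd.DataFrame  # all input SNPs: biallelic, coverage, mac (bool), dropped_by

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def allele_freq(self) -> pd.DataFrame:
        """Alternate-allele frequency per retained SNP and population."""
        tot = self.ref_alleles + self.alt_alleles
        return self.alt_alleles / tot.where(tot > 0)

    def to_frame(self) -> pd.DataFrame:
        out = self.filters.copy()
        out["retained"] = out.index.isin(self.snp_ids)
        return out


def mac_threshold(n_individuals: int, fraction: float = 0.05) -> int:
    """Minor-allele-count threshold: ceiling(fraction * n_individuals).

    With 174 individuals and fraction 0.05 this gives 9.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    return math.ceil(fraction * n_individuals)


def _population_groups(populations: pd.Series) -> Dict[str, np.ndarray]:
    return {p: np.flatnonzero((populations == p).to_numpy()) for p in pd.unique(populations)}


def population_allele_counts(
    genotypes: GenotypeMatrix, snp_ids: Optional[pd.Index] = None
) -> Dict[str, pd.DataFrame]:
    """Ref/alt allele counts per population from genotype dosages."""
    ids = genotypes.snp_ids if snp_ids is None else snp_ids
    rows = genotypes.snp_ids.get_indexer(ids)
    dos = genotypes.dosage[rows]
    groups = _population_groups(genotypes.populations)
    ref = {}
    alt = {}
    for pop, idx in groups.items():
        d = dos[:, idx]
        called = ~np.isnan(d)
        alt[pop] = np.nansum(d, axis=1)
        ref[pop] = 2 * called.sum(axis=1) - alt[pop]
    cols = list(groups)
    return {
        "ref": pd.DataFrame(ref, index=ids)[cols],
        "alt": pd.DataFrame(alt, index=ids)[cols],
    }


def call_snps(
    counts: AlleleCountMatrix,
    min_individuals_per_pop: int = 10,
    mac_fraction: float = 0.05,
    min_base_depth: int = 1,
    genotypes: Optional[GenotypeMatrix] = None,
) -> SnpPanel:
    """Apply the biallelic / per-population coverage / MAC filters.

    The three filters are independent predicates of the input matrix, so
    the panel does not depend on the order they are listed in.  The MAC is
    counted over per-individual genotypes (2 alleles per scored
    individual); ``genotypes`` defaults to :func:`score_genotypes` output.
    """
    pops = pd.unique(counts.populations)
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    if counts.n_snps == 0:
        warnings.warn("empty allele count matrix: returning empty panel")
        empty = pd.DataFrame(columns=pops.tolist())
        filters = pd.DataFrame(
            columns=["biallelic", "coverage", "mac", "dropped_by"], index=counts.snp_ids
        )
        return SnpPanel(counts.snp_ids[:0], list(pops), empty, empty, filters)

    if genotypes is None:
        genotypes = score_genotypes(counts)

    # (a) biallelic: both alleles observed in the pooled read data
    pooled_ref = counts.ref_count.sum(axis=1)
    pooled_alt = counts.alt_count.sum(axis=1)
    biallelic = (pooled_ref > 0) & (pooled_alt > 0)

    # (b) per-population coverage: >= k individuals with depth >= min_base_depth
    depth = counts.depth()
    coverage = np.ones(counts.n_snps, dtype=bool)
    for pop, idx in _population_groups(counts.populations).items():
        coverage &= (depth[:, idx] >= min_base_depth).sum(axis=1) >= min_individuals_per_pop

    # (c) pooled minor allele count from scored genotypes
    thr = mac_threshold(counts.n_individuals, mac_fraction)
    called = genotypes.called()
    alt_alleles = np.nansum(genotypes.dosage, axis=1)
    total_alleles = 2 * called.sum(axis=1)
    mac = np.minimum(alt_alleles, total_alleles - alt_alleles) >= thr

    keep = biallelic & coverage & mac
    dropped_by = np.where(
        ~biallelic, "biallelic", np.where(~coverage, "coverage", np.where(~mac, "mac", ""))
    )
    filters = pd.DataFrame(
        {"biallelic": biallelic, "coverage": coverage, "mac": mac, "dropped_by": dropped_by},
        index=counts.snp_ids,
    )

    kept_ids = counts.snp_ids[keep]
    ac = population_allele_counts(genotypes, kept_ids)
    return SnpPanel(
        snp_ids=kept_ids,
        populations=list(_population_groups(counts.populations)),
        ref_alleles=ac["ref"],
        alt_alleles=ac["alt"],
        filters=filters,
    )


def score_genotypes(
    counts: AlleleCountMatrix, het_min_each: int = 3, hom_min: int = 10
) -> GenotypeMatrix:
    """Read-count genotype scoring.

    Heterozygous when ref and alt each have >= ``het_min_each`` reads;
    homozygous when only one allele is detected with >= ``hom_min`` reads;
    anything else is a missing call.
    """
    ref, alt = counts.ref_count, counts.alt_count
    dosage = np.full(ref.shape, np.nan)
    dosage[(ref >= het_min_each) & (alt >= het_min_each)] = 1.0
    dosage[(alt == 0) & (ref >= hom_min)] = 0.0
    dosage[(ref == 0) & (alt >= hom_min)] = 2.0
    return GenotypeMatrix(snp_ids=counts.snp_ids, populations=counts.populations, dosage=dosage)


def _read_backed_freqs(counts: AlleleCountMatrix, min_depth: int) -> pd.DataFrame:
    """Population alt-allele frequency from pooled reads of individuals
    passing the per-individual depth threshold."""
    depth = counts.depth()
    ok = depth >= min_depth
    freqs = {}
    for pop, idx in _population_groups(counts.populations).items():
        alt = (counts.alt_count[:, idx] * ok[:, idx]).sum(axis=1)
        tot = (depth[:, idx] * ok[:, idx]).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs[pop] = np.where(tot > 0, alt / tot, np.nan)
    return pd.DataFrame(freqs, index=counts.snp_ids)


def threshold_robustness_scan(
    counts: AlleleCountMatrix,
    thresholds: Sequence[int],
    landscape_of_population: Optional[Dict[str, str]] = None,
) -> Dict[str, object]:
    """Allele-frequency robustness to the minimum coverage threshold.

    For each threshold, population allele frequencies are recomputed using
    only individuals with depth >= threshold, and the per-SNP frequency
    difference between landscape groups (or between the first two
    populations if no landscape map is given) is compared across threshold
    settings by Spearman rank correlation.
    """
    if not thresholds:
        raise ValueError("thresholds must be non-empty")
    if any(t < 1 for t in thresholds):
        raise ValueError("thresholds must be >= 1")

    diffs = {}
    freq_tables = {}
    for t in thresholds:
        freqs = _read_backed_freqs(counts, t)
        freq_tables[t] = freqs
        if landscape_of_population:
            frag = [p for p in freqs.columns if landscape_of_population.get(p) == "fragmented"]
            cont = [p for p in freqs.columns if landscape_of_population.get(p) == "continuous"]
            d = freqs[frag].mean(axis=1) - freqs[cont].mean(axis=1)
        else:
            d = freqs.iloc[:, 0] - freqs.iloc[:, 1]
        diffs[t] = d
        if d.isna().all():
            warnings.warn(f"threshold {t} exceeds every depth: frequencies undefined")

    uniq = list(dict.fromkeys(thresholds))
    corr = pd.DataFrame(np.nan, index=uniq, columns=uniq, dtype=float)
    for a in uniq:
        for b in uniq:
            pair = pd.concat([diffs[a], diffs[b]], axis=1).dropna()
            if a == b:
                corr.loc[a, b] = 1.0
            elif len(pair) >= 2:
                corr.loc[a, b] = spearmanr(pair.iloc[:, 0], pair.iloc[:, 1]).statistic
    return {"frequencies": freq_tables, "differences": pd.DataFrame(diffs), "correlations": corr}
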