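"""Allele-frequency differentiation and within-population diversity.

Differentiation between groups of populations is tested two ways, as in the
study design: per-SNP Fisher exact tests on genotype-backed allele counts,
and a permutation test of the absolute allele-frequency difference between
landscape groups obtained by permuting individual landscape labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, rankdata
from statsmodels.stats.multitest import multipletests

from .datatypes import GenotypeMatrix
from .snp_calling import SnpPanel
from .util import stage_rng


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values; NaN p-values propagate."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def bonferroni(pvalues: Sequence[float]) -> np.ndarray:
    p = np.asarray(pvalues, dtype=float)
    out = np.minimum(p * np.sum(~np.isnan(p)), 1.0)
    return out


def fisher_pairwise(
    panel: SnpPanel, group_a: Sequence[str], group_b: Sequence[str]
) -> pd.Series:
    """Two-sided Fisher exact p per SNP on pooled (ref, alt) allele counts.

    ``group_a`` and ``group_b`` are disjoint non-empty population lists;
    their allele counts are summed within group.  SNPs with zero total
    alleles in a group get NaN.
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    ra = panel.ref_alleles[group_a].sum(axis=1).to_numpy()
    aa = panel.alt_alleles[group_a].sum(axis=1).to_numpy()
    rb = panel.ref_alleles[group_b].sum(axis=1).to_numpy()
    ab = panel.alt_alleles[group_b].sum(axis=1).to_numpy()
    p = np.full(len(panel.snp_ids), np.nan)
    for i in range(len(p)):
        if ra[i] + aa[i] == 0 or rb[i] + ab[i] == 0:
            continue
        p[i] = fisher_exact([[ra[i], aa[i]], [rb[i], ab[i]]], alternative="two-sided")[1]
    return pd.Series(p, index=panel.snp_ids, name="fisher_p")


def landscape_permutation_test(
    genotypes: GenotypeMatrix,
    landscape_of_individual: pd.Series,
    n_perm: int = 10_000,
    seed: int = 0,
    snp_ids: Optional[pd.Index] = None,
) -> pd.DataFrame:
    """Permutation test of |allele-frequency difference| between landscapes.

    The statistic is the absolute difference of alternate-allele frequency
    (from genotype dosages) between fragmented and continuous individuals.
    The null distribution permutes individual landscape labels freely; with
    four populations a block permutation would admit only three relabelings,
    so individual-level permutation is used.

    Returns a frame indexed by SNP with columns ``stat``, ``p``, ``q``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    labels = landscape_of_individual.reindex(genotypes.individuals)
    groups = set(labels.dropna().unique())
    if groups != {"fragmented", "continuous"}:
        raise ValueError("labels must define fragmented and continuous groups")

    rows = (
        slice(None) if snp_ids is None else genotypes.snp_ids.get_indexer(snp_ids)
    )
    dos = genotypes.dosage[rows]
    ids = genotypes.snp_ids if snp_ids is None else snp_ids
    frag = (labels == "fragmented").to_numpy()
    called = ~np.isnan(dos)
    d0 = np.where(called, dos, 0.0)

    def freq_diff(assign_frag: np.ndarray) -> np.ndarray:
        # assign_frag: (n_individuals, k) 0/1 columns of fragmented membership
        num_f = d0 @ assign_frag
        den_f = 2.0 * (called @ assign_frag)
        num_c = d0 @ (1 - assign_frag)
        den_c = 2.0 * (called @ (1 - assign_frag))
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.abs(num_f / den_f - num_c / den_c)

    obs = freq_diff(frag[:, None].astype(float))[:, 0]

    rng = stage_rng(seed, "permutation_af")
    n = len(labels)
    exceed = np.zeros(len(ids))
    chunk = max(1, min(n_perm, int(2e8 // max(1, dos.size))))
    done = 0
    while done < n_perm:
        k = min(chunk, n_perm - done)
        perms = np.empty((n, k))
        for j in range(k):
            perms[:, j] = frag[rng.permutation(n)]
        sim = freq_diff(perms)
        sim = np.nan_to_num(sim, nan=0.0)
        exceed += (sim >= np.nan_to_num(obs, nan=np.inf)[:, None] - 1e-12).sum(axis=1)
        done += k
    p = (1.0 + exceed) / (1.0 + n_perm)
    p[np.isnan(obs)] = np.nan
    # constant SNPs: zero observed difference -> every permutation matches
    return pd.DataFrame({"stat": obs, "p": p, "q": bh_fdr(p)}, index=ids)


def pair_partitions(populations: Sequence[str]) -> List[Tuple[Tuple[str, str], Tuple[str, str]]]:
    """The three ways to split four populations into two pairs."""
    pops = list(populations)
    if len(pops) != 4:
        raise ValueError("pair partitioning is defined for exactly 4 populations")
    first = pops[0]
    out = []
    for partner in pops[1:]:
        rest = tuple(p for p in pops[1:] if p != partner)
        out.append(((first, partner), rest))
    return out


def pairing_name(pairing: Tuple[Tuple[str, str], Tuple[str, str]]) -> str:
    (a1, a2), (b1, b2) = pairing
    return f"{a1}+{a2}|{b1}+{b2}"


@dataclass
class VennCounts:
    """Disjoint Venn regions of significant SNPs across the 3 pairings."""

    pairings: List[str]
    regions: Dict[Tuple[str, ...], int]

    def union_size(self) -> int:
        return sum(self.regions.values())

    def set_size(self, pairing: str) -> int:
        return sum(v for k, v in self.regions.items() if pairing in k)


def venn_partition(results: Dict[str, pd.Series], alpha_fdr: float = 0.05) -> VennCounts:
    """Venn-region counts of FDR-significant SNPs per pair-vs-pair test.

    ``results`` maps pairing name to the per-SNP q-value series of its
    Fisher comparison; all three series must share one SNP index.
    """
    names = list(results)
    idx = results[names[0]].index
    for name in names[1:]:
        if not results[name].index.equals(idx):
            raise ValueError("mismatched SNP sets across pairings")
    flags = {name: (results[name] < alpha_fdr).to_numpy() for name in names}
    regions: Dict[Tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = np.ones(len(idx), dtype=bool)
            for name in names:
                inside &= flags[name] if name in combo else ~flags[name]
            regions[combo] = int(inside.sum())
    return VennCounts(pairings=names, regions=regions)


def diversity_ranking(
    genotypes: GenotypeMatrix, subsample: int = 10, reps: int = 100, seed: int = 0
) -> pd.DataFrame:
    """Resampled ranking of populations by number of polymorphic SNPs.

    Per repetition, ``subsample`` individuals are drawn without replacement
    from each population and the SNPs with both alleles observed among the
    called genotypes are counted; populations are ranked (1 = most diverse,
    ties share the smallest rank).  Returns populations x ranks counts.
    """
    pops = list(pd.unique(genotypes.populations))
    groups = {p: np.flatnonzero((genotypes.populations == p).to_numpy()) for p in pops}
    for p, idx in groups.items():
        if len(idx) < subsample:
            raise ValueError(f"population {p} has fewer than {subsample} individuals")
    rng = stage_rng(seed, "diversity")
    tally = pd.DataFrame(0, index=pops, columns=range(1, len(pops) + 1))
    for _ in range(reps):
        counts = {}
        for p, idx in groups.items():
            chosen = idx[rng.choice(len(idx), size=subsample, replace=False)]
            d = genotypes.dosage[:, chosen]
            with np.errstate(invalid="ignore"):
                has_alt = np.nansum(d, axis=1) > 0
                has_ref = np.nansum(2.0 - d, axis=1) > 0
            counts[p] = int((has_alt & has_ref & (~np.isnan(d)).any(axis=1)).sum())
        vals = np.array([counts[p] for p in pops], dtype=float)
        ranks = rankdata(-vals, method="min").astype(int)
        for p, r in zip(pops, ranks):
            tally.loc[p, r] += 1
    tally.index.name = "population"
    tally.columns.name = "rank"
    return tally


def genotype_dissimilarity(genotypes: GenotypeMatrix, individual_i: str, individual_j: str) -> float:
    """Fraction of jointly-called SNPs with different genotype calls."""
    i = genotypes.individuals.get_loc(individual_i)
    j = genotypes.individuals.get_loc(individual_j)
    di, dj = genotypes.dosage[:, i], genotypes.dosage[:, j]
    shared = ~np.isnan(di) & ~np.isnan(dj)
    n = int(shared.sum())
    if n == 0:
        raise ValueError(f"individuals {individual_i} and {individual_j} share no called SNPs")
    return float((di[shared] != dj[shared]).sum() / n)


def dissimilarity_matrix(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """All-pairs non-shared-genotype dissimilarity (NaN when no shared SNPs)."""
    n = genotypes.n_individuals
    out = np.zeros((n, n))
    called = genotypes.called()
    dos = genotypes.dosage
    for i in range(n):
        for j in range(i + 1, n):
            shared = called[:, i] & called[:, j]
            m = shared.sum()
            if m == 0:
                out[i, j] = out[j, i] = np.nan
            else:
                v = (dos[shared, i] != dos[shared, j]).sum() / m
                out[i, j] = out[j, i] = v
    return pd.DataFrame(out, index=genotypes.individuals, columns=genotypes.individuals)
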