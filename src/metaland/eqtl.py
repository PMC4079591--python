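"""Kinship-aware cis-eQTL screening.

Each SNP is tested against the expression of its nearest gene with
generalized least squares whose error covariance is a shared-allele
relatedness matrix.  Fits run separately per population under additive,
dominance and recessive genotype codings; a pair is accepted when the SNP
is landscape-differentiated, FDR < 0.05 in at least one population, and the
coefficient sign agrees across every population with a defined fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import t as t_dist

from .datatypes import ExpressionMatrix, GenotypeMatrix
from .popgen import bh_fdr

CODINGS = ("additive", "dominance", "recessive")


def relatedness_matrix(genotypes: GenotypeMatrix, ridge: float = 1e-6) -> pd.DataFrame:
    """Shared-allele similarity between individuals.

    Entry (i, j) is the mean over jointly-called SNPs of the per-SNP shared
    allele fraction ``1 - |dosage_i - dosage_j| / 2``; the diagonal is 1 and
    a small ridge keeps the matrix positive definite.  Pairs with no
    jointly-called SNPs are imputed with the mean similarity of their
    population pair (with a warning).
    """
    if genotypes.n_individuals < 2:
        raise ValueError("need at least two individuals")
    dos = genotypes.dosage
    called = genotypes.called().astype(float)
    filled = np.where(np.isnan(dos), 0.0, dos)
    # sum over SNPs of |d_i - d_j| restricted to jointly called entries,
    # via the expansion of |a-b| into dot products is not available: loop
    # columns (individuals are few).
    n = genotypes.n_individuals
    sim = np.eye(n)
    counts = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = (called[:, i] * called[:, j]) > 0
            m = int(both.sum())
            counts[i, j] = counts[j, i] = m
            if m:
                v = 1.0 - np.abs(filled[both, i] - filled[both, j]) / 2.0
                sim[i, j] = sim[j, i] = v.mean()
            else:
                sim[i, j] = sim[j, i] = np.nan
    if np.isnan(sim).any():
        warnings.warn("pairs with no shared SNPs: imputing population-pair mean similarity")
        pops = genotypes.populations.to_numpy()
        for i, j in zip(*np.where(np.isnan(sim))):
            mask = np.zeros_like(sim, dtype=bool)
            mask[np.ix_(pops == pops[i], pops == pops[j])] = True
            np.fill_diagonal(mask, False)
            vals = sim[mask]
            sim[i, j] = np.nanmean(vals) if np.isfinite(vals).any() else 0.5
    out = sim + ridge * np.eye(n)
    np.fill_diagonal(out, 1.0 + ridge)
    return pd.DataFrame(out, index=genotypes.individuals, columns=genotypes.individuals)


def genotype_coding(dosage: np.ndarray, model: str) -> np.ndarray:
    """Numeric predictor under an inheritance model.

    additive: 0/1/2; dominance: 0/1/1; recessive: 0/0/1 (of the alternate
    allele).  Missing dosages stay missing.
    """
    if model not in CODINGS:
        raise ValueError(f"model must be one of {CODINGS}")
    d = np.asarray(dosage, dtype=float)
    if model == "additive":
        return d
    if model == "dominance":
        return np.where(np.isnan(d), np.nan, (d > 0).astype(float))
    return np.where(np.isnan(d), np.nan, (d == 2).astype(float))


def gls_fit(
    y: np.ndarray,
    x: np.ndarray,
    V: np.ndarray,
    covariates: Optional[np.ndarray] = None,
) -> Dict[str, float]:
    """Generalized least squares of y on [1, x] with error covariance ∝ V.

    Returns the slope, its standard error and the two-sided t-test p-value.
    With V = identity this reduces exactly to ordinary least squares.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = y.size
    cols = [np.ones(n), x]
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] == n:
            covariates = covariates.T
        cols.extend(list(covariates))
    X = np.column_stack(cols)
    p = X.shape[1]
    if n <= p:
        raise ValueError("not enough observations for the design")
    c, low = cho_factor(np.asarray(V, dtype=float))
    vi_x = cho_solve((c, low), X)
    vi_y = cho_solve((c, low), y)
    xtvx = X.T @ vi_x
    beta = np.linalg.solve(xtvx, X.T @ vi_y)
    resid = y - X @ beta
    sigma2 = float(resid @ cho_solve((c, low), resid)) / (n - p)
    if sigma2 <= 0:
        return {"beta": 0.0, "se": np.nan, "p": 1.0, "df": n - p}
    cov = sigma2 * np.linalg.inv(xtvx)
    se = float(np.sqrt(cov[1, 1]))
    if se == 0 or not np.isfinite(se):
        return {"beta": float(beta[1]), "se": se, "p": 1.0, "df": n - p}
    tval = beta[1] / se
    pval = float(2.0 * t_dist.sf(abs(tval), df=n - p))
    return {"beta": float(beta[1]), "se": se, "p": pval, "df": n - p}


def nearest_gene_map(snp_table: pd.DataFrame, gene_table: pd.DataFrame) -> pd.DataFrame:
    """Assign each SNP to the nearest gene on its scaffold.

    Distance is |SNP position - gene midpoint|; ties go to the lower
    coordinate.  SNPs on scaffolds without genes are dropped.
    """
    rows = []
    mid = (gene_table["start"] + gene_table["end"]) / 2.0
    by_scaffold = {
        scaf: grp.assign(mid=mid.loc[grp.index]).sort_values(["mid", "start"])
        for scaf, grp in gene_table.groupby("scaffold")
    }
    for snp_id, rec in snp_table.iterrows():
        genes = by_scaffold.get(rec["scaffold"])
        if genes is None:
            continue
        dist = np.abs(genes["mid"].to_numpy() - rec["pos"])
        best = np.flatnonzero(dist == dist.min())
        # ties: lower gene coordinate (table is mid-sorted, so first hit)
        gi = best[0]
        rows.append((snp_id, genes.index[gi], float(dist[gi])))
    return pd.DataFrame(rows, columns=["snp", "gene", "distance"]).set_index("snp")


@dataclass
class EqtlRecord:
    snp: str
    gene: str
    coding: str
    betas: Dict[str, float]
    pvalues: Dict[str, float]
    fdrs: Dict[str, float]
    landscape_differentiated: bool
    sign_consistent: bool
    accepted: bool


def screen_eqtl(
    expr: ExpressionMatrix,
    genotypes: GenotypeMatrix,
    snp_gene_map: pd.DataFrame,
    kinship: Optional[pd.DataFrame] = None,
    landscape_snps: Optional[Iterable[str]] = None,
    alpha: float = 0.05,
    codings: Sequence[str] = CODINGS,
    sex: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Screen SNP-gene pairs for cis-eQTL under the study's filters.

    Per pair and coding, GLS fits run within each population whose
    individuals carry all three genotype classes of the SNP (pairs with no
    such population are skipped).  FDR is computed per population across
    all tested pairs of a coding.  ``landscape_snps`` marks SNPs with a
    significant fragmented-vs-continuous allele-frequency difference; when
    given, acceptance additionally requires membership.

    Returns one row per (snp, gene, coding) with per-population betas,
    p-values, FDRs, and the ``accepted`` verdict.
    """
    log_expr = expr.log_cpm()
    pops = list(pd.unique(genotypes.populations))
    pop_idx = {p: np.flatnonzero((genotypes.populations == p).to_numpy()) for p in pops}
    if kinship is None:
        kinship = relatedness_matrix(genotypes)
    K = kinship.reindex(index=genotypes.individuals, columns=genotypes.individuals).to_numpy()
    land_set = set(landscape_snps) if landscape_snps is not None else None

    records = []
    for snp_id, row in snp_gene_map.iterrows():
        gene = row["gene"]
        if snp_id not in genotypes.snp_ids or gene not in log_expr.index:
            continue
        si = genotypes.snp_ids.get_loc(snp_id)
        dos = genotypes.dosage[si]
        yg = log_expr.loc[gene].to_numpy()
        for coding in codings:
            betas, pvals = {}, {}
            for p in pops:
                idx = pop_idx[p]
                d = dos[idx]
                ok = ~np.isnan(d)
                # all three genotype classes must be present in this population
                if len(set(d[ok])) < 3:
                    continue
                x = genotype_coding(d[ok], coding)
                if len(set(x)) < 2:
                    continue
                sel = idx[ok]
                cov = None
                if sex is not None:
                    cov = (sex.reindex(genotypes.individuals).to_numpy()[sel] == "M").astype(float)
                try:
                    fit = gls_fit(yg[sel], x, K[np.ix_(sel, sel)], covariates=cov)
                except (np.linalg.LinAlgError, ValueError):
                    continue
                betas[p] = fit["beta"]
                pvals[p] = fit["p"]
            if not betas:
                continue
            records.append(
                {
                    "snp": snp_id,
                    "gene": gene,
                    "coding": coding,
                    **{f"beta_{p}": betas.get(p, np.nan) for p in pops},
                    **{f"p_{p}": pvals.get(p, np.nan) for p in pops},
                }
            )
    if not records:
        return pd.DataFrame(
            columns=["snp", "gene", "coding", "landscape_differentiated", "sign_consistent", "accepted"]
        )
    out = pd.DataFrame.from_records(records)

    # FDR within population, per coding, across tested pairs
    for coding in codings:
        mask = out["coding"] == coding
        for p in pops:
            out.loc[mask, f"q_{p}"] = bh_fdr(out.loc[mask, f"p_{p}"])

    signs = out[[f"beta_{p}" for p in pops]].to_numpy()
    with np.errstate(invalid="ignore"):
        pos = np.nansum(signs > 0, axis=1)
        neg = np.nansum(signs < 0, axis=1)
        defined = np.sum(~np.isnan(signs), axis=1)
    out["sign_consistent"] = (defined > 0) & ((pos == defined) | (neg == defined))
    qcols = out[[f"q_{p}" for p in pops]]
    out["any_significant"] = (qcols < alpha).any(axis=1)
    if land_set is None:
        out["landscape_differentiated"] = True
    else:
        out["landscape_differentiated"] = out["snp"].isin(land_set)
    out["accepted"] = (
        out["landscape_differentiated"] & out["any_significant"] & out["sign_consistent"]
    )
    return out
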