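"""Category enrichment tests and cross-dataset concordance analyses.

Generic machinery for questions like "are 4 significant genes out of a
7-gene family more than expected when 11% of all genes are significant?"
(binomial upper tail), pathway over-representation (one-sided Fisher), and
whether two independent log2 expression contrasts agree on a filtered gene
set (Pearson correlation, direction tables).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix


@dataclass
class CategoryTestResult:
    category: str
    k_significant: int
    n_category: int
    background_rate: float
    p_upper_tail: float


@dataclass
class ConcordanceResult:
    genes: pd.Index
    delta_a: pd.Series
    delta_b: pd.Series
    correlation: float
    p: float
    method: str = "pearson"


def binomial_category_test(k: int, n: int, rate: float) -> float:
    """P(X >= k) for X ~ Binomial(n, rate), by exact summation of the pmf."""
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    if k == 0:
        return 1.0
    ks = np.arange(k, n + 1)
    return float(min(stats.binom.pmf(ks, n, rate).sum(), 1.0))


def fraction_test(
    members_significant: int,
    members_total: int,
    universe_significant: int,
    universe_total: int,
) -> float:
    """One-sided Fisher exact p for over-representation of significant genes
    in a category against the universe."""
    if members_significant > members_total:
        raise ValueError("significant members exceed category size")
    if members_total > universe_total or universe_significant > universe_total:
        raise ValueError("category exceeds universe")
    if members_significant > universe_significant:
        raise ValueError("category significants exceed universe significants")
    if members_total == 0:
        return 1.0
    table = [
        [members_significant, members_total - members_significant],
        [
            universe_significant - members_significant,
            (universe_total - members_total) - (universe_significant - members_significant),
        ],
    ]
    return float(stats.fisher_exact(table, alternative="greater")[1])


def filter_concordance_genes(
    de_set: Iterable[str],
    log_cpm: Dict[str, pd.Series] | pd.DataFrame,
    log2_ratio: pd.Series,
    cpm_floor: float = 1.0,
    ratio_floor: float = 1.0,
) -> Dict[str, object]:
    """Coverage and effect-size filters before a concordance analysis.

    Keeps genes of ``de_set`` with log-CPM strictly above ``cpm_floor`` in
    every provided data set and |log2 ratio| strictly above
    ``ratio_floor``.  Returns the surviving genes and per-step counts.
    """
    genes = pd.Index(list(de_set))
    steps = {"input": len(genes)}
    if isinstance(log_cpm, pd.DataFrame):
        tables = {c: log_cpm[c] for c in log_cpm.columns}
    else:
        tables = dict(log_cpm)
    keep = genes
    for name, series in tables.items():
        keep = keep[series.reindex(keep).to_numpy() > cpm_floor]
    steps["after_cpm"] = len(keep)
    keep = keep[np.abs(log2_ratio.reindex(keep).to_numpy()) > ratio_floor]
    steps["after_ratio"] = len(keep)
    return {"genes": keep, "steps": steps}


def landscape_log2_delta(
    expr: ExpressionMatrix,
    landscape_of_individual: pd.Series,
    exclude_population: Optional[str] = None,
    population_of_individual: Optional[pd.Series] = None,
) -> pd.Series:
    """Per-gene log2 mean-CPM difference, fragmented minus continuous.

    ``exclude_population`` recomputes the contrast without that
    population's individuals (leave-one-population-out check).
    """
    land = landscape_of_individual.reindex(expr.individuals)
    keep = pd.Series(True, index=expr.individuals)
    if exclude_population is not None:
        if population_of_individual is None:
            raise ValueError("population labels needed to exclude a population")
        keep &= population_of_individual.reindex(expr.individuals) != exclude_population
    log_cpm = expr.log_cpm()
    frag = log_cpm.loc[:, (land == "fragmented") & keep].mean(axis=1)
    cont = log_cpm.loc[:, (land == "continuous") & keep].mean(axis=1)
    return frag - cont


def concordance_test(
    delta_a: pd.Series,
    delta_b: pd.Series,
    method: str = "pearson",
) -> ConcordanceResult:
    """Correlation of two per-gene log2 contrasts on their shared genes."""
    shared = delta_a.index.intersection(delta_b.index)
    a = delta_a.reindex(shared)
    b = delta_b.reindex(shared)
    ok = a.notna() & b.notna()
    a, b = a[ok], b[ok]
    if len(a) < 3:
        raise ValueError("need at least 3 genes for a correlation")
    if np.isclose(a.std(), 0) or np.isclose(b.std(), 0):
        return ConcordanceResult(a.index, a, b, np.nan, np.nan, method)
    if method == "pearson":
        r, p = stats.pearsonr(a, b)
    elif method == "spearman":
        r, p = stats.spearmanr(a, b)
    else:
        raise ValueError("method must be pearson or spearman")
    return ConcordanceResult(a.index, a, b, float(r), float(p), method)


def flight_baseline_concordance(
    flight_response: pd.Series,
    landscape_delta: pd.Series,
    sex_of_individual: Optional[pd.Series] = None,
    per_sex_deltas: Optional[Dict[str, pd.Series]] = None,
) -> Dict[str, object]:
    """Flight-induced expression change vs baseline landscape difference.

    Returns the correlation (value withheld from significance claims by
    the caller if desired), a 2x2 direction-agreement table
    (up/down-regulated after flight x higher/lower in fragmented) with a
    Fisher exact p, and, when per-sex contrasts are supplied, the same
    result per sex.
    """
    shared = flight_response.index.intersection(landscape_delta.index)
    if len(shared) == 0:
        raise ValueError("no shared genes between the flight and landscape sets")
    fr = flight_response.reindex(shared)
    ld = landscape_delta.reindex(shared)
    if np.isclose(ld.std(ddof=0), 0) or np.isclose(fr.std(ddof=0), 0):
        result = {"correlation": np.nan, "p": np.nan, "flagged": "zero-variance contrast"}
    else:
        r, p = stats.pearsonr(fr, ld)
        result = {"correlation": float(r), "p": float(p)}
    up = fr > 0
    higher = ld > 0
    table = pd.DataFrame(
        {
            "higher_in_fragmented": [int((up & higher).sum()), int((~up & higher).sum())],
            "lower_in_fragmented": [int((up & ~higher).sum()), int((~up & ~higher).sum())],
        },
        index=["up_after_flight", "down_after_flight"],
    )
    fisher_p = float(stats.fisher_exact(table.to_numpy())[1])
    out = {"n_genes": len(shared), "direction_table": table, "direction_fisher_p": fisher_p, **result}
    if per_sex_deltas:
        out["per_sex"] = {
            sx: flight_baseline_concordance(flight_response, d) for sx, d in per_sex_deltas.items()
        }
    return out
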