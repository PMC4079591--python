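"""Marginal-likelihood scoring of population set partitions.

Each candidate grouping of the populations is scored by the summed
gene-wise log marginal likelihood of standardized expression under a
conjugate Normal–Gamma model: data are Gaussian N(m, 1/p), the precision p
has an Exp(1) = Gamma(1, 1) prior and the mean m | p is N(0, 1/p).  Within
a partition, each cluster's individuals form one Gaussian sample per gene;
the closed-form marginal integrates m and p out exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .datatypes import ExpressionMatrix
from .expression import normalize


@dataclass(frozen=True)
class NormalGammaPrior:
    """Conjugate prior on a Gaussian's (mean, precision).

    Defaults encode mean ~ N(0, 1/p) and precision p ~ Exp(1), i.e.
    Gamma(shape 1, rate 1).
    """

    mu0: float = 0.0
    kappa0: float = 1.0
    alpha0: float = 1.0
    beta0: float = 1.0

    def __post_init__(self) -> None:
        if min(self.kappa0, self.alpha0, self.beta0) <= 0:
            raise ValueError("kappa0, alpha0, beta0 must be positive")


def enumerate_partitions(labels: Sequence[str]) -> List[Tuple[Tuple[str, ...], ...]]:
    """All set partitions of ``labels`` (Bell-number many).

    Canonical order: by number of blocks, then lexicographically; blocks
    are sorted internally and between each other.
    """
    labels = list(labels)
    if not 1 <= len(labels) <= 12:
        raise ValueError("partition enumeration supports 1..12 labels")

    def _parts(items: List[str]):
        if not items:
            yield []
            return
        head, rest = items[0], items[1:]
        for part in _parts(rest):
            for i in range(len(part)):
                yield part[:i] + [[head] + part[i]] + part[i + 1 :]
            yield [[head]] + part

    canon = []
    for part in _parts(labels):
        blocks = tuple(sorted(tuple(sorted(b)) for b in part))
        canon.append(blocks)
    canon = sorted(set(canon), key=lambda p: (len(p), p))
    return canon


def standardize_expression(
    expr: ExpressionMatrix, ddof: int = 1
) -> pd.DataFrame:
    """TMM -> log2-CPM -> per-gene z-scores over all individuals.

    Genes with zero variance are dropped (a constant gene carries no
    clustering signal and would divide by zero).
    """
    if expr.tmm is None:
        normalize(expr)
    log_cpm = expr.log_cpm()
    mu = log_cpm.mean(axis=1)
    sd = log_cpm.std(axis=1, ddof=ddof)
    keep = sd > 0
    z = (log_cpm.loc[keep] - mu[keep].to_numpy()[:, None]) / sd[keep].to_numpy()[:, None]
    return z


def ng_log_marginal(x: np.ndarray, prior: NormalGammaPrior = NormalGammaPrior()) -> float:
    """Closed-form log marginal likelihood of a Gaussian sample under the
    Normal–Gamma prior.

    With n observations, sample mean xbar and sum of squares about the
    mean S: kappa_n = kappa0 + n, alpha_n = alpha0 + n/2,
    beta_n = beta0 + S/2 + kappa0 n (xbar - mu0)^2 / (2 kappa_n), and

    log ML = lnG(alpha_n) - lnG(alpha0) + alpha0 ln beta0
             - alpha_n ln beta_n + (ln kappa0 - ln kappa_n)/2
             - (n/2) ln 2 pi.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if n == 0:
        raise ValueError("need at least one observation")
    xbar = x.mean()
    s = float(((x - xbar) ** 2).sum())
    kn = prior.kappa0 + n
    an = prior.alpha0 + n / 2.0
    bn = prior.beta0 + 0.5 * s + prior.kappa0 * n * (xbar - prior.mu0) ** 2 / (2.0 * kn)
    return float(
        gammaln(an)
        - gammaln(prior.alpha0)
        + prior.alpha0 * np.log(prior.beta0)
        - an * np.log(bn)
        + 0.5 * (np.log(prior.kappa0) - np.log(kn))
        - (n / 2.0) * np.log(2.0 * np.pi)
    )


def _ng_log_marginal_rows(z: np.ndarray, prior: NormalGammaPrior) -> np.ndarray:
    """Vectorized ng_log_marginal across the rows of a matrix."""
    n = z.shape[1]
    xbar = z.mean(axis=1)
    s = ((z - xbar[:, None]) ** 2).sum(axis=1)
    kn = prior.kappa0 + n
    an = prior.alpha0 + n / 2.0
    bn = prior.beta0 + 0.5 * s + prior.kappa0 * n * (xbar - prior.mu0) ** 2 / (2.0 * kn)
    return (
        gammaln(an)
        - gammaln(prior.alpha0)
        + prior.alpha0 * np.log(prior.beta0)
        - an * np.log(bn)
        + 0.5 * (np.log(prior.kappa0) - np.log(kn))
        - (n / 2.0) * np.log(2.0 * np.pi)
    )


@dataclass
class PartitionScore:
    partition: Tuple[Tuple[str, ...], ...]
    total_log_ml: float

    def n_blocks(self) -> int:
        return len(self.partition)

    def to_dict(self) -> Dict:
        return {"partition": [list(b) for b in self.partition], "log_ml": self.total_log_ml}


def score_partitions(
    z: pd.DataFrame,
    population_of_individual: pd.Series,
    prior: NormalGammaPrior = NormalGammaPrior(),
) -> List[PartitionScore]:
    """Rank every set partition of the populations by total log marginal
    likelihood (descending; ties broken toward fewer blocks).

    The total is the sum over genes and clusters of the Normal–Gamma log
    marginal of the z-scores of the cluster's individuals.
    """
    labels = population_of_individual.reindex(z.columns)
    pops = sorted(labels.unique())
    if labels.isna().any():
        raise ValueError("every individual needs a population label")
    zmat = z.to_numpy(dtype=float)
    cols = {p: np.flatnonzero((labels == p).to_numpy()) for p in pops}
    # cache cluster scores: same block appears in several partitions
    cache: Dict[Tuple[str, ...], float] = {}

    def block_score(block: Tuple[str, ...]) -> float:
        if block not in cache:
            idx = np.concatenate([cols[p] for p in block])
            cache[block] = float(_ng_log_marginal_rows(zmat[:, idx], prior).sum())
        return cache[block]

    scores = [
        PartitionScore(part, sum(block_score(b) for b in part))
        for part in enumerate_partitions(pops)
    ]
    scores.sort(key=lambda s: (-s.total_log_ml, s.n_blocks()))
    return scores
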