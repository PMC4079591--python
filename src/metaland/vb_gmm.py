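"""Variational-Bayes univariate Gaussian mixtures for expression
heterogeneity screening.

Per gene, mixtures with K = 1..5 components are fitted to the standardized
log expression of the individuals and the best K is chosen by the highest
variational lower bound (the ELBO, used as the marginal-likelihood
surrogate).  Priors: symmetric Dirichlet(1) on the weights and
Normal–Gamma(0, 1, 1, 1) on each component's (mean, precision) — the same
family as the population-partition model, so that standardized inputs can
share one uninformative prior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln, logsumexp
from scipy.stats import chi2_contingency, fisher_exact
from sklearn.cluster import KMeans

from .popgen import bh_fdr
from .util import child_seed


@dataclass
class VBGMMFit:
    K: int
    weights: np.ndarray  # posterior-expected mixing weights
    means: np.ndarray  # posterior mean of component means
    precisions: np.ndarray  # posterior-expected component precisions
    responsibilities: np.ndarray  # (n, K)
    elbo: float
    elbo_trace: np.ndarray
    converged: bool
    n_iter: int

    @property
    def effective_k(self) -> int:
        """Components supported by at least half an individual of weight."""
        return int((self.responsibilities.sum(axis=0) > 0.5).sum())


# prior hyperparameters (symmetric Dirichlet, Normal-Gamma)
_ALPHA0 = 1.0
_M0, _BETA0, _A0, _B0 = 0.0, 1.0, 1.0, 1.0


def _m_step(x: np.ndarray, r: np.ndarray):
    n_k = r.sum(axis=0) + 1e-12
    xbar = (r * x[:, None]).sum(axis=0) / n_k
    s = (r * (x[:, None] - xbar[None, :]) ** 2).sum(axis=0) / n_k
    alpha = _ALPHA0 + n_k
    beta = _BETA0 + n_k
    m = (_BETA0 * _M0 + n_k * xbar) / beta
    a = _A0 + n_k / 2.0
    b = _B0 + 0.5 * (n_k * s + _BETA0 * n_k * (xbar - _M0) ** 2 / beta)
    return {"n_k": n_k, "xbar": xbar, "s": s, "alpha": alpha, "beta": beta, "m": m, "a": a, "b": b}


def _e_step(x: np.ndarray, q: Dict[str, np.ndarray]):
    e_ln_lam = digamma(q["a"]) - np.log(q["b"])
    e_ln_pi = digamma(q["alpha"]) - digamma(q["alpha"].sum())
    quad = 1.0 / q["beta"][None, :] + (q["a"] / q["b"])[None, :] * (
        x[:, None] - q["m"][None, :]
    ) ** 2
    ln_rho = e_ln_pi[None, :] + 0.5 * e_ln_lam[None, :] - 0.5 * np.log(2 * np.pi) - 0.5 * quad
    r = np.exp(ln_rho - logsumexp(ln_rho, axis=1, keepdims=True))
    return r, e_ln_lam, e_ln_pi


def _elbo(x: np.ndarray, r: np.ndarray, q: Dict[str, np.ndarray]) -> float:
    k = r.shape[1]
    n_k = r.sum(axis=0) + 1e-12
    xbar = (r * x[:, None]).sum(axis=0) / n_k
    s = (r * (x[:, None] - xbar[None, :]) ** 2).sum(axis=0) / n_k
    e_ln_lam = digamma(q["a"]) - np.log(q["b"])
    e_ln_pi = digamma(q["alpha"]) - digamma(q["alpha"].sum())
    e_lam = q["a"] / q["b"]

    t_lik = 0.5 * np.sum(
        n_k
        * (
            e_ln_lam
            - np.log(2 * np.pi)
            - 1.0 / q["beta"]
            - e_lam * (s + (xbar - q["m"]) ** 2)
        )
    )
    t_z = float(np.sum(n_k * e_ln_pi))
    t_pi = gammaln(k * _ALPHA0) - k * gammaln(_ALPHA0) + (_ALPHA0 - 1.0) * e_ln_pi.sum()
    t_mulam = np.sum(
        0.5 * (np.log(_BETA0) - np.log(2 * np.pi) + e_ln_lam)
        - 0.5 * _BETA0 * (1.0 / q["beta"] + e_lam * (q["m"] - _M0) ** 2)
        + _A0 * np.log(_B0)
        - gammaln(_A0)
        + (_A0 - 1.0) * e_ln_lam
        - _B0 * e_lam
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        t_qz = float(np.sum(np.where(r > 0, r * np.log(r), 0.0)))
    t_qpi = (
        gammaln(q["alpha"].sum())
        - gammaln(q["alpha"]).sum()
        + np.sum((q["alpha"] - 1.0) * e_ln_pi)
    )
    gamma_entropy = q["a"] - np.log(q["b"]) + gammaln(q["a"]) + (1.0 - q["a"]) * digamma(q["a"])
    t_qmulam = np.sum(
        0.5 * (np.log(q["beta"]) - np.log(2 * np.pi) + e_ln_lam) - 0.5 - gamma_entropy
    )
    return float(t_lik + t_z + t_pi + t_mulam - t_qz - t_qpi - t_qmulam)


def fit_vbgmm(
    x: np.ndarray,
    K: int,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> VBGMMFit:
    """Fit one Bayesian univariate GMM by coordinate-ascent VB.

    Responsibilities are initialized from k-means (one restart, seeded);
    the ELBO is non-decreasing across iterations and iteration stops when
    it improves by less than ``tol``.
    """
    x = np.asarray(x, dtype=float).ravel()
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > x.size:
        raise ValueError(f"K={K} exceeds the number of observations ({x.size})")

    if K == 1:
        r = np.ones((x.size, 1))
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            km = KMeans(n_clusters=K, n_init=1, random_state=seed).fit(x[:, None])
        r = np.zeros((x.size, K))
        r[np.arange(x.size), km.labels_] = 1.0

    trace = []
    converged = False
    q = _m_step(x, r)
    for it in range(1, max_iter + 1):
        r, _, _ = _e_step(x, q)
        q = _m_step(x, r)
        trace.append(_elbo(x, r, q))
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
    weights = q["alpha"] / q["alpha"].sum()
    return VBGMMFit(
        K=K,
        weights=weights,
        means=q["m"],
        precisions=q["a"] / q["b"],
        responsibilities=r,
        elbo=trace[-1],
        elbo_trace=np.asarray(trace),
        converged=converged,
        n_iter=it,
    )


def select_components(
    x: np.ndarray, k_max: int = 5, seed: int = 0, tol: float = 1e-6, max_iter: int = 500
) -> Dict[str, object]:
    """Fit K = 1..k_max and pick the highest-ELBO model.

    Components left empty by the fit are pruned before the comparison: the
    reported ``best_k`` is the number of populated components of the
    winning fit.  Deterministic for a fixed seed.
    """
    x = np.asarray(x, dtype=float).ravel()
    fits = {}
    for k in range(1, min(k_max, x.size) + 1):
        fits[k] = fit_vbgmm(x, k, seed=child_seed(seed, k), tol=tol, max_iter=max_iter)
    best = max(fits.values(), key=lambda f: (f.elbo, -f.K))
    return {"best_k": best.effective_k, "best_fit": best, "fits": fits}


def classify_components(fit: VBGMMFit) -> np.ndarray:
    """Hard labels: argmax responsibility per individual."""
    return fit.responsibilities.argmax(axis=1)


def screen_heterogeneity(
    z: pd.DataFrame, k_max: int = 5, seed: int = 0, tol: float = 1e-6
) -> pd.DataFrame:
    """Model selection per gene on a standardized expression matrix.

    Returns a frame indexed by gene with ``best_k``, per-K ELBOs and the
    sizes of the populated components of the winning fit.
    """
    rows = {}
    for i, gene in enumerate(z.index):
        sel = select_components(
            z.loc[gene].to_numpy(), k_max=k_max, seed=child_seed(seed, i), tol=tol
        )
        row = {"best_k": sel["best_k"]}
        for k, f in sel["fits"].items():
            row[f"elbo_k{k}"] = f.elbo
        row["component_sizes"] = ",".join(
            str(int(round(s))) for s in sorted(sel["best_fit"].responsibilities.sum(axis=0))
            if s > 0.5
        )
        rows[gene] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "gene"
    return out


def component_association(
    labels: np.ndarray, covariate: pd.Series | np.ndarray
) -> float:
    """Fisher exact p for association between component labels and a
    categorical covariate (chi-square fallback beyond 2x2 tables).

    Degenerate tables (any margin zero, i.e. a single label or single
    covariate level) return p = 1.
    """
    labels = np.asarray(labels)
    cov = np.asarray(covariate)
    tab = pd.crosstab(labels, cov).to_numpy()
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        return 1.0
    if tab.shape == (2, 2):
        return float(fisher_exact(tab)[1])
    return float(chi2_contingency(tab)[1])


def association_screen(
    component_labels: pd.DataFrame, covariate: pd.Series
) -> pd.DataFrame:
    """Per-gene component-covariate association with BH FDR.

    ``component_labels`` is genes x individuals (hard labels); the
    covariate series is aligned on individual id.
    """
    cov = covariate.reindex(component_labels.columns)
    p = np.array(
        [component_association(component_labels.loc[g].to_numpy(), cov) for g in component_labels.index]
    )
    return pd.DataFrame({"p": p, "q": bh_fdr(p)}, index=component_labels.index)
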