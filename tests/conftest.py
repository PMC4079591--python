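"""Shared fixtures and independent numerical oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.stats import gamma, norm

from metaland.bayes_cluster import NormalGammaPrior
from metaland.simulate import StudyConfig, simulate_study

# Gauss-Legendre nodes for the inner (mean) integral of the oracle
_NODES, _WEIGHTS = np.polynomial.legendre.leggauss(400)


def ng_marginal_oracle(x, prior: NormalGammaPrior = NormalGammaPrior()) -> float:
    """Log marginal likelihood by numerical double integration over
    (mean, precision) — independent of the conjugate closed form."""
    x = np.asarray(x, dtype=float)

    def outer(p):
        sp = 1.0 / np.sqrt(p)
        prior_sp = 1.0 / np.sqrt(prior.kappa0 * p)
        lo = min(x.mean() - 10 * sp, prior.mu0 - 10 * prior_sp)
        hi = max(x.mean() + 10 * sp, prior.mu0 + 10 * prior_sp)
        m = 0.5 * (hi - lo) * _NODES + 0.5 * (hi + lo)
        lik = norm.pdf(x[None, :], m[:, None], sp).prod(axis=1)
        inner = 0.5 * (hi - lo) * np.sum(_WEIGHTS * lik * norm.pdf(m, prior.mu0, prior_sp))
        return inner * gamma.pdf(p, prior.alpha0, scale=1.0 / prior.beta0)

    val = quad(outer, 0, np.inf, epsabs=0, epsrel=1e-9, limit=200)[0]
    return float(np.log(val))


def weir_cockerham_fst(dosage: np.ndarray, populations: pd.Series) -> float:
    """Weir–Cockerham theta-hat across populations, ratio-of-sums over SNPs.

    ``dosage`` is (n_snps, n_individuals) in {0,1,2} (no missing values
    expected here: used on simulator truth output).
    """
    pops = pd.unique(populations)
    r = len(pops)
    groups = [np.flatnonzero((populations == p).to_numpy()) for p in pops]
    n_i = np.array([len(g) for g in groups], dtype=float)
    nbar = n_i.mean()
    n_c = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
    p_i = np.stack([dosage[:, g].mean(axis=1) / 2.0 for g in groups], axis=1)
    h_i = np.stack([(dosage[:, g] == 1).mean(axis=1) for g in groups], axis=1)
    pbar = (n_i[None, :] * p_i).sum(axis=1) / (r * nbar)
    s2 = (n_i[None, :] * (p_i - pbar[:, None]) ** 2).sum(axis=1) / ((r - 1) * nbar)
    hbar = (n_i[None, :] * h_i).sum(axis=1) / (r * nbar)
    a = (nbar / n_c) * (
        s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
    )
    c = hbar / 2.0
    poly = (pbar > 0) & (pbar < 1)
    return float(a[poly].sum() / (a + b + c)[poly].sum())


@pytest.fixture(scope="session")
def small_study():
    """One modest synthetic study shared by read-only tests."""
    cfg = StudyConfig(
        n_snps=600,
        n_genes=400,
        n_individuals_per_population=(15, 15, 15, 15),
        n_landscape_snps=120,
        landscape_freq_shift=0.25,
        n_landscape_de_genes=40,
        n_sex_de_genes=10,
        n_eqtl_pairs=8,
        n_mixture_genes=8,
        mean_coverage_per_snp=25.0,
        seed=42,
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def null_study():
    """A study with every effect switched off (global null)."""
    cfg = StudyConfig(
        n_snps=400,
        n_genes=400,
        n_individuals_per_population=(15, 15, 15, 15),
        n_landscape_snps=0,
        n_landscape_de_genes=0,
        n_sex_de_genes=0,
        n_eqtl_pairs=0,
        n_mixture_genes=0,
        mean_coverage_per_snp=25.0,
        seed=99,
    )
    return simulate_study(cfg)
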