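"""Synthetic metapopulation RNA-seq studies.

Generates the full data bundle the analysis stages consume: drift-structured
biallelic SNP genotypes for four regional populations (two per landscape
type), RNA-seq-like allele read depths, negative-binomial gene expression
with landscape / sex / cis-eQTL / mixture structure, and per-individual
metadata.  All truth assignments are recorded so recovery can be scored.

The generative model
--------------------
* Ancestral allele frequencies are uniform on (0.05, 0.95).  Population
  frequencies follow a Balding–Nichols Beta draw along a two-level tree
  (optional landscape-level branch, then one terminal branch per
  population); a drift parameter ``c`` maps to ``Beta(p(1-c)/c,
  (1-p)(1-c)/c)`` so that ``c`` equals the expected F_ST contributed by the
  branch.  ``c = 0`` is the no-drift limit (frequency copied).
* A configured subset of SNPs receives an extra landscape-correlated
  frequency shift (+delta/2 in fragmented, -delta/2 in continuous
  populations, clipped away from fixation).
* Genotypes are Hardy–Weinberg binomial draws; read depths are Poisson with
  binomial allele sampling, emulating unnormalized RNA-seq coverage.
* Expression counts are NB(mean = L_i * q_g * exp(effects), dispersion
  phi_g) with gene-wise dispersion, log-uniform library sizes, and
  multiplicative landscape, sex, additive-eQTL and latent two-component
  mixture effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .datatypes import AlleleCountMatrix, ExpressionMatrix, GenotypeMatrix, StudyMetadata
from .util import stage_rng

DEFAULT_POPULATIONS = ("AL", "UP", "SA", "OL")
DEFAULT_LANDSCAPE = {"AL": "fragmented", "UP": "fragmented", "SA": "continuous", "OL": "continuous"}


@dataclass
class StudyConfig:
    """Parameters of a synthetic four-population study.

    Defaults follow the study design this package targets: four regional
    populations, two per landscape type, a balanced 15 individuals per
    population, ~10^4 biallelic SNPs and 16,667 gene models.
    """

    populations: Tuple[str, ...] = DEFAULT_POPULATIONS
    landscape_of_population: Dict[str, str] = field(default_factory=lambda: dict(DEFAULT_LANDSCAPE))
    n_individuals_per_population: Sequence[int] = (15, 15, 15, 15)
    n_snps: int = 10_000
    n_genes: int = 16_667
    # drift parameters: expected F_ST per branch, in [0, 1)
    population_drift: Dict[str, float] = field(
        default_factory=lambda: {p: 0.05 for p in DEFAULT_POPULATIONS}
    )
    landscape_drift: Dict[str, float] = field(
        default_factory=lambda: {"fragmented": 0.0, "continuous": 0.0}
    )
    n_landscape_snps: int = 500
    landscape_freq_shift: float = 0.2
    n_landscape_de_genes: int = 200
    landscape_log2_effect: float = 1.0
    n_sex_de_genes: int = 100
    sex_log2_effect: float = 1.0
    n_eqtl_pairs: int = 20
    eqtl_beta: float = 1.0  # natural-log scale per alternate allele
    n_mixture_genes: int = 50
    mixture_delta: float = 3.0  # separation between component means, in log-SD units
    nb_dispersion_range: Tuple[float, float] = (0.05, 0.5)
    library_size_range: Tuple[int, int] = (1_000_000, 10_000_000)
    mean_coverage_per_snp: float = 20.0
    fraction_new_populations: float = 0.25  # share of "new" individuals in fragmented pops
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_individuals_per_population) != len(self.populations):
            raise ValueError("one sample size per population required")
        if any(n <= 0 for n in self.n_individuals_per_population):
            raise ValueError("sample sizes must be positive")
        if self.n_snps < 0 or self.n_genes <= 0:
            raise ValueError("n_snps must be >= 0 and n_genes positive")
        landscapes = set(self.landscape_of_population.values())
        if set(self.landscape_of_population) != set(self.populations):
            raise ValueError("landscape map must cover exactly the configured populations")
        if landscapes != {"fragmented", "continuous"}:
            raise ValueError("need at least one population per landscape type")
        for name, c in list(self.population_drift.items()) + list(self.landscape_drift.items()):
            if not (0.0 <= c < 1.0):
                raise ValueError(
                    f"degenerate drift parameter {c} on branch {name!r}: must be in [0, 1)"
                )
        lo, hi = self.nb_dispersion_range
        if lo <= 0 or hi < lo:
            raise ValueError("NB dispersion range must be positive")
        if self.mean_coverage_per_snp < 0:
            raise ValueError("mean coverage must be non-negative")

    def individual_ids(self) -> pd.Index:
        ids = []
        for pop, n in zip(self.populations, self.n_individuals_per_population):
            ids.extend(f"{pop}_{i + 1:03d}" for i in range(n))
        return pd.Index(ids, name="individual")

    def population_labels(self) -> pd.Series:
        labels = []
        for pop, n in zip(self.populations, self.n_individuals_per_population):
            labels.extend([pop] * n)
        return pd.Series(labels, index=self.individual_ids(), name="population")


@dataclass
class SyntheticStudy:
    """A complete simulated study plus the truth behind it."""

    config: StudyConfig
    allele_counts: AlleleCountMatrix
    truth_genotypes: GenotypeMatrix
    expression: ExpressionMatrix
    metadata: StudyMetadata
    population_freqs: pd.DataFrame  # SNP x population true allele frequencies
    gene_table: pd.DataFrame  # gene coordinates (scaffold, start, end)
    truth: Dict[str, pd.DataFrame]


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, c: float) -> np.ndarray:
    """One drift step: Beta draw with mean p and expected F_ST c (c=0 copies p)."""
    if c == 0.0:
        return p.copy()
    scale = (1.0 - c) / c
    return rng.beta(p * scale, (1.0 - p) * scale)


def _snp_coordinates(rng: np.random.Generator, n_snps: int, gene_table: pd.DataFrame) -> pd.DataFrame:
    """Place SNPs uniformly on the gene-bearing scaffolds."""
    scaffolds = gene_table["scaffold"].unique()
    span = int(gene_table["end"].max()) + 5_000
    scaf = rng.choice(scaffolds, size=n_snps)
    pos = rng.integers(1, span, size=n_snps)
    bases = np.array(list("ACGT"))
    ref_i = rng.integers(0, 4, size=n_snps)
    alt_i = (ref_i + rng.integers(1, 4, size=n_snps)) % 4
    df = pd.DataFrame(
        {
            "scaffold": scaf,
            "pos": pos,
            "ref": bases[ref_i],
            "alt": bases[alt_i],
        },
        index=pd.Index([f"snp{i + 1:06d}" for i in range(n_snps)], name="snp"),
    )
    return df


def make_gene_table(n_genes: int, genes_per_scaffold: int = 200) -> pd.DataFrame:
    """Deterministic gene models: fixed-length genes tiled along scaffolds."""
    length, gap = 2_000, 3_000
    rows = []
    for g in range(n_genes):
        scaf = f"scaffold{g // genes_per_scaffold + 1:04d}"
        k = g % genes_per_scaffold
        start = 1 + k * (length + gap)
        rows.append((scaf, start, start + length - 1))
    return pd.DataFrame(
        rows,
        columns=["scaffold", "start", "end"],
        index=pd.Index([f"gene{i + 1:05d}" for i in range(n_genes)], name="gene"),
    )


def simulate_genotypes(
    config: StudyConfig,
) -> Tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame, pd.Index]:
    """Draw truth genotypes under the drift tree.

    Returns
    -------
    genotypes : GenotypeMatrix
        Truth dosages (complete, no missingness).
    population_freqs : DataFrame
        True alternate-allele frequency per SNP and population.
    snp_table : DataFrame
        SNP coordinates (scaffold, pos, ref, alt).
    landscape_snps : Index
        SNPs carrying the extra landscape-correlated frequency shift.
    """
    rng = stage_rng(config.seed, "genotypes")
    gene_table = make_gene_table(config.n_genes)
    snp_table = _snp_coordinates(rng, config.n_snps, gene_table)

    anc = rng.uniform(0.05, 0.95, size=config.n_snps)
    land_freq = {}
    for land in ("fragmented", "continuous"):
        land_freq[land] = _balding_nichols(rng, anc, config.landscape_drift.get(land, 0.0))
    pop_freq = {}
    for pop in config.populations:
        base = land_freq[config.landscape_of_population[pop]]
        pop_freq[pop] = _balding_nichols(rng, base, config.population_drift[pop])

    # landscape-correlated shift on a configured subset
    n_shift = min(config.n_landscape_snps, config.n_snps)
    landscape_snps = pd.Index(
        snp_table.index[rng.choice(config.n_snps, size=n_shift, replace=False)]
        if n_shift
        else [],
        name="snp",
    )
    shift_idx = snp_table.index.get_indexer(landscape_snps)
    delta = config.landscape_freq_shift
    for pop in config.populations:
        s = delta / 2 if config.landscape_of_population[pop] == "fragmented" else -delta / 2
        pop_freq[pop][shift_idx] = np.clip(pop_freq[pop][shift_idx] + s, 0.01, 0.99)

    freqs = pd.DataFrame(pop_freq, index=snp_table.index)[list(config.populations)]

    pops = config.population_labels()
    dosage = np.empty((config.n_snps, len(pops)), dtype=float)
    col = 0
    for pop, n in zip(config.populations, config.n_individuals_per_population):
        dosage[:, col : col + n] = rng.binomial(
            2, freqs[pop].to_numpy()[:, None], size=(config.n_snps, n)
        )
        col += n
    genotypes = GenotypeMatrix(snp_ids=snp_table.index, populations=pops, dosage=dosage)
    return genotypes, freqs, snp_table, landscape_snps


def simulate_allele_reads(
    genotypes: GenotypeMatrix, config: StudyConfig, snp_table: Optional[pd.DataFrame] = None
) -> AlleleCountMatrix:
    """Poisson depth, binomial allele sampling per (SNP, individual)."""
    if np.isnan(genotypes.dosage).any():
        raise ValueError("truth genotypes must be complete")
    if config.mean_coverage_per_snp < 0:
        raise ValueError("mean coverage must be non-negative")
    rng = stage_rng(config.seed, "reads")
    if snp_table is None:
        gene_table = make_gene_table(config.n_genes)
        snp_table = _snp_coordinates(stage_rng(config.seed, "genotypes"), config.n_snps, gene_table)
    depth = rng.poisson(config.mean_coverage_per_snp, size=genotypes.dosage.shape)
    alt = rng.binomial(depth, genotypes.dosage / 2.0)
    return AlleleCountMatrix(
        snps=snp_table.loc[genotypes.snp_ids],
        populations=genotypes.populations,
        ref_count=depth - alt,
        alt_count=alt,
    )


def _simulate_metadata(config: StudyConfig, rng: np.random.Generator) -> StudyMetadata:
    pops = config.population_labels()
    land = pops.map(config.landscape_of_population)
    sex = pd.Series(rng.choice(["F", "M"], size=len(pops)), index=pops.index, name="sex")
    age = pd.Series("old", index=pops.index, name="age_class")
    for pop in config.populations:
        if config.landscape_of_population[pop] == "fragmented":
            members = pops.index[pops == pop]
            n_new = int(round(config.fraction_new_populations * len(members)))
            if n_new:
                chosen = rng.choice(len(members), size=n_new, replace=False)
                age.loc[members[chosen]] = "new"
    table = pd.DataFrame(
        {
            "population": pops,
            "landscape": land,
            "sex": sex,
            "age_class": age,
            "flight": "control",
        }
    )
    return StudyMetadata(table=table)


def simulate_expression(
    config: StudyConfig,
    genotypes: GenotypeMatrix,
    metadata: Optional[StudyMetadata] = None,
    landscape_snps: Optional[pd.Index] = None,
    snp_table: Optional[pd.DataFrame] = None,
) -> Tuple[ExpressionMatrix, StudyMetadata, Dict[str, pd.DataFrame]]:
    """NB expression with landscape / sex / eQTL / mixture effects.

    Truth-effect genes are drawn among genes whose baseline abundance is
    high enough to be observable (top half of the abundance distribution):
    an effect planted on a never-expressed gene would be untestable by any
    method and does not occur in the study's curated DE lists.
    """
    lo, hi = config.nb_dispersion_range
    if lo <= 0:
        raise ValueError("dispersion must be positive")
    rng = stage_rng(config.seed, "expression")
    if metadata is None:
        metadata = _simulate_metadata(config, rng)
    inds = metadata.individuals
    n, g = len(inds), config.n_genes
    gene_table = make_gene_table(g)
    genes = gene_table.index

    # heavy-tailed relative abundance: half the genes near zero expression
    q = rng.lognormal(mean=0.0, sigma=2.0, size=g)
    q /= q.sum()
    phi = rng.uniform(lo, hi, size=g)
    lib = np.exp(
        rng.uniform(np.log(config.library_size_range[0]), np.log(config.library_size_range[1]), size=n)
    )

    log_mu = np.log(q)[:, None] + np.log(lib)[None, :]

    frag = (metadata.landscape == "fragmented").to_numpy()
    male = (metadata.table["sex"] == "M").to_numpy()

    # cis-eQTL pairs first: a SNP's effect lands on its *nearest* gene (the
    # relation the downstream screen assumes), so pair selection walks
    # candidate SNPs and keeps those whose nearest gene is expressed.
    # Candidates have intermediate frequency (all three genotype classes
    # realistically present) and prefer landscape-shifted SNPs so that the
    # screen's landscape-differentiation filter can pass.
    from .eqtl import nearest_gene_map  # local import avoids cycle at module load

    if snp_table is None and config.n_snps:
        snp_table = _snp_coordinates(
            stage_rng(config.seed, "genotypes"), config.n_snps, gene_table
        )
    snp_ids = genotypes.snp_ids
    expressed_set = set(np.flatnonzero(q > np.median(q)))
    gene_pos = {g: i for i, g in enumerate(genes)}
    eqtl_snp_idx: List[int] = []
    eqtl_gene_idx: List[int] = []
    if config.n_eqtl_pairs and config.n_snps:
        mean_dosage = genotypes.dosage.mean(axis=1)
        inter = (mean_dosage > 0.6) & (mean_dosage < 1.4)
        if landscape_snps is not None and len(landscape_snps):
            shifted = np.zeros(len(snp_ids), dtype=bool)
            shifted[snp_ids.get_indexer(landscape_snps)] = True
        else:
            shifted = np.ones(len(snp_ids), dtype=bool)
        cand = np.flatnonzero(inter & shifted)
        rng.shuffle(cand)
        gmap = nearest_gene_map(snp_table.iloc[cand], gene_table)
        used_genes: set = set()
        for si in cand:
            sid = snp_ids[si]
            if sid not in gmap.index:
                continue
            gi = gene_pos[gmap.loc[sid, "gene"]]
            if gi not in expressed_set or gi in used_genes:
                continue
            eqtl_snp_idx.append(si)
            eqtl_gene_idx.append(gi)
            used_genes.add(gi)
            if len(eqtl_snp_idx) == config.n_eqtl_pairs:
                break
    eqtl_snp_idx = np.asarray(eqtl_snp_idx, dtype=int)
    eqtl_gene_idx = np.asarray(eqtl_gene_idx, dtype=int)
    for sj, gj in zip(eqtl_snp_idx, eqtl_gene_idx):
        dos = genotypes.dosage[sj]
        log_mu[gj] += config.eqtl_beta * (dos - dos.mean())

    expressed = np.array(sorted(expressed_set - set(eqtl_gene_idx)), dtype=int)
    rng.shuffle(expressed)
    cursor = 0

    def take(k: int) -> np.ndarray:
        nonlocal cursor
        out = expressed[cursor : cursor + k]
        cursor += k
        return out

    # landscape-DE genes, random sign
    de_idx = take(min(config.n_landscape_de_genes, len(expressed)))
    de_sign = rng.choice([-1.0, 1.0], size=de_idx.size)
    eff = config.landscape_log2_effect * np.log(2.0)
    for j, s in zip(de_idx, de_sign):
        log_mu[j, frag] += s * eff / 2
        log_mu[j, ~frag] -= s * eff / 2

    # sex-DE genes
    sex_idx = take(min(config.n_sex_de_genes, max(len(expressed) - cursor, 0)))
    sex_sign = rng.choice([-1.0, 1.0], size=sex_idx.size)
    seff = config.sex_log2_effect * np.log(2.0)
    for j, s in zip(sex_idx, sex_sign):
        log_mu[j, male] += s * seff / 2
        log_mu[j, ~male] -= s * seff / 2

    # latent two-component mixture genes (individual-level Bernoulli(0.5) shift,
    # independent of population); separation in units of the log-scale SD
    mix_idx = take(min(config.n_mixture_genes, max(len(expressed) - cursor, 0)))
    mix_assign = np.zeros((mix_idx.size, n), dtype=int)
    med_lib = np.median(lib)
    for row, j in enumerate(mix_idx):
        z = rng.integers(0, 2, size=n)
        mix_assign[row] = z
        base_mean = q[j] * med_lib
        s_log = np.sqrt(phi[j] + 1.0 / max(base_mean, 1e-9))
        shift = config.mixture_delta * s_log
        log_mu[j] += (z - 0.5) * shift

    mu = np.exp(log_mu)
    r = 1.0 / phi
    # NB as Gamma-Poisson mixture, vectorized over the matrix
    lam = rng.gamma(shape=r[:, None], scale=mu / r[:, None])
    counts = rng.poisson(lam)

    expr = ExpressionMatrix(counts=pd.DataFrame(counts, index=genes, columns=inds))
    truth = {
        "landscape_de": pd.DataFrame(
            {"gene": genes[de_idx], "sign": de_sign.astype(int), "log2_effect": config.landscape_log2_effect}
        ),
        "sex_de": pd.DataFrame({"gene": genes[sex_idx], "sign": sex_sign.astype(int)}),
        "eqtl": pd.DataFrame(
            {
                "snp": snp_ids[eqtl_snp_idx],
                "gene": genes[eqtl_gene_idx],
                "beta": config.eqtl_beta,
            }
        ),
        "mixture": pd.DataFrame({"gene": genes[mix_idx], "delta": config.mixture_delta}),
        "dispersion": pd.DataFrame({"gene": genes, "phi": phi}),
    }
    return expr, metadata, truth


def simulate_study(config: StudyConfig) -> SyntheticStudy:
    """End-to-end generation of one synthetic study."""
    genotypes, freqs, snp_table, landscape_snps = simulate_genotypes(config)
    reads = simulate_allele_reads(genotypes, config, snp_table=snp_table)
    expr, metadata, truth = simulate_expression(
        config, genotypes, landscape_snps=landscape_snps, snp_table=snp_table
    )
    truth["landscape_snps"] = pd.DataFrame({"snp": landscape_snps})
    return SyntheticStudy(
        config=config,
        allele_counts=reads,
        truth_genotypes=genotypes,
        expression=expr,
        metadata=metadata,
        population_freqs=freqs,
        gene_table=make_gene_table(config.n_genes),
        truth=truth,
    )
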