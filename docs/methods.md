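# Methods

This note records the statistical models implemented in `metaland`, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical choices that matter for reproducing
results.

## The synthetic study

The generator produces a four-population study, two populations per
landscape type, with paired genotype and expression read-outs for the same
individuals — the structure every analysis stage assumes.

**Genotypes.** Ancestral alternate-allele frequencies are uniform on
(0.05, 0.95).  Each population's frequency is a Balding–Nichols Beta draw
`Beta(p(1-c)/c, (1-p)(1-c)/c)` along a two-level tree (an optional
landscape-level branch followed by one terminal branch per population).  The
drift parameter `c` equals the expected F_ST contributed by that branch;
`c = 0` is the exact no-drift limit.  The default of `c = 0.05` per terminal
branch gives closely related populations (the Weir–Cockerham estimate on
simulator output is within ±0.02 of 0.05 at 10^4 SNPs, asserted in tests).
A configured subset of SNPs (default 500 of 10^4) receives an extra
landscape-correlated shift of ±δ/2 (default δ = 0.2), clipped away from
fixation — the planted "landscape adaptation" signal.  Individual genotypes
are Hardy–Weinberg binomial draws.

**Allele reads.** Depth per (SNP, individual) is Poisson with mean 20 by
default; alternate reads are Binomial(depth, dosage/2).  This emulates
unnormalized RNA-seq coverage with frequent low-coverage entries — the
regime the genotype-scoring rules were designed for.  No sequencing-error or
allelic-bias model is included, so genotype scoring at high depth is exact;
a green recovery test establishes the scoring logic, not robustness to
miscalls.

**Expression.** Counts are negative binomial with mean
`L_i · q_g · exp(effects)` and gene-wise dispersion φ_g uniform on
(0.05, 0.5) (squared biological CV — the typical bulk RNA-seq range).
Relative abundances `q_g` are log-normal with σ = 2, putting half the genes
near zero expression as in 3′-anchored count data.  Library sizes are
log-uniform on (10^6, 10^7): a >10× spread without modeling lanes or
batches.  Effects are multiplicative: a landscape effect of ±log2-effect/2
per group with a random sign per gene (default 200 genes at 1 log2 unit), a
sex effect of the same form, an additive cis-eQTL effect β·(dosage − mean
dosage) on the gene *nearest* the eQTL SNP (the relation the screen tests;
eQTL SNPs are drawn among landscape-shifted SNPs of intermediate frequency
so that all three genotype classes occur and the screen's
landscape-differentiation filter is satisfiable), and for mixture genes an
individual-level latent Bernoulli(0.5) shift of `delta` log-scale standard
deviations (`s_g = sqrt(φ_g + 1/mean count)`, the delta-method SD of log
counts), independent of population — matching the observation that bimodal
expression was largely unrelated to the designed covariates.  Effect genes
are planted only among genes above median abundance: an effect on a
never-expressed gene is untestable by construction.

**What a green test does not establish.** The generator has no mapping
bias, no isoform structure, no batch effects, no sequencing error, and no
linkage between SNPs.  Calibration and recovery results transfer to real
data only insofar as those ignored features are negligible.

**Reproducibility.** One study seed is expanded into fixed per-stage
substreams (`SeedSequence` spawn keys), so regenerating one stage never
consumes another stage's random numbers; identical seeds give byte-identical
output files.

## SNP panel and genotype scoring

The panel filter keeps SNPs that are (a) biallelic in pooled reads, (b)
covered (depth ≥ 1 by default) in ≥10 individuals of *every* population, and
(c) have pooled minor-allele count ≥ ⌈0.05·N⌉ (9 at N = 174).  The three
filters are independent predicates, so the panel is order-independent; the
first failing filter is recorded per dropped SNP.  The MAC is counted over
scored genotypes (two alleles per called individual); whether the original
analysis counted individuals or reads is not documented, and this choice is
exposed by passing a custom `genotypes` argument.  Genotype scoring is
verbatim: het at ≥3 reads of both alleles, hom at ≥10 reads of a single
allele, else missing.

## Allele-frequency differentiation

Fisher exact tests run on 2×2 tables of genotype-backed allele counts pooled
within each population group, two-sided, with BH FDR across SNPs (the FDR
procedure is BH by choice; no specific procedure was prescribed).  The
landscape permutation test uses |Δp̂| between landscape groups and permutes
*individual* labels: with only four populations, permuting population blocks
admits just three distinct relabelings, far too few for meaningful p-values.
Two consequences are documented rather than hidden:

* the statistic is discrete (counts over ~30 individuals per group) with an
  atom at zero, so null p-values are *super*-uniform — valid and
  conservative, with excess mass near 1; calibration tests therefore check
  one-sided uniformity and rejection-rate bounds, not two-sided KS;
* individual-label permutation assumes exchangeability, which drift
  violates: with drift > 0 the test detects *any* population differentiation,
  not landscape adaptation specifically.  Calibration is run at zero drift,
  where the null is exact.

P-values use the add-one convention `(1 + #{perm ≥ obs})/(1 + n_perm)`, so
the smallest attainable p is `1/(1 + n_perm)` and p = 0 never occurs.

## TMM and the dual differential-expression procedure

TMM follows the published trimmed-mean-of-M-values scheme: the reference is
the individual whose upper-quartile depth-normalized count is closest to the
mean upper quartile; per individual, log2 ratios (M) against the reference
are trimmed at 30% and average abundances (A) at 5%, combined with
reciprocal-delta-method-variance weights, and factors are rescaled to
geometric mean 1.  The implementation matches edgeR's `calcNormFactors` to
~1e-6 on shared matrices (asserted via an Rscript cross-check in the tests —
a test oracle, not a dependency).  Log-CPM uses `log2(CPM + 0.5)`; the +0.5
offset avoids log 0 and is the package's reading of "logarithmic normalized
read counts".

The NB GLM fits one mean per population with `log` link and offset = log
effective library size.  Dispersion is estimated per gene by Cox–Reid
adjusted profile likelihood on a 21-point log grid with quadratic
refinement, then shrunk toward a binned-median abundance trend with weight
`prior_df` (default 10) against the residual degrees of freedom — moderation
in the spirit of empirical-Bayes genewise dispersion, with the strength
configurable.  The landscape contrast (mean of fragmented population means
minus mean of continuous ones, log scale) is tested by likelihood ratio
against the model constrained to contrast = 0 (fitted on a null-space basis
of the contrast), referred to χ²(1).  Type-I error on 2,000 simulated null
genes lands within [0.03, 0.07] at α = 0.05, and the median estimated log2FC
of planted 1-log2-unit effects is within ±0.2 (both asserted).

The permutation test awards the statistic |mean log-CPM difference between
landscape groups| only when the four population means are
landscape-consistent — both fragmented means strictly above both continuous
means, or strictly below; otherwise the gene (or the permuted replicate)
scores zero.  Labels are permuted at the individual level (the same
rationale as for the allele-frequency test; whether the original procedure
preserved population structure under the null is undocumented, and free
permutation is the recorded assumption).  The consistency requirement makes
the test conservative under the null.  The default of 10^5 permutations is
reduced to 10^4 in the pipeline defaults for desk-scale runtime; both are
flags.  Landscape-DE genes are the intersection of the two FDR<α sets, and
the intersection is monotone in α.

## Partition scoring by Normal–Gamma marginal likelihood

Expression is TMM-normalized, log2-transformed and standardized per gene to
zero mean and unit variance over all individuals (unbiased SD; a knob, as
the convention was not documented).  For each of the 15 set partitions of
the four populations, the score is the sum over genes and clusters of the
closed-form Normal–Gamma log marginal likelihood with prior
`m | p ~ N(0, 1/p)`, `p ~ Exp(1) = Gamma(1, 1)` — the fully conjugate choice.
The closed form is verified against an independent numerical double
integration over (mean, precision) to better than 1e-6 on random vectors.
Ties rank toward fewer blocks.  Reported values are natural logs; their
absolute magnitude scales with data size and is not comparable across data
sets.

## VB Gaussian mixture screening

Per gene, univariate Bayesian GMMs with K = 1..5 are fitted to the
standardized values by coordinate-ascent variational Bayes with a symmetric
Dirichlet(1) prior on weights and Normal–Gamma(0, 1, 1, 1) priors on
component parameters — the same family as the partition model, which is what
standardizing to unit variance buys: one uninformative prior serves every
gene.  Responsibilities are initialized from k-means (one seeded restart by
default).  The ELBO is the model-selection criterion (the variational bound
stands in for the marginal likelihood); it is checked to be non-decreasing
at every iteration, and for K = 1 the bound converges to the *exact*
Normal–Gamma log marginal likelihood (the Dirichlet terms vanish), which the
tests assert to 1e-9 — a strong joint check of both implementations.
Components supported by less than half an individual of responsibility mass
are pruned before the comparison.  Convergence is |ΔELBO| < 1e-6 with a
500-iteration cap; the original convergence rule and hyperparameters are
undocumented, so these defaults are assumptions.  "Well-separated" in the
selection tests means components at ±2 with component SD 0.5; at a
separation of only 4 within-component SDs and n = 60, the exact Bayes factor
itself is indifferent (BIC agrees), so no honest selector can be near-certain
there.

## Kinship-GLS eQTL

Relatedness between two individuals is the mean over jointly-called SNPs of
the shared-allele fraction `1 − |Δdosage|/2` — the package's concrete
reading of "covariance from shared alleles", which the source does not
specify; the diagonal is 1 and a 1e-6 ridge keeps the matrix positive
definite.  Pairs with no jointly-called SNPs are imputed with their
population-pair mean (logged).  Each SNP is tested against its nearest gene
(midpoint distance on the same scaffold, ties to the lower coordinate) by
GLS with error covariance proportional to the population's kinship submatrix
(fits run separately per population), under additive (0/1/2), dominance
(0/1/1) and recessive (0/0/1) codings; a population contributes a fit only
if all three genotype classes are present.  With identity covariance the
estimator reduces exactly to OLS (asserted to 1e-10).  FDR is BH within
population across tested pairs of a coding (the FDR scope was unstated).  A
pair is accepted iff the SNP is landscape-differentiated, FDR < 0.05 in at
least one population, and the coefficient sign agrees in every population
with a defined fit.  An optional sex covariate is available (default off;
whether the original fits included one is unknown).

## Enrichment and concordance

The category test is the exact binomial upper tail P(X ≥ k) at the
study-wide significance rate; the over-representation test is one-sided
Fisher (hypergeometric upper tail, verified against brute-force summation).
Concordance analyses first filter to genes with logCPM > 1 in both data sets
and |log2 ratio| > 1 (strict inequalities), then correlate the two per-gene
contrasts; Pearson is the default and Spearman a flag, since the original
correlation statistic is unstated.  A leave-one-population-out recomputation
of the landscape contrast guards against shared individuals driving the
correlation.  For the flight-response comparison the direction-agreement
table and its Fisher p are the primary output; the correlation p-value is
computed but should be treated with caution when genes are co-regulated
(degrees of freedom are inflated), which is why the pipeline reports the
table alongside.

## Known limitations

* The NB-GLM dispersion moderation shrinks the genewise APL estimate toward
  a binned-median trend in log space; it is not the full weighted-APL
  maximization of edgeR, and genewise estimates at very low counts rail to
  the grid bounds before moderation.
* Individual-label permutation tests are anti-conservative for the
  *landscape* hypothesis when populations carry drift: they test
  exchangeability, not landscape effects specifically.  This mirrors the
  original design and is flagged in the test suite.
* The eQTL screen is cis-only, one SNP → one nearest gene; no
  variance-component mixed model, no trans effects.
* Partition enumeration is exact and therefore capped at 12 labels (Bell
  numbers explode).
* The flight-treatment arm of the synthetic metadata is a placeholder
  (all controls); flight-vs-baseline concordance is exercised on
  constructed contrast vectors in the tests.
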