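# Methods

`mtgblup` compares single-trait and bivariate (multi-trait) GBLUP genomic
prediction on simulated pig-breeding populations. This note documents the
models, the synthetic-data generator, the numerical choices, and the known
limitations of what desk-scale simulation can and cannot show.

## The prediction models

Both models predict additive genetic merit (breeding values) of genotyped
but unphenotyped selection candidates from a phenotyped, genotyped
reference population.

**Single trait.** For reference phenotypes `y` (one record per animal),

    y = 1 mu + Z g + e,   g ~ N(0, G sigma_a^2),   e ~ N(0, I sigma_e^2),

where `g` contains one additive effect per individual in the genomic
relationship matrix `G` (reference *and* candidates) and `Z` selects the
phenotyped rows. `G` is VanRaden's method 1,

    G = W W' / sum_j 2 p_j (1 - p_j),

with `W` the allele-dosage matrix column-centered by twice the allele
frequency `p_j`; frequencies are computed on reference and candidates
jointly, and a small epsilon (default 1e-6) is added to the diagonal.
Narrow-sense heritability is `h^2 = sigma_a^2 / (sigma_a^2 + sigma_e^2)`.

**Bivariate.** The two-trait model stacks both phenotype vectors and lets
additive effects covary across traits through a 2x2 matrix `M` and
residuals through a 2x2 matrix `R`:

    [y1; y2] = (I_2 (x) 1) u + (I_2 (x) Z) [g1; g2] + [e1; e2],
    [g1; g2] ~ N(0, M (x) G),     [e1; e2] ~ N(0, R (x) I).

The genetic correlation is `r_g = M_12 / sqrt(M_11 M_22)`. Six parameters
(three in `M`, three in `R`) are free; both traits must be recorded on the
same reference animals (candidates are unphenotyped for both), which is
the breeding design this package simulates. Other missing-value patterns
are rejected.

**Accuracy.** Predictive performance is the squared Pearson correlation
(coefficient of determination) between candidate GEBVs and true breeding
values over the candidate set; `accuracy(..., squared=False)` exposes the
plain correlation for sensitivity checks.

## AI-REML in the GRM eigenbasis

Variance components maximize the restricted likelihood. Writing
`G_oo = U diag(d) U'` for the observed (reference) block of `G`, the
phenotype covariance becomes diagonal (single trait:
`v_i = sigma_a^2 d_i + sigma_e^2`) or 2x2-block-diagonal (bivariate:
`V_i = d_i M + R`) after rotating the data by `U'`. One symmetric
eigendecomposition therefore reduces every REML iteration — restricted
log-likelihood, analytic gradient, average-information matrix, EM update
— to O(n) work. This is algebraically identical to dense AI-REML; it is
not an approximation.

Iteration policy:

- **Step**: Newton step with the average-information matrix; proposed
  covariance matrices are bent (eigenvalues floored at 1e-6 x trace)
  back into the positive-definite cone.
- **Ascent guarantee**: a step that lowers the restricted log-likelihood
  is halved up to 30 times; if still failing, an EM-REML step is taken
  (matrix form `M <- M + M S_M M / n`, which reduces to the scalar
  EM update in one dimension). Accepted iterations never decrease the
  log-likelihood, and every iteration (value, parameters, step type) is
  recorded in a `ConvergenceLog`.
- **Start values**: half the phenotypic (co)variance assigned to the
  additive and residual parts.
- **Convergence**: relative parameter change below `tol` (default 1e-8;
  the scenario driver uses 1e-6) *and* log-likelihood change below 1e-6.
  Hitting `max_iter` (default 200) flags the fit as non-converged and
  returns the last estimates — non-convergence is a recorded outcome,
  not an exception, because low-heritability/low-correlation trait pairs
  legitimately produce it.
- **Degenerate input**: a constant phenotype returns boundary variance
  components with status `degenerate`.

GEBVs, including candidates, come from the marginal BLUP identity
`g_hat = Cov(g, y) V^{-1} (y - X b_hat)`, which coincides exactly with
solving Henderson's mixed-model equations with zero incidence rows for
unphenotyped individuals (the two-step projection `G_co G_oo^{-1} g_o`
is *not* used). Standard errors of variance components come from the
inverse average-information matrix at the optimum; heritability and
genetic-correlation standard errors use the delta method.

## The synthetic data generator

The real genotypes behind the study design (a 50K-chip pig population)
are not redistributable, so the package generates its own substrate. The
generator's job is to provide what the trait simulator needs: phased
diploid biallelic SNPs on multiple chromosomes, allele frequencies across
the MAF >= 0.05 spectrum, and intra-chromosomal LD rich enough that any
locus has nearby partners with signed dosage correlation near 0.2, 0.5
and 0.8.

**Founders.** Each haplotype is a first-order Markov "copy" chain along
the chromosome: the allele at SNP j copies SNP j-1 with probability
`adjacency_rho` (default 0.95), else is redrawn from that SNP's marginal
frequency (uniform on [0.05, 0.95]). Signed LD between loci k apart then
decays like `0.95^k`, whose ladder (0.95, 0.81 at lag 4, 0.51 at lag 13,
0.20 at lag 31) covers all three pairing targets inside the +/-50-SNP
search window. Founder sexes default to 1 male per 9 females, mirroring
a nucleus herd of 500 boars and 4500 sows; the scenario driver instead
generates parents at the 1:24 mating ratio it needs.

**Meiosis.** Each gamete draws its crossover count per chromosome
uniformly from {4, 5, 6}, places distinct breakpoints uniformly on the
SNP-index interval (uniform-in-bp is available as an option), starts on
a random parental haplotype, and copies mosaics with no mutation and no
interference beyond the fixed count range. One generation only: sires
each serve 24 dams, every dam has 12 offspring, and 2000 candidates (500
at desk scale) are sampled from the F1.

**Traits.** A pair of genetically correlated traits is built from 500
QTL pairs: trait-A QTLs are sampled uniformly from segregating loci;
each is matched with the non-QTL locus within +/-50 SNPs whose signed
dosage correlation is closest to the target (tolerance 0.05, failures
resampled); both members of a pair receive the *same* signed effect —
gamma(shape 0.4, scale 2/3) magnitude, random sign. TBV is the
effect-weighted dosage sum; the additive variance `V_g` is the empirical
TBV variance over the founder/reference population; the residual
variance follows from `h^2 = V_g / (V_g + V_e)`, and phenotypes add
independent N(0, V_e) residuals per trait (residual cross-trait
covariance is zero by construction, though the bivariate model still
estimates it freely).

Because effects are shared, each pair contributes genetic covariance
proportional to its dosage correlation, so the correlation of the two
TBV vectors approaches the LD target. Two realities of this construction
are worth knowing:

- The per-draw realized correlation is noisy: gamma(0.4) effects are
  heavy-tailed (a few dozen pairs dominate), and at desk marker density
  (500 pairs in 3000 SNPs) cross-pair LD adds noise with sd ~0.09 at the
  low target. At chip-like density (1000 pair loci in ~38k SNPs) it
  concentrates to sd ~0.03. Quantities defined as "the realized genetic
  correlation" are therefore reported as means over independent
  replicate simulations.
- The realized correlation is mildly attenuated (about 0.015-0.02 below
  the target) because the paired loci have unequal dosage variances.

## What desk scale does and does not show

Tests and the acceptance script run the full pipeline at reduced scale
(reference sizes 600-2500, 3 chromosomes x 1000 SNPs, 20 or fewer
replicates). Two scale effects matter when reading the results:

- **Accuracy levels are inflated.** With ~3000 SNPs and long-range
  geometric LD, the genome has on the order of 10^2 independently
  segregating segments, so GBLUP accuracies at n_ref ~1000 (0.36-0.72
  across h^2 levels) sit well above what a real 50K-chip population
  shows at n_ref = 4500. Orderings between models are meaningful at
  desk scale; absolute accuracies are not.
- **The estimated genetic correlation is architecture-dependent.** The
  two traits have effects at *disjoint* loci, so their marker-effect
  vectors are orthogonal; the cross-trait signal lives purely in LD.
  Bivariate GBLUP reads the genetic covariance through `G`: at small n
  the paired loci are indistinguishable inside their LD block and the
  estimate saturates above the target (target 0.8 -> ~0.95); with
  enough data the smooth geometric LD makes the pair separable and the
  marker-level covariance falls below the TBV correlation. Single-trait
  heritability estimation is unaffected (recovered to within 0.01-0.02).

A consequence the scenario experiments make visible: with the genetic
correlation read as high, the second trait of a pair nearly doubles the
reference information available to a low-heritability trait, so at desk
scale the largest multi-trait gains appear for *low*-h^2 traits at high
r_g — the same direction as the unequal-heritability result (the lower
trait of a mixed pair gains more), and the direction selection-index
theory predicts. At mid and low r_g, the variance cost of estimating six
covariance parameters at desk n can leave the bivariate model a fraction
of a percent *behind* the single-trait model on average. Both behaviors
are properties of the method at these sample sizes, and the test suite
reports them as measured.

## Scenario driver and reproducibility

`run_scenario1` crosses equal-h^2 pairs {0.1, 0.3, 0.5} with genetic
correlations {0.2, 0.5, 0.8} over a configurable reference-size grid;
`run_scenario2` runs unequal-h^2 pairs (default (0.3, 0.5) and
(0.1, 0.5), a reconstruction — the exact published combinations are
shown only graphically) at a fixed reference size, reporting per-trait
accuracies. For each reference size the founder pool is subsampled
first (preserving 1:24), then the F1 is regenerated. Replicates re-draw
everything — founders, matings, QTLs, effects, residuals.

Seeding uses `numpy.random.SeedSequence(master_seed, spawn_key=(cell,
size, replicate))`, so any single replicate can be re-run in isolation
and a full run reproduces byte-for-byte (wall-time columns aside).
Within a replicate the same data go to both models, so model contrasts
are paired. Per-fit wall times are recorded as information only; they
say nothing about the reference software the models replace.

## Known limitations

- Additive genetics only: no dominance, epistasis, pleiotropy, mutation,
  selection, crossover interference, or sex chromosomes; one generation.
- The Markov-copy genome has geometric, smooth LD; real chip LD is
  blocky, heterogeneous and low-rank within blocks, which is precisely
  why desk-scale genetic-correlation estimates behave as described
  above.
- Two traits per model; dense Cholesky/eigendecomposition linear algebra
  (no sparse or APY-style solvers), practical to a few thousand
  phenotyped individuals.
- The PLINK reader supports the formats this package writes (bed/bim/fam
  SNP-major, ped/map with A/B allele coding); it is an interchange
  convenience, not a general-purpose QC stack.
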