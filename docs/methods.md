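# Methods

## The model

`famvar` decomposes the phenotypic variance of a trait measured in a family
cohort into genetic and shared-environment components with the linear mixed
model

    y = Xb + g + k + f + c + s + e

where `X` holds fixed covariates (sex, age if available, and leading
eigenvectors of the genomic relationship matrix to absorb large-scale
structure) and each random term has covariance `sigma^2_i A_i`:

| term | structure `A_i` | interpretation |
|------|-----------------|----------------|
| g | **G**, genomic relationship matrix from genome-wide SNPs | SNP (chip) heritability |
| k | **K**, pedigree numerator relationship matrix (2x kinship) | additive genetic variance not tagged by SNPs |
| f | **F**, 1 iff same nuclear family | family environment |
| c | **C**, 1 iff spouses | couple environment |
| s | **S**, 1 iff full siblings | sibling environment |
| e | identity | residual |

G uses the standard GREML estimator
`A_jk = (1/m) sum_i (x_ij - 2p_i)(x_ik - 2p_i) / (2 p_i (1 - p_i))` with
sample allele frequencies, mean imputation of missing calls and per-pair
SNP counts in the denominator.  K is built by the tabular recursion and
supports inbreeding (diagonal `1 + F_inb`).  F, C and S are {0,1} block
indicators with unit diagonal; they may be singular, and a diagonal
"bending" of 1e-6 is available where an inverse is required (the REML
solver itself never needs the individual matrices inverted, only their
non-negative combination plus the residual).

## REML

Variance components are estimated by restricted maximum likelihood using
average-information (AI) updates: one EM step first, then Newton steps on
the AI matrix with step-halving and an EM fallback whenever a step would
reduce the restricted likelihood.  Convergence is declared when the change
in restricted log-likelihood falls below 1e-6 (at most 100 iterations).
Components are constrained non-negative by default by pinning at a small
positive floor; a pinned component is released if its score turns positive.
If a constrained fit fails to converge, an unconstrained refit is performed
and flagged — the convention used in published GREML tables whose footnotes
report negative pedigree components from unconstrained refits.

Estimates are reported as fractions of the total phenotypic variance
(including the residual), the scale on which such decompositions are
published.  Standard errors come from the inverse AI matrix propagated to
the fraction scale by the delta method.  Two tests are attached to every
component:

* **Wald**: `(estimate/SE)^2` against chi-square(1), two-sided.
* **LRT**: `2 * (lnL_full - lnL_reduced)` against the boundary mixture
  `1/2 chi2_0 + 1/2 chi2_1` appropriate for a single variance component
  whose null value lies on the parameter boundary.  A non-positive
  statistic is reported as p = 1 (no evidence; the point mass contributes
  its full half).

**Backward stepwise selection** starts from the full GKFCS model, removes
the component that fails both tests (alpha = 5%) with the largest Wald p,
and repeats until every remaining component is significant in at least one
test.  An empty final model is legal.

### A note on identifiability in two-generation cohorts

The synthetic cohorts generated here consist of founder couples, their full
sibships and unrelated singletons.  In such strictly two-generation
pedigrees the matrix identity

    F = C + 2K - 2I

holds exactly: nuclear-family pairs are spouse pairs plus parent-offspring
plus sibling pairs, and K's off-diagonal entries are exactly one half on
those last two pair types.  The full GKFCS model therefore has one flat
likelihood direction, and a trait generated with family environment only is
represented exactly by couple + pedigree components (`C = f, K = 2f`).
Which representation backward selection lands on is decided by the
optimiser's position on this ridge, not by the data.  Real multi-generation
cohorts escape the degeneracy through grandparental, avuncular and cousin
links (pairs with K > 0 outside any shared nuclear family); the
two-generation generator deliberately trades this richness for unambiguous
F/C/S definitions.  The stepwise recovery experiments are interpreted in
that light: SNP+couple and SNP+pedigree designs are identified (spouse
pairs separate K from F), while the family-only design is structurally
ambiguous at any sample size.

## Liability scale and power

For a binary trait thresholded at population prevalence `K` and observed
with sample case proportion `P`, observed-scale variance fractions are
converted to the liability scale by

    c = K^2 (1-K)^2 / (P (1-P) z^2),    z = phi(Phi^-1(1-K)),

(h2 and SE multiplied by `c`; regression coefficients and their SEs by
`sqrt(c)`, the first-order Taylor factor).  At `K = P = 0.5` the multiplier
is exactly `pi/2`.

GREML detection power uses `SE(h2) = sqrt(2 / (n^2 var_pi))` with
`var_pi = 2e-5`, the variance of genomic relatedness among unrelateds at
common-SNP panels; the non-centrality `(h2/SE)^2` is referred to the
noncentral chi-square(1) tail beyond the alpha critical value.
Case-control designs first convert the liability-scale h2 to the observed
scale with the inverse of `c`.

## Polygenic scores

Clumping is greedy by ascending p-value: the most significant unclaimed SNP
indexes a clump and removes unclaimed SNPs within ±250 kb (inclusive) with
genotypic r² > 0.1 against the reference panel; ties in p break by
(chromosome, bp).  Scores at threshold `t` are
`sum_{p_j <= t} beta_j * dosage_ij` over the clumped set, by default on the
grid 0.01, 0.02, ..., 1.00.  Strand-ambiguous (A/T, C/G) SNPs are dropped
at allele alignment; effect sizes are sign-flipped when the discovery
effect allele is the target's other allele; missing dosages are
mean-imputed.  The analysis threshold is the one whose (standardised) score
maximises incremental fixed-effect r² over the covariate-only mixed model,
ties to the smallest threshold.

Association uses the mixed model `y = Xb + beta*PRS + u + e` with
`u ~ N(0, sigma^2 K)`: variance components by REML, fixed effects by GLS,
significance by Wald's conditional F-test (F(1, n - p)).  Incremental r² is
defined on the fixed-effect scale as `(varexp_full - varexp_cov) / var(y)`
where `varexp` is the variance of the fitted fixed-effect predictor — the
published r² for such models is small and its exact definition unstated, so
this definition is fixed here and used consistently.

## GWAS and LD-score regression

`mlma_loco` is a leave-one-chromosome-out mixed-model association scan: for
each chromosome the variance components of a GRM built from all *other*
chromosomes are re-estimated, and each SNP on the chromosome is tested as a
fixed effect by GLS given those components.  This avoids proximal
contamination (the tested SNP contributing to its own correction).

LD scores are `l_j = 1 + sum_k r2_adj(j,k)` over a ±1 Mb window with the
small-sample adjustment `r2_adj = r2 - (1 - r2)/(n - 2)`.  Heritability is
the slope of the weighted regression of chi-square on `n l_j / m` with a
free intercept; weights are `1/l` sharpened once by the step-one estimate
(`1 / (l (1 + n h2 l/m)^2)`).  The cross-trait regression of `z1 z2` on
`sqrt(n1 n2) l_j / m` gives the genetic covariance; the genetic correlation
is `gencov / sqrt(h2_1 h2_2)`, clamped to [-1.25, 1.25] with a warning
outside [-1, 1].  Standard errors are delete-one block jackknives over 200
contiguous SNP blocks (fewer for small panels, minimum 20), with regression
weights frozen at their full-data values across deletions.  Cohort overlap
is assumed absent (independent discovery samples), so no shared-sample
intercept term is added.  Note the regression needs *variation* in
`n_j l_j`: with constant LD scores and equal sample sizes slope and
intercept are collinear and the fit raises an error rather than returning
an arbitrary split.

Two genetic correlations are compared with `Z = (r1 - r2) /
sqrt(se1^2 + se2^2)`; one- and two-sided p-values are both reported because
published comparisons mix the conventions.

## The synthetic-data generator

* **Pedigrees** are founder couples with sibship sizes drawn from a
  configurable distribution, plus unrelated singletons.  No remarriage,
  half-sibs, assortative mating or X chromosome.
* **Genotypes**: founder haplotypes are Bernoulli(MAF) per SNP, with
  optional within-block LD induced by a Gaussian copula with exchangeable
  correlation `ld_rho` over blocks of `ld_block_size` SNPs (blocks never
  span chromosomes).  Children inherit one allele per SNP from each parent
  independently (no recombination map); this preserves enough LD to
  exercise clumping and LD scores without a coalescent simulator.
* **Phenotypes** sum a SNP-genetic value (effects N(0,1) on standardised
  dosages of `n_causal` polymorphic SNPs), a pedigree-genetic value
  (Cholesky draw against K), one draw per nuclear family / couple / sibship
  shared by its members (non-members draw independently, keeping the unit
  diagonal), and white noise.  Each component is rescaled so its realised
  sample variance equals its specified fraction exactly — recovery
  experiments then measure estimator error rather than generator sampling
  noise.  Binary traits threshold the liability at `Phi^-1(1 - prevalence)`.
* **Summary statistics** are drawn directly from the LDSC generative model:
  `E[z1^2] = 1 + n h2 l/m`, `E[z1 z2] = rG sqrt(h2_1 h2_2) sqrt(n1 n2) l/m`
  for independent cohorts.

What the generator does **not** emulate: genotyping error and missingness
patterns, imputation uncertainty, population stratification, assortative
mating, recombination-based LD decay, and multi-generation pedigree links.
Passing recovery tests therefore demonstrate correctness of the estimators
under the model's own assumptions, not robustness to those real-data
features.

## Problem sizes and numerical choices

All experiments are sized for a single CPU core:

* Two-component (G=0.08, C=0.13) recovery: 400 couples with sibship mix
  {0: .25, 1: .25, 2: .3, 3: .2} plus 200 singletons (~1,520 individuals),
  3,000 SNPs (600 causal), 20 replicates in the test suite and 50 in the
  acceptance script.  With ~400 spouse pairs and ~310 sib pairs the
  per-replicate sampling SDs are ~0.04 for both fractions, so the replicate
  means carry Monte-Carlo SEs of ~0.005–0.009 — small against the
  generating values.
* Stepwise recovery designs use ~1,400 individuals and 1,500 SNPs; effect
  sizes (0.2–0.3) are chosen so each generating component is comfortably
  detectable at that scale.
* REML convergence: |change in lnL| < 1e-6, max 100 iterations; component
  floor 1e-8 x var(y); fixed-effect collinearity detected by QR with a
  1e-10 relative tolerance and reported by column.
* LD-score and clumping windows are inclusive; genomic coordinates are
  1-based throughout (PLINK convention).

## Known limitations

* The GKFCS ridge described above: family-only designs cannot be
  distinguished from couple+pedigree representations in two-generation
  cohorts.
* GRM-based correction in `mlma_loco` absorbs family structure only as well
  as the marker panel estimates kinship; at a few hundred SNPs a strong
  pedigree-structured signal is under-corrected.  The null-calibration
  guarantee is exact only for unstructured phenotypes.
* The LDSC block jackknife freezes regression weights across deletions; at
  very small SNP counts (< ~1,000) its SEs are rough.
* `liability_beta`'s `sqrt(c)` factor is the first-order Taylor conversion;
  it ignores covariate-induced variation in the threshold.
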