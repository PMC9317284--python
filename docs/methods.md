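# Methods

`hefam` estimates how much of the variability of quantitative traits —
plasma protein levels in the motivating application — is explained by
additive genetic effects, by household environment shared between
siblings, and by a small set of genotyped SNPs, using only pedigree
structure and trait/genotype tables from extended families.

## Model

For individual *j* in family *i*, a standardized trait is modeled as

    y_ij = b0 + b1*status_ij + b2*sex_ij + g_ij + c_ij + e_ij

with `g ~ N(0, s2G * A)`, `c ~ N(0, s2C * H)` and `e ~ N(0, s2I * I)`.
`A = 2*Phi` is the additive relationship matrix from the kinship
recursion (`Phi_ii = (1 + Phi_fm)/2`, `Phi_ij = (Phi_fj + Phi_mj)/2`,
parents before children; inbreeding is handled by the recursion itself).
`H` has 1 on the diagonal and for pairs of full siblings sharing a
non-missing household id (half-sibling sharing is configurable and off
by default, the conservative reading of "siblings raised in the same
household"). Both matrices are block diagonal by family; unrelated
singletons are their own family and household, so their off-diagonal
entries are zero. Variance fractions are `h2 = s2G/s2T` and
`c2 = s2C/s2T` with `s2T = s2G + s2C + s2I`.

## Haseman–Elston stage

Fixed effects (intercept, disease status, sex) are removed by OLS; the
residual products `e_i * e_j` over all pairs `i <= j` (diagonal
included, so `s2I` is estimated from own-products) are regressed without
intercept on the pair design `(1(i=j), a_ij, h_ij)`. The normal
equations are 3x3 and solved in closed form; each component estimate is
a quadratic form `e' B_k e`. Negative estimates are truncated at zero
after the unconstrained solve. Aliased designs (e.g. an all-singleton
sample, where A and H coincide with I) raise an explicit
unidentifiability error.

**Fixed-effect adjustment.** Because `e = (I-P) y` for the OLS hat
matrix P, the residual products have expectation `(I-P) Sigma (I-P)`,
not `Sigma`. Regressing on the plain matrix entries therefore biases
`s2G` downward (about -0.07 on h2 at the default study scale of 20
families, ~300 individuals, three covariates). The analysis default
regresses on the entries of `(I-P) M (I-P)` for each component matrix
M, which restores unbiasedness by construction (measured mean h2 0.586
at true 0.6); `he_fit(projection=None)` keeps the plain textbook design
for comparison. An intercept-augmented pair regression was evaluated as
an alternative and removed less of the bias.

## Tail probabilities, confidence intervals, p-values

The fraction estimator satisfies `h2_hat <= t` iff
`e'(B_G - t*B_tot)e <= 0`, a weighted sum of chi-squares under a
Gaussian law for the residuals, with weights the eigenvalues of
`Sigma^1/2 (B_G - t*B_tot) Sigma^1/2` at the plug-in
`Sigma_hat = s2G*A + s2C*H + (s2I + 1e-8)*I` (projected as
`(I-P) Sigma_hat (I-P)` under the adjusted design). For the plain
design everything is block diagonal and eigenvalues are gathered per
family; the adjusted design uses the dense path.

The weighted-chi-square CDF is computed by Imhof characteristic-function
inversion (adaptive quadrature; accurate to ~1e-8), with a first-order
Lugannani–Rice saddlepoint as the fast approximation and automatic
fallback when the quadrature is unreliable or the saddlepoint equation
degenerates at the distribution mean. The saddlepoint alone was measured
at absolute errors up to ~6e-3 on random 30-dimensional instances, which
is why inversion is the default for reported probabilities; a
second-order saddlepoint correction was tried and found numerically
unstable near the mean.

Confidence limits come from a binary search on t in [0, 1] (tolerance
1e-4) for plug-in tail probability alpha/2 and 1-alpha/2, truncated to
[0, 1] — upper limits can sit at exactly 1.00. The p-value for
`h2 > 0` (analogously `c2 > 0`) is one-sided: the raw (untruncated)
fraction is referred to the upper tail of its law under a null plug-in
covariance refitted with the tested component removed from the pair
design. Across traits, p-values are Benjamini–Hochberg adjusted
(statsmodels) and traits flagged at FDR 0.05.

Measured operating characteristics at the default study conditions
(20 families of 6-26, true h2 = 0.6, c2 = 0.1): mean h2 ~0.59, mean c2
~0.12, 95% CI coverage ~0.96; type-I error of the h2 = 0 test ~0.05.

## pQTL stage

Runs on controls only (disease status could otherwise feed back into
protein levels); cases are excluded up front. Genotype QC applies, in
order: MAF >= 0.05 (strict < removal, effect allele re-oriented to the
minor allele), the exact conditional Hardy–Weinberg test at p >= 1e-4
(heterozygote-count enumeration given allele counts, computed on the
full analyzed control sample), and greedy windowed LD pruning (r2 <=
0.2, 50-SNP windows advancing by 5; within a window the lower-MAF
member of an offending pair is dropped, ties to the later position).
Window and step are conventional defaults; both are configurable.

Each surviving SNP enters a univariate mixed model with sex as covariate
and random structure `s2G*A + s2C*H + s2I*I`, fitted by REML
(L-BFGS-B on bounded variances with an analytic gradient; variance
components re-estimated per SNP model). The likelihood is evaluated
family-block-wise with batched linear algebra; V is positive definite by
construction since A and H are PSD and the residual variance is bounded
below at 1e-8. A stalled line search triggers one restart at a realistic
tolerance, and convergence is declared from the projected gradient.
Wald tests use the GLS covariance of the fixed effects.

The top 50 univariate hits (ties by |z| then position) feed
forward–backward stepwise selection at a single alpha = 1e-4 for entry
and removal; mid-path non-convergence shrinks the pool by 5 (floor 10)
and retries, mirroring the 50 -> 35 fallback the sample sizes sometimes
force. Missing dosages are mean-imputed per SNP.

**Marginal R2.** For the final multivariable fit,
`s2SNPs` is the sample variance of the joint SNP linear predictor and
`s2F` that of the remaining fixed-effect predictor (sex). The default
reports the marginal R2 with the SNP variance included in the
denominator, `R2 = s2SNPs / (s2SNPs + s2F + s2G + s2C + s2I)` — the
standard mixed-model marginal-R2 convention, under which a SNP set
built to explain 40% of unit variance is recovered at 0.40 +/- 0.05.
The variant omitting `s2SNPs` from the denominator is available
(`include_snp_variance_in_denominator=False`) for comparison with
formulations that list only the non-SNP components.

**Uncertainty.** A bias-corrected accelerated (BCA) bootstrap resamples
whole families (including singletons) with replacement, B = 1000 by
default; duplicated families enter as independent blocks so no spurious
cross-copy covariance is created. Bias correction z0 comes from the
fraction of replicates below the point estimate, acceleration from a
leave-one-family-out jackknife; intervals are clipped to [0, 1]. By
default the selected SNP set is held fixed inside the bootstrap (the
interval quantifies uncertainty of the explained fraction given the
set); `resample_selection=True` repeats the stepwise search per
replicate for honesty analyses.

## Synthetic data

The generator emulates the study design: ~20 extended three-generation
pedigrees of 6-26 members grown couple by couple, households equal to
nuclear families, sexes consistent with parenthood, disease status an
independent Bernoulli per individual (register-based ascertainment is
deliberately not modeled — the estimation machinery, not ascertainment,
is what the synthetic data must exercise). Genotypes are gene-dropped:
founder alleles Bernoulli(MAF), children inherit one uniformly chosen
allele per parent; SNPs are independent given the pedigree (no LD
simulation). Phenotypes are built on the unit-variance scale
(`s2G = h2`, `s2C = c2`, residual takes the remainder after any planted
SNP variance `sum 2p(1-p)beta^2`), via per-family matrix square roots
of A and H, then standardized like the real analysis path. All
randomness flows from one integer seed.

What passing tests on these data do **not** show: robustness to
ascertainment through affected families, to non-Gaussian trait
distributions, to LD between panel SNPs, to genotyping error, or to
household structures other than nuclear families.

## Problem sizes used in the test suite

Simulation-backed checks run at the study's stated scales: 500
replicates for h2 recovery/coverage/type-I, 100 + 50 replicates for the
explained-variance recovery and BCA coverage (B = 250), 150 replicates
for the household-confounding contrast, 20 pedigrees x 1e5 allele drops
for the kinship oracle, and 20 x 1e5-draw Monte-Carlo instances for the
tail oracle. The end-to-end pipeline property (scan -> selection -> R2
-> CI) runs at 20 replicates with B = 150 and three SNPs at 18% of
variance each, sizes chosen so the whole suite completes in minutes.

## Known limitations

- The plug-in confidence interval takes quantiles of the estimator's
  law at the fitted covariance (a parametric-bootstrap-style interval),
  not a full test inversion; measured coverage is ~0.96 at h2 = 0.6.
- BCA coverage for the explained fraction sits near 0.90 at ~80
  families; with few clusters the jackknife acceleration is noisy.
- The HWE test on the full control sample ignores relatedness, which
  inflates rejection slightly; the 1e-4 threshold makes this immaterial.
- Stepwise selection inherits the usual winner's-curse caveats; the
  default bootstrap conditions on the selected set.
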