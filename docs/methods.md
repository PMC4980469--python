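# Methods

This note documents the models, numerical choices and limitations of
`genesetgxe`.  Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## 1. Single-variant model

Every variant is tested with ordinary least squares of the continuous
outcome on an intercept, the minor-allele dosage g ∈ {0, 1, 2} (additive
model) and the covariates (child sex, age at assessment in months, four
ancestry PCs by default).  Two-sided p-values use the t distribution
with residual degrees of freedom, which matters at stratum sizes in the
hundreds.  Missing genotypes are handled by per-variant casewise
deletion, matching common GWAS-tool behaviour; mean imputation is not
used for inference.  A variant that is constant on its complete cases
("monomorphic in stratum") has no defined p and is excluded from the set
statistic — consistently in the observed data and in every permutation,
since monomorphism is a property of the genotypes, not of the phenotype
shuffle.

The permutation engine computes the dosage-term t statistic through the
Frisch–Waugh–Lovell identity: one QR factorisation of the covariate
block serves every variant and every permuted phenotype, so each
permutation reduces to two matrix products.  Unit tests verify agreement
with a fresh full-design OLS (statsmodels) to ~1e-10 relative error,
including the casewise-deletion path.

## 2. Set statistic and permutation scheme

The gene or gene-set statistic is T = Σ −log₁₀ pᵢ over the member
variants (distinct variants when genes overlap, as at the
DRD2/ANKK1-style adjacency).  The null distribution comes from
permutations of the raw phenotype vector across samples; genotypes and
covariates stay attached to samples, so LD and the set's size structure
are preserved exactly.  The empirical p is the plain fraction
#{T\* ≥ T}/n_perm (default n_perm = 9000); the (hits+1)/(B+1)
small-sample correction is available behind a `correction` flag but is
off by default for fidelity to the reference procedure.  Parametric
p-values are floored at 1e-300 before the logarithm.

Permuting the raw phenotype also breaks any phenotype–covariate
association; a Freedman–Lane variant (permute covariate-adjusted
residuals, add back the fitted part) is available via
`method="freedman_lane"` for covariate-preserving inference.  One
permutation stream is shared by the whole set and all genes in a run, so
per-gene and set-level p-values are mutually consistent and a seed fully
reproduces the analysis.

The competitive test draws `n_random` (default 150) gene-sets matched on
gene count, without replacement within a set, from the non-focal gene
universe, computes each one's self-contained p on a shared permutation
stream, and reports the fraction with a self-contained p below the focal
one.  Matching is on gene count only, as in the reference procedure;
because T scales with variant count, variant-rich random sets are not
penalised — a documented caveat of that design.

## 3. Effect sizes and the stratum contrast

Permutation tests produce no coefficient, so stratum effect sizes are
recovered from (p, n): z = Φ⁻¹(1 − p/2), d = 2z/√n,
se = √(4/n + d²/2n), CI = d ± 1.96·se.  This normal-deviate, one-group
form reproduces published 2-dp d values from their printed (p, n) pairs
(verified in the acceptance tests for p ∈ {0.0250, 0.97, 0.05, 0.0040,
0.10}).  The conversion is sign-free — permutation p-values carry no
direction — and the CI is computed from the unrounded d.  An empirical p
of exactly 0 is floored at 1/n_perm before conversion.

Strata are compared with the fixed-effect heterogeneity statistic
Q = (d₁ − d₂)²/(se₁² + se₂²) with a χ²₁ upper-tail p.  This is the
standard convention; it is symmetric in the strata and zero iff the two
d values coincide.

## 4. Quality control

Defaults: sample call rate ≥ 0.95; MAF ≥ 0.01; variant call rate
≥ 0.98; Hardy–Weinberg exact-test p ≥ 1e-6; PC outliers beyond 4 SD on
any of the first 4 PCs; differential missingness between genotyping
batches at Fisher-exact p < 1e-5 (the reference protocol states the
filter but no cutoff; it is configurable and logged).  Order of
application: sample call-rate filter, then PC outliers, then variant
filters recomputed on the retained samples.  QC is idempotent and every
exclusion is logged with stage, reason and value.

The HWE test is the exact conditional test on heterozygote counts
(recurrence seeded at the conditional mode), standard for GWAS QC and
well defined at low MAF; it is validated against an exact-rational
enumeration oracle for n ≤ 50.  Because the exact test is discrete and
conservative, calibration is checked with randomized p-values
(p_strict + U·(p − p_strict)), which are exactly Uniform(0,1) under the
null; the plain p is additionally checked for superuniformity.

Ancestry PCs come from the SVD of the genotype matrix with each variant
mean-imputed and standardized by √(2p(1−p)).  PC-space outlier removal
stands in for reference-anchored IBS clustering when no external
reference panel is used — a documented deviation.  A genotype-derived
sex check is omitted (no sex chromosomes are modelled).

## 5. Annotation and multiple testing

Coordinates are 1-based with both transcription boundaries inclusive
(NCBI convention); no flanking regions by default; strand never affects
membership; gene aliases resolve by exact case-insensitive match.
Manually genotyped polymorphisms (e.g. a 48-bp VNTR coded additively)
can be appended to the genotype matrix and a gene's membership.

Gene-level effective test counts use single-linkage clustering of genes
whose closest transcription boundaries are less than 5 Mb apart
(overlap = gap 0); the gap is measured between boundaries, not
midpoints, and chaining is allowed — both choices are fixed here because
the reference procedure specifies neither.  Applied to the shipped
dopamine annotation this rule yields 10 clusters for the 12
variant-bearing genes; the historically used count of six is not
self-evidently derivable from the printed coordinates under any boundary
or midpoint rule, so the computed count is reported as such and the
Bonferroni arithmetic (0.05/6 = 0.0083, 0.05/49 = 0.0010) is exposed as
plain functions of (α, m).

SNP-level counts use sliding-window LD pruning: windows of 50 variants
advancing by 5, removing from the worst-correlated pair (r² > 0.20) the
lower-MAF member, ties broken against the later position — fixed here
because the reference tool's internal choice is version-dependent.  The
output provably satisfies the r² ceiling for all retained within-window
pairs.

## 6. Exposure and outcome scoring

Six discipline items per parent on a 0–5 frequency scale are collapsed
to {0, 1, 2} (categories ≥ 2 merged, reflecting their low prevalence);
the high-prevalence "shouted or screamed" item is dropped; the remaining
five are summed (0–10) and the exposure dichotomy is harsh iff the sum
is ≥ 1.  Any missing retained item leaves the assignment undefined and
the child is excluded from that parent's analysis.  Pooled exposure is
harsh if either parent's dichotomy is harsh.

Missing main-wave externalizing scores are completed by regression
imputation on the 18- and 36-month scores (both predictors when present,
a single-predictor model otherwise); children with no observed predictor
wave are dropped.

## 7. The synthetic cohort generator

The generator provides fully self-contained data with the statistical
structure the analysis assumes.  Defaults mirror the emulated study
conditions: 1710 children, 151 variants in 12 genes, exposure
prevalences 0.349 (father) and 0.358 (mother), cross-parent φ target
0.27, 6.6% missing outcomes, wave correlation 0.5.

*Genotypes* — within a block of `ld_block_size` variants each haplotype
draws a latent normal vector with exchangeable correlation `ld_rho`,
thresholded at the MAF quantile (MAF ~ U(maf_range)); the two haplotypes
are independent, so HWE holds in expectation by construction.  This
latent-Gaussian block model is deliberately simple — parameter-
transparent and sufficient to exercise LD pruning and permutation
validity — and is *not* a coalescent: it does not reproduce realistic
human LD decay, allele-frequency spectra, or recombination maps, and
blocks may span gene boundaries.  Conclusions from passing tests
therefore concern the statistical machinery, not population-genetic
realism.

*Exposures* — a family factor F is shared by the two parents' liability
scores (loading a), and six items load on each parent's liability with a
common loading of 0.7, thresholded into {0, 1, 2}.  Item thresholds are
calibrated by root finding (Gauss–Hermite quadrature, 61 nodes) to hit
the per-parent dichotomy prevalence, and the family loading a is
calibrated the same way to hit the target φ between the parents'
dichotomies; φ is monotone in a, and unreachable targets raise an error.

*Phenotype* — outcome = covariate effects + Σ gⱼ·(β_noexp·(1−E) +
β_exp·E) + exposure main effect (0.45 SD default, matching the observed
group difference) + unit Gaussian noise, on a standardized continuous
scale.  The item-level CBCL distribution is not modelled; the
externalizing sum is generated directly, so the non-negativity of a real
CBCL sum does not apply to the synthetic score.  Earlier waves are
noisy correlates (r ≈ 0.5) of the main-wave score so that regression
imputation is meaningfully testable; outcome missingness is completely
at random (informative missingness is out of scope).

## 8. Pipeline and reproducibility

`StratifiedGxEAnalysis.fit()` runs: QC → PCs → annotation → harsh
scoring for the chosen parent → one-child-per-family selection (seeded)
→ imputation → self-contained set and gene tests in the total, no-harsh
and harsh groups → competitive test where a self-contained p < 0.05 →
p-to-d conversion and heterogeneity contrast per unit → SNP-level
interaction regressions on the total group → allele-frequency rGE check
→ multiple-testing plans → report.  All stage seeds derive from the run
seed in a fixed order and are recorded in the manifest; rerunning with
the same inputs and seed reproduces the report bitwise.  Any stage
failure aborts with the stage name and a machine-readable reason.

## 9. Problem sizes in the test and acceptance runs

Simulation-based checks use desk-scale sizes chosen to give stable
statistics at interactive runtimes: type-I calibration uses 200 null
cohorts of n = 500 with 200 variants and 999 permutations; pattern
recovery uses 50 replicate cohorts of n = 800 with ten causal SNPs
(β = 0.25) active only in the no-exposure stratum; the exhaustive oracle
enumerates all 8! phenotype orderings at n = 8.  One caveat is inherent
to the pattern design: the exposed stratum is an exact null there, so
its empirical p is uniform and single replicates land below 0.5 about
half the time; the stable signatures — majority significance off
exposure, majority non-significance with exposure, central median p —
are what the tests assert, and the per-replicate strict pattern fraction
is reported alongside by the acceptance script.

## 10. Known limitations

Linear models only (no logistic/ordinal outcomes, mixed models or
robust errors); no relatedness estimation or imputation to reference
panels; no X-chromosome handling (the emulated gene-set is autosomal);
competitive sets matched on gene count only by default; the synthetic
LD model is exchangeable within blocks rather than distance-decaying.
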