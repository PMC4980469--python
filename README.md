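# genesetgxe

Stratified gene-set gene-by-environment (G×E) association testing for
continuous behavioural outcomes, with permutation empirical p-values.

Developmental-genetics studies often ask whether aggregated genetic
variation across a set of functionally related genes (for example the
dopaminergic genes `DRD1..DRD5`, `DAT`, `VMAT1/2`, `TH`, `DDC`, `COMT`,
`DBH`, `ANKK1`) predicts a child-behaviour phenotype such as the CBCL
externalizing score — and whether that association depends on an
environmental exposure such as harsh parenting.  Single-SNP G×E scans are
underpowered at cohort scale; this package implements the gene-set
alternative: run self-contained permutation tests of the whole set and of
each gene *separately in exposure strata*, convert the stratum p-values
into effect sizes, and contrast them.

## The statistics

For a variant set *S* with single-variant additive-model p-values
*p₁ … p_m* (OLS of the outcome on minor-allele dosage plus covariates),
the set statistic is

    T = Σᵢ −log₁₀ pᵢ .

**Self-contained test** — the phenotype vector is permuted across samples
(genotypes, covariates and hence LD stay fixed), all member variants are
refitted, and the empirical p-value is the fraction of at-least-9000
permuted statistics with T\* ≥ T.

**Competitive test** — triggered when a self-contained p is below 0.05:
150 random gene-sets matched on gene count are drawn from the remaining
gene universe, each gets its own self-contained p, and the competitive
p-value is the fraction of random sets with a smaller self-contained p.

**Indirect G×E test** — each stratum's empirical p and sample size are
converted to Cohen's *d* via the normal deviate, *z* = Φ⁻¹(1 − p/2),
*d* = 2z/√n, se(*d*) = √(4/n + d²/2n), and strata are compared with the
fixed-effect heterogeneity statistic Q = (d₁ − d₂)²/(se₁² + se₂²) ~ χ²₁.

Supporting machinery: GWAS-style QC (call rates, MAF, exact
Hardy–Weinberg test, differential missingness, PC-outlier removal),
transcription-boundary SNP-to-gene annotation with manual-variant
injection (e.g. a VNTR typed off-array), LD pruning
(`--indep-pairwise 50 5 0.20` semantics) and 5-Mb gene clustering for
Bonferroni thresholds, plus a fully self-contained synthetic cohort
generator for validation.

## Worked example

```python
import genesetgxe as gg

config = gg.SimConfig(
    n_samples=800, n_variants=120, n_genes=24, seed=11,
    effect_snps=tuple((f"snp{j:05d}", 0.25, 0.0) for j in range(1, 11)),
)
cohort = gg.simulate_cohort(config)          # signal only without exposure
options = gg.AnalysisOptions(
    parent="father", n_perm=999, n_random_sets=150, seed=5,
    focal_genes=tuple(f"GENE{k:03d}" for k in range(1, 7)),
)
results = gg.run_stratified_analysis(cohort, options)
print(results.summary())
```

```
Stratified gene-set G x E analysis
  parent: father   permutations: 999   seed: 5
  samples: total=800, no_harsh=481, harsh=319
  gene-set: 6 genes with variants, 30 distinct variants
  set p (   total) = 0.0000   d = 0.23 [0.09, 0.37]
  set p (no_harsh) = 0.0000   d = 0.30 [0.12, 0.48]
  set p (   harsh) = 0.8368   d = 0.02 [-0.20, 0.24]
  competitive p (total) = 0.0000 (150 random sets)
  competitive p (no_harsh) = 0.0000 (150 random sets)
  stratum contrast: Q(1) = 3.66, p = 0.06
  gene-level threshold: alpha = 0.0083 (6 effective tests)
  snp-level threshold: alpha = 0.0017 (30 effective tests)
  SNP-level G x E: 9 of 30 interactions significant after correction
  rGE check: min allele-frequency-difference p = 0.0132 over 30 variants
```

The cohort was generated with ten causal SNPs active only in the
no-exposure stratum, and the report recovers exactly that signature: a
tiny self-contained (and competitive) p without harsh parenting with
*d* ≈ 0.3, a null result (p = 0.84, *d* ≈ 0) with harsh parenting, and a
borderline heterogeneity contrast — the set-level association is
environment-dependent, and 9 of the 30 member variants additionally show
individually significant interaction coefficients at the SNP-level
Bonferroni threshold.  `results.save("outdir")` writes the per-unit report,
per-stratum test tables, SNP interaction and allele-frequency (rGE)
tables and a JSON manifest that suffices to reproduce every number.

The same pipeline is scriptable from the shell:

```bash
genesetgxe simulate --seed 2 --out cohort
genesetgxe run-all --bfile cohort --parent father --n-perm 9000 \
    --n-random-sets 150 --seed 7 --out results/
```

Real data enter as PLINK `.bed/.bim/.fam` plus TSV phenotype, covariate
and exposure tables keyed by `IID`, with a gene annotation table
(`gene, chrom, tss, tes, strand`).  `genesetgxe.dopamine_gene_table()`
ships the 14-gene dopamine annotation (GRCh37 transcription boundaries).

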