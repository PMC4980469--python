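"""Synthetic cohort generator for stratified gene-set G x E analyses.

The generator emulates the data structure of a population-based birth
cohort: LD-structured diallelic genotypes in Hardy-Weinberg equilibrium,
six ordinal harsh-discipline items per parent with a calibrated
cross-parent association (phi), standard covariates (sex, age at
assessment, four ancestry PCs) and a continuous externalizing score whose
genetic component may differ between exposure strata.  Earlier assessment
waves and completely-at-random outcome missingness are included so that
regression imputation is exercised end to end.

LD model: within a block of ``ld_block_size`` consecutive variants, each
haplotype draws a latent standard-normal vector with exchangeable
correlation ``ld_rho``; alleles are the latent values thresholded at the
MAF quantile.  Haplotypes are independent within and between samples
(random mating), so HWE holds in expectation at every variant.

Exposure model: per family a shared latent factor F; each parent's
liability is ``a*F + sqrt(1-a^2)*eta`` and the six items load on the
parent liability with a common loading, thresholded into {0,1,2}.  The
shared-factor loading ``a`` is calibrated numerically (Gauss-Hermite
quadrature + root finding) so that the phi coefficient between the two
parents' harsh/no-harsh dichotomies hits ``parent_phi_target``.
"""

from __future__ import annotations

import dataclasses
import io
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datasets import GenotypeDataset, write_plink

#: 0-based position of the high-prevalence "shouted or screamed" item,
#: which is dropped from the harsh-parenting sum score downstream.
SHOUTED_INDEX = 1

_N_ITEMS = 6
_N_RETAINED = 5


@dataclasses.dataclass
class SimConfig:
    """Generating parameters of a synthetic cohort.

    Defaults mirror the study conditions the generator emulates: 1710
    children (the paternal-report analysis sample), 151 variants in 12
    genes, ~35% exposure prevalence per parent, cross-parent phi of 0.27
    and 6.6% missing outcome scores.
    """

    n_samples: int = 1710
    n_variants: int = 151
    ld_block_size: int = 10
    ld_rho: float = 0.5
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_genes: int = 12
    effect_snps: tuple[tuple[str, float, float], ...] = ()
    exposure_prevalence_father: float = 0.349
    exposure_prevalence_mother: float = 0.358
    parent_phi_target: float = 0.27
    covariate_effects: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"sex": 0.15, "age_at_cbcl": 0.0}
    )
    exposure_main_effect: float = 0.45
    effect_parent: str = "father"
    wave_correlation: float = 0.5
    missing_outcome_rate: float = 0.066
    noise_sd: float = 1.0
    shouted_prevalence: float = 0.55
    item_loading: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        low, high = self.maf_range
        if not (0.0 < low <= high <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must lie in [0, 1)")
        for name in (
            "exposure_prevalence_father",
            "exposure_prevalence_mother",
            "missing_outcome_rate",
            "shouted_prevalence",
        ):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must be a probability, got {value}")
        if not (0.0 <= self.parent_phi_target < 1.0):
            raise ValueError("parent_phi_target must lie in [0, 1)")
        if self.n_samples < 1 or self.n_variants < 1 or self.n_genes < 1:
            raise ValueError("counts must be positive")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        if not (0.0 < self.item_loading < 1.0):
            raise ValueError("item_loading must lie in (0, 1)")
        if self.effect_parent not in ("father", "mother"):
            raise ValueError("effect_parent must be 'father' or 'mother'")


@dataclasses.dataclass
class SyntheticCohort:
    """A fully self-contained simulated cohort.

    All tables are keyed by the same ``iid`` sample identifiers as the
    genotype roster; ``truth`` records the generating parameters.
    """

    genotypes: GenotypeDataset
    phenotypes: pd.DataFrame
    exposures: pd.DataFrame
    genes: pd.DataFrame
    truth: dict

    def __post_init__(self) -> None:
        ids = self.genotypes.samples["iid"].to_numpy()
        for name in ("phenotypes", "exposures"):
            table = getattr(self, name)
            if not np.array_equal(table["iid"].to_numpy(), ids):
                raise ValueError(f"{name} table is not aligned with the sample roster")


# ---------------------------------------------------------------------------
# gene / variant layout
# ---------------------------------------------------------------------------

def gene_map(config: SimConfig) -> pd.DataFrame:
    """Deterministic gene layout: contiguous genes tiling the variants.

    Genes cycle over autosomes 1..22; successive genes on the same
    chromosome are spaced 20 Mb apart so they are independent under a 5 Mb
    clustering rule unless deliberately constructed otherwise.
    """
    per_gene = np.full(config.n_genes, config.n_variants // config.n_genes)
    per_gene[: config.n_variants % config.n_genes] += 1
    rows = []
    j = 0
    for g, nv in enumerate(per_gene):
        chrom = (g % 22) + 1
        k = g // 22
        tss = 1_000_000 + k * 20_000_000
        positions = tss + 500 + 2_000 * np.arange(nv)
        tes = int(positions[-1]) + 500 if nv else tss + 1_000
        rows.append(
            {
                "gene": f"GENE{g + 1:03d}",
                "chrom": chrom,
                "tss": int(tss),
                "tes": int(tes),
                "strand": "+" if g % 2 == 0 else "-",
                "first_variant": j,
                "n_variants": int(nv),
            }
        )
        j += nv
    return pd.DataFrame(rows)


def simulate_genotypes(config: SimConfig, rng: np.random.Generator | None = None) -> GenotypeDataset:
    """Draw HWE genotypes with exchangeable latent-Gaussian LD blocks."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n, m = config.n_samples, config.n_variants
    maf = rng.uniform(*config.maf_range, size=m)
    thresholds = stats.norm.ppf(maf)

    rho = config.ld_rho
    alleles = np.empty((n, 2, m), dtype=np.int8)
    for start in range(0, m, config.ld_block_size):
        stop = min(start + config.ld_block_size, m)
        width = stop - start
        shared = rng.standard_normal((n, 2, 1))
        noise = rng.standard_normal((n, 2, width))
        z = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * noise
        alleles[:, :, start:stop] = z < thresholds[start:stop]
    genotypes = alleles.sum(axis=1).astype(float)

    genes = gene_map(config)
    positions = np.empty(m, dtype=int)
    chroms = np.empty(m, dtype=int)
    for row in genes.itertuples():
        sl = slice(row.first_variant, row.first_variant + row.n_variants)
        positions[sl] = row.tss + 500 + 2_000 * np.arange(row.n_variants)
        chroms[sl] = row.chrom
    variants = pd.DataFrame(
        {
            "variant_id": [f"snp{j + 1:05d}" for j in range(m)],
            "chrom": chroms,
            "pos": positions,
            "a1": "A",
            "a2": "G",
        }
    )
    samples = pd.DataFrame(
        {
            "fid": [f"F{i + 1:06d}" for i in range(n)],
            "iid": [f"S{i + 1:06d}" for i in range(n)],
        }
    )
    return GenotypeDataset(genotypes, variants, samples)


# ---------------------------------------------------------------------------
# exposure model and its numerical calibration
# ---------------------------------------------------------------------------

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(61)
_GH_WEIGHTS = _GH_WEIGHTS / np.sqrt(2.0 * np.pi)  # E[h(Z)] = sum w*h(x)


def _p_all_zero_given_liability(tau: float, b: float, liability: np.ndarray, k: int) -> np.ndarray:
    """P(all k items score 0 | parent liability), items conditionally iid."""
    scale = np.sqrt(1.0 - b * b)
    return stats.norm.cdf((tau - b * liability) / scale) ** k


def _marginal_prevalence(tau: float, b: float, k: int) -> float:
    """P(at least one of k items >= 1) marginally over the liability."""
    q = _p_all_zero_given_liability(tau, b, _GH_NODES, k)
    return 1.0 - float(np.sum(_GH_WEIGHTS * q))


def _calibrate_threshold(prevalence: float, b: float, k: int) -> float:
    """Item threshold giving the target any-item prevalence."""
    if prevalence <= 0.0:
        return np.inf
    if prevalence >= 1.0:
        return -np.inf
    return float(
        optimize.brentq(lambda t: _marginal_prevalence(t, b, k) - prevalence, -12.0, 12.0)
    )


def _p_all_zero_given_family(tau: float, b: float, a: float, f: np.ndarray, k: int) -> np.ndarray:
    """P(parent dichotomy = 0 | family factor F=f), via quadrature over eta."""
    if np.isinf(tau):
        return np.ones_like(f) if tau > 0 else np.zeros_like(f)
    s = np.sqrt(1.0 - a * a)
    liab = a * f[:, None] + s * _GH_NODES[None, :]
    q = _p_all_zero_given_liability(tau, b, liab, k)
    return q @ _GH_WEIGHTS


def _phi_for_loading(a: float, tau_f: float, tau_m: float, b: float, k: int) -> float:
    """phi between the two parents' dichotomies for shared-factor loading a."""
    qf = _p_all_zero_given_family(tau_f, b, a, _GH_NODES, k)
    qm = _p_all_zero_given_family(tau_m, b, a, _GH_NODES, k)
    p0f = float(np.sum(_GH_WEIGHTS * qf))
    p0m = float(np.sum(_GH_WEIGHTS * qm))
    p00 = float(np.sum(_GH_WEIGHTS * qf * qm))
    pf, pm = 1.0 - p0f, 1.0 - p0m
    p11 = 1.0 - p0f - p0m + p00
    denom = np.sqrt(pf * (1.0 - pf) * pm * (1.0 - pm))
    if denom == 0.0:
        return 0.0
    return (p11 - pf * pm) / denom


def _calibrate_family_loading(config: SimConfig, tau_f: float, tau_m: float) -> float:
    target = config.parent_phi_target
    if target <= 0.0 or np.isinf(tau_f) or np.isinf(tau_m):
        return 0.0
    b, k = config.item_loading, _N_RETAINED
    hi = 0.999
    phi_max = _phi_for_loading(hi, tau_f, tau_m, b, k)
    if target >= phi_max:
        raise ValueError(
            f"parent_phi_target={target} unreachable; maximum under this item "
            f"model is {phi_max:.3f}"
        )
    return float(
        optimize.brentq(
            lambda a: _phi_for_loading(a, tau_f, tau_m, b, k) - target, 0.0, hi
        )
    )


def _draw_items(
    rng: np.random.Generator,
    liability: np.ndarray,
    tau1: float,
    tau_shouted: float,
    b: float,
) -> np.ndarray:
    """Six ordinal items in {0,1,2}; the shouted item has its own threshold."""
    n = liability.shape[0]
    scale = np.sqrt(1.0 - b * b)
    u = b * liability[:, None] + scale * rng.standard_normal((n, _N_ITEMS))
    tau_once = np.full(_N_ITEMS, tau1)
    tau_once[SHOUTED_INDEX] = tau_shouted
    tau_twice = tau_once + 0.7  # "twice or more" is rarer than "once"
    return ((u > tau_once).astype(np.int8) + (u > tau_twice).astype(np.int8))


def simulate_exposures(config: SimConfig, n: int, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Six ordinal harsh-discipline items per parent, phi-calibrated.

    Columns ``father_item1..6`` / ``mother_item1..6`` on {0,1,2}; item
    ``SHOUTED_INDEX+1`` is the high-prevalence shouted/screamed item that
    the downstream sum score drops.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    b = config.item_loading
    tau_f = _calibrate_threshold(config.exposure_prevalence_father, b, _N_RETAINED)
    tau_m = _calibrate_threshold(config.exposure_prevalence_mother, b, _N_RETAINED)
    tau_sh = _calibrate_threshold(config.shouted_prevalence, b, 1)
    a = _calibrate_family_loading(config, tau_f, tau_m)

    family = rng.standard_normal(n)
    s = np.sqrt(1.0 - a * a)
    liab_f = a * family + s * rng.standard_normal(n)
    liab_m = a * family + s * rng.standard_normal(n)
    items_f = _draw_items(rng, liab_f, tau_f, tau_sh, b)
    items_m = _draw_items(rng, liab_m, tau_m, tau_sh, b)

    data = {}
    for j in range(_N_ITEMS):
        data[f"father_item{j + 1}"] = items_f[:, j]
    for j in range(_N_ITEMS):
        data[f"mother_item{j + 1}"] = items_m[:, j]
    return pd.DataFrame(data)


def harsh_dichotomy(exposures: pd.DataFrame, parent: str) -> np.ndarray:
    """1 if any retained item (shouted/screamed excluded) >= 1, else 0."""
    cols = [
        f"{parent}_item{j + 1}" for j in range(_N_ITEMS) if j != SHOUTED_INDEX
    ]
    return (exposures[cols].to_numpy().sum(axis=1) >= 1).astype(int)


# ---------------------------------------------------------------------------
# covariates and phenotype
# ---------------------------------------------------------------------------

def simulate_covariates(config: SimConfig, n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Sex, age at assessment (months) and four stand-in ancestry PCs."""
    return pd.DataFrame(
        {
            "sex": rng.integers(0, 2, size=n),
            "age_at_cbcl": rng.normal(71.2, 3.7, size=n),
            **{f"PC{k}": rng.standard_normal(n) for k in range(1, 5)},
        }
    )


def simulate_phenotype(
    config: SimConfig,
    genotypes: GenotypeDataset,
    exposures: pd.DataFrame,
    covariates: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Externalizing score with optional stratum-specific genetic effects.

    outcome = covariate effects + sum_j g_j * (beta_noexp*(1-E) + beta_exp*E)
              + exposure main effect + Gaussian noise,
    where E is the harsh-parenting dichotomy of ``config.effect_parent``.
    Earlier waves (18 and 36 months) are noisy correlates of the age-5
    score; ``missing_outcome_rate`` of age-5 scores are set missing
    completely at random.  The score is on a standardized continuous scale.
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    n = genotypes.n_samples
    exposure = harsh_dichotomy(exposures, config.effect_parent).astype(float)

    y = rng.normal(0.0, config.noise_sd, size=n)
    y += config.exposure_main_effect * exposure
    for name, beta in dict(config.covariate_effects).items():
        if name not in covariates.columns:
            raise ValueError(f"unknown covariate in covariate_effects: {name!r}")
        col = covariates[name].to_numpy(dtype=float)
        y += beta * (col - col.mean())
    for variant_id, beta_noexp, beta_exp in config.effect_snps:
        try:
            g = genotypes.dosage(variant_id)
        except KeyError:
            raise ValueError(f"effect_snps references unknown variant {variant_id!r}")
        g = np.nan_to_num(g, nan=float(np.nanmean(g)))
        y += g * (beta_noexp * (1.0 - exposure) + beta_exp * exposure)

    y_std = (y - y.mean()) / y.std()
    r = config.wave_correlation
    w18 = r * y_std + np.sqrt(1.0 - r * r) * rng.standard_normal(n)
    w36 = r * y_std + np.sqrt(1.0 - r * r) * rng.standard_normal(n)

    age5 = y.copy()
    n_missing = int(round(config.missing_outcome_rate * n))
    if n_missing:
        age5[rng.choice(n, size=n_missing, replace=False)] = np.nan

    return pd.DataFrame(
        {
            "externalizing_age5": age5,
            "externalizing_18m": w18,
            "externalizing_36m": w36,
        }
    )


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate a complete cohort; a fixed seed reproduces it bitwise."""
    rng = np.random.default_rng(config.seed)
    genotypes = simulate_genotypes(config, rng)
    n = genotypes.n_samples
    exposures = simulate_exposures(config, n, rng)
    covariates = simulate_covariates(config, n, rng)
    waves = simulate_phenotype(config, genotypes, exposures, covariates, rng)

    ids = genotypes.samples["iid"].reset_index(drop=True)
    phenotypes = pd.concat([ids, waves, covariates], axis=1)
    exposures = pd.concat([ids, exposures], axis=1)
    truth = {
        "config": dataclasses.asdict(config),
        "father_harsh": harsh_dichotomy(exposures, "father"),
        "mother_harsh": harsh_dichotomy(exposures, "mother"),
    }
    return SyntheticCohort(genotypes, phenotypes, exposures, gene_map(config), truth)


# ---------------------------------------------------------------------------
# dopamine gene-set fixture (published coordinates, GRCh37)
# ---------------------------------------------------------------------------

_DOPAMINE_TABLE = """\
gene	alias	entrez_id	chrom	tss	tes	strand	n_snps_array
DRD1		1812	5	174867675	174871163	-	2
DRD2		1813	11	113280317	113346001	-	15
DRD3		1814	3	113847557	113897899	-	12
DRD4		1815	11	637305	640706	+	0
DRD5		1816	4	9783258	9785633	+	0
DAT	SLC6A3,DAT1	6531	5	1392905	1445543	-	13
VMAT1	SLC18A1	6570	8	20002366	20040717	-	20
VMAT2	SLC18A2	6571	10	119000584	119038941	+	18
TH		7054	11	2185159	2193035	-	2
DDC		1644	7	50526134	50633154	-	32
COMT		1312	22	19929263	19957498	+	14
DARPP-32	PP1R1B	84152	17	37783177	37792878	+	0
DBH		1621	9	136501485	136524466	+	17
ANKK1		255239	11	113258513	113271140	+	5
"""


def dopamine_gene_table() -> tuple[pd.DataFrame, pd.Series]:
    """The 14-gene dopamine annotation (GRCh37) and per-gene SNP counts.

    Returns the gene table (name, alias, chromosome, transcription
    start/end, strand) and the number of array-genotyped SNPs per gene.
    DRD4 has no array SNPs but carries one manually genotyped 48-bp VNTR
    in the analysed gene-set; DRD5 and DARPP-32 have no variants at all.
    """
    table = pd.read_csv(io.StringIO(_DOPAMINE_TABLE), sep="\t", keep_default_na=False)
    counts = pd.Series(
        table["n_snps_array"].to_numpy(), index=table["gene"].to_numpy(), name="n_variants"
    )
    return table, counts


def dopamine_synthetic_variants(seed: int = 0) -> pd.DataFrame:
    """Synthetic variant map matching the published per-gene SNP counts.

    Real rs positions are not reproduced; positions are placed uniformly
    inside each gene's transcription boundaries so that boundary mapping
    recovers the printed counts exactly.
    """
    table, counts = dopamine_gene_table()
    rng = np.random.default_rng(seed)
    rows = []
    j = 0
    for rec in table.itertuples():
        nv = int(rec.n_snps_array)
        if nv == 0:
            continue
        positions = np.sort(
            rng.choice(np.arange(rec.tss, rec.tes + 1), size=nv, replace=False)
        )
        for pos in positions:
            j += 1
            rows.append(
                {
                    "variant_id": f"rsynth{j:04d}",
                    "chrom": int(rec.chrom),
                    "pos": int(pos),
                    "a1": "A",
                    "a2": "G",
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# on-disk export
# ---------------------------------------------------------------------------

def write_plink_dataset(cohort: SyntheticCohort, prefix) -> dict:
    """Write the cohort as PLINK binary plus TSV phenotype/exposure tables.

    Emits ``prefix``.bed/.bim/.fam (see :func:`genesetgxe.datasets.write_plink`)
    and ``prefix``.phenotypes.tsv / .exposures.tsv / .covariates.tsv /
    .genes.tsv keyed by the sample ID column ``IID``.
    """
    if cohort.genotypes.n_samples == 0 or cohort.genotypes.n_variants == 0:
        raise ValueError("refusing to write an empty cohort")
    prefix = Path(prefix)
    paths = write_plink(cohort.genotypes, prefix)

    pheno_cols = ["externalizing_age5", "externalizing_18m", "externalizing_36m"]
    covar_cols = ["sex", "age_at_cbcl", "PC1", "PC2", "PC3", "PC4"]

    def _dump(df: pd.DataFrame, suffix: str) -> Path:
        path = prefix.with_suffix(suffix)
        df.rename(columns={"iid": "IID"}).to_csv(path, sep="\t", index=False)
        return path

    paths["phenotypes"] = _dump(cohort.phenotypes[["iid"] + pheno_cols], ".phenotypes.tsv")
    paths["covariates"] = _dump(cohort.phenotypes[["iid"] + covar_cols], ".covariates.tsv")
    paths["exposures"] = _dump(cohort.exposures, ".exposures.tsv")
    genes_path = prefix.with_suffix(".genes.tsv")
    cohort.genes.to_csv(genes_path, sep="\t", index=False)
    paths["genes"] = genes_path
    return paths
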