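"""Sample- and variant-level genotype quality control and ancestry PCs.

Filters follow standard GWAS practice: sample call rate, PC-space ancestry
outliers, minor allele frequency, variant call rate, an exact
Hardy-Weinberg test and differential missingness between genotyping
batches.  Filters are applied in a fixed order (samples, then PC outliers,
then variant filters recomputed on the retained samples) and every
exclusion is logged with its reason and offending value.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import GenotypeDataset


@dataclasses.dataclass
class QCThresholds:
    """Default thresholds of the reference QC protocol."""

    sample_call_rate: float = 0.95
    maf: float = 0.01
    variant_call_rate: float = 0.98
    hwe_p: float = 1e-6
    pc_outlier_sd: float = 4.0
    n_pcs: int = 4
    batch_missingness_p: float = 1e-5


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(
    n_het: int, n_hom_rare: int, n_hom_common: int, with_strict: bool = False
):
    """Exact conditional HWE test p-value from genotype counts.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts no more likely than the observed one (the
    standard two-sided exact test used in GWAS QC).

    With ``with_strict=True`` also returns the strictly-less-likely tail
    mass, so callers can form the randomized p-value
    ``p_strict + U*(p - p_strict)`` which is exactly Uniform(0,1) under
    the null — the appropriate object for calibration checks, since the
    plain exact p is discrete and conservative (superuniform).
    """
    if min(n_het, n_hom_rare, n_hom_common) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_het + n_hom_rare + n_hom_common
    if n == 0:
        return (np.nan, np.nan) if with_strict else np.nan
    rare = 2 * min(n_hom_rare, n_hom_common) + n_het
    # heterozygote counts share the parity of the rare-allele count
    het_values = np.arange(rare % 2, rare + 1, 2)
    het_values = het_values[(rare - het_values) // 2 + het_values <= n]

    # unnormalised probabilities via the recurrence
    # P(h+2)/P(h) = 4*hom_r(h)*hom_c(h) / ((h+2)*(h+1)),
    # seeded at the conditional mode to keep the ratios in range
    probs = np.zeros(het_values.shape[0])
    expected = rare * (2 * n - rare) / (2.0 * n)
    mid = int(np.clip(np.argmin(np.abs(het_values - expected)), 0, het_values.shape[0] - 1))
    probs[mid] = 1.0
    for i in range(mid, het_values.shape[0] - 1):
        h = het_values[i]
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        probs[i + 1] = probs[i] * 4.0 * hom_r * hom_c / ((h + 2.0) * (h + 1.0))
    for i in range(mid, 0, -1):
        h = het_values[i]
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        probs[i - 1] = probs[i] * h * (h - 1.0) / (4.0 * (hom_r + 1.0) * (hom_c + 1.0))
    probs /= probs.sum()

    obs = np.searchsorted(het_values, n_het)
    p_obs = probs[obs]
    p = float(min(1.0, probs[probs <= p_obs * (1.0 + 1e-12)].sum()))
    if with_strict:
        p_strict = float(probs[probs < p_obs * (1.0 - 1e-12)].sum())
        return p, p_strict
    return p


def _hwe_from_dosages(g: np.ndarray) -> float:
    g = g[~np.isnan(g)]
    if g.size == 0:
        return np.nan
    n_het = int(np.sum(g == 1.0))
    n_hom_a1 = int(np.sum(g == 2.0))
    n_hom_a2 = int(np.sum(g == 0.0))
    return hwe_exact_test(n_het, n_hom_a1, n_hom_a2)


# ---------------------------------------------------------------------------
# per-sample / per-variant statistics
# ---------------------------------------------------------------------------

def compute_sample_stats(genotypes: GenotypeDataset) -> pd.DataFrame:
    """Call rate per sample (non-missing genotype fraction)."""
    if genotypes.n_variants < 1:
        raise ValueError("need at least one variant")
    return pd.DataFrame(
        {
            "sample_id": genotypes.sample_ids.to_numpy(),
            "call_rate": genotypes.sample_call_rate(),
        }
    )


def compute_variant_stats(
    genotypes: GenotypeDataset, batch_labels: np.ndarray | None = None
) -> pd.DataFrame:
    """MAF, call rate, exact HWE p and (optionally) differential missingness.

    ``batch_labels`` must take exactly two values (the two genotyping
    arrays); the differential-missingness p comes from Fisher's exact test
    on the 2x2 table of missing/non-missing by batch.  Variants with all
    genotypes missing get NaN statistics and fail QC automatically.
    """
    g = genotypes.genotypes
    maf = genotypes.maf()
    call_rate = genotypes.variant_call_rate()
    hwe_p = np.array([_hwe_from_dosages(g[:, j]) for j in range(g.shape[1])])

    if batch_labels is not None:
        batch_labels = np.asarray(batch_labels)
        levels = np.unique(batch_labels)
        if levels.shape[0] != 2:
            raise ValueError("batch_labels must have exactly two levels")
        in_b1 = batch_labels == levels[0]
        missing = np.isnan(g)
        batch_p = np.empty(g.shape[1])
        for j in range(g.shape[1]):
            table = [
                [int(missing[in_b1, j].sum()), int((~missing[in_b1, j]).sum())],
                [int(missing[~in_b1, j].sum()), int((~missing[~in_b1, j]).sum())],
            ]
            batch_p[j] = stats.fisher_exact(table)[1]
    else:
        batch_p = np.full(g.shape[1], np.nan)

    return pd.DataFrame(
        {
            "variant_id": genotypes.variant_ids.to_numpy(),
            "maf": maf,
            "call_rate": call_rate,
            "hwe_p": hwe_p,
            "batch_missingness_p": batch_p,
        }
    )


# ---------------------------------------------------------------------------
# ancestry principal components
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PCResult:
    coordinates: pd.DataFrame  # sample_id + PC1..PCk
    outlier: np.ndarray        # boolean, any of first k PCs beyond the SD cut
    explained_variance: np.ndarray


def ancestry_pcs(
    genotypes: GenotypeDataset, k: int = 4, outlier_sd: float = 4.0
) -> PCResult:
    """Leading PCs of the standardized genotype matrix.

    Each variant is mean-imputed for missing calls and standardized by
    sqrt(2p(1-p)); outliers are samples whose coordinate on any of the
    first ``k`` PCs lies more than ``outlier_sd`` standard deviations from
    that PC's mean.  This PC-space rule stands in for reference-anchored
    IBS outlier detection when no external reference panel is used.
    """
    n, m = genotypes.n_samples, genotypes.n_variants
    if k > min(n, m):
        raise ValueError(f"k={k} exceeds min(n_samples, n_variants)={min(n, m)}")
    g = genotypes.genotypes.copy()
    freq = genotypes.allele_freq()
    means = 2.0 * freq
    nan_rows, nan_cols = np.nonzero(np.isnan(g))
    g[nan_rows, nan_cols] = means[nan_cols]
    scale = np.sqrt(2.0 * freq * (1.0 - freq))
    usable = scale > 0
    z = (g[:, usable] - means[usable]) / scale[usable]

    u, s, vt = np.linalg.svd(z, full_matrices=False)
    coords = u[:, :k] * s[:k]
    # deterministic sign: largest-magnitude loading positive
    for comp in range(k):
        pivot = np.argmax(np.abs(vt[comp]))
        if vt[comp, pivot] < 0:
            coords[:, comp] *= -1.0
    std = coords.std(axis=0, ddof=1)
    std[std == 0] = 1.0
    outlier = (np.abs(coords - coords.mean(axis=0)) > outlier_sd * std).any(axis=1)
    frame = pd.DataFrame(coords, columns=[f"PC{i + 1}" for i in range(k)])
    frame.insert(0, "sample_id", genotypes.sample_ids.to_numpy())
    explained = (s[:k] ** 2) / np.sum(s**2)
    return PCResult(frame, outlier, explained)


# ---------------------------------------------------------------------------
# full QC pass
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class QCResult:
    dataset: GenotypeDataset
    exclusions: pd.DataFrame  # id, kind, stage, reason, value
    sample_stats: pd.DataFrame
    variant_stats: pd.DataFrame
    pcs: PCResult | None


def apply_qc(
    genotypes: GenotypeDataset,
    thresholds: QCThresholds | None = None,
    batch_labels: np.ndarray | None = None,
    compute_pcs: bool = True,
) -> QCResult:
    """Run the full QC cascade and return the filtered dataset plus log.

    Order of application: sample call-rate filter, then PC-space ancestry
    outliers, then variant filters (MAF, call rate, HWE, differential
    missingness) recomputed on the retained samples.
    """
    thr = thresholds or QCThresholds()
    log: list[dict] = []

    sample_stats = compute_sample_stats(genotypes)
    keep_samples = sample_stats["call_rate"].to_numpy() >= thr.sample_call_rate
    for sid, value in zip(
        sample_stats["sample_id"][~keep_samples], sample_stats["call_rate"][~keep_samples]
    ):
        log.append(
            {"id": sid, "kind": "sample", "stage": "sample_filters",
             "reason": "sample_call_rate", "value": value}
        )
    data = genotypes.select_samples(keep_samples)
    if data.n_samples == 0:
        raise ValueError("all samples excluded by the call-rate filter")

    pcs = None
    if compute_pcs and data.n_samples > thr.n_pcs and data.n_variants >= thr.n_pcs:
        provisional = compute_variant_stats(data)
        ok = (
            (provisional["maf"].to_numpy() >= thr.maf)
            & (provisional["call_rate"].to_numpy() >= thr.variant_call_rate)
            & (np.nan_to_num(provisional["hwe_p"].to_numpy(), nan=0.0) >= thr.hwe_p)
        )
        if ok.sum() >= thr.n_pcs:
            pcs = ancestry_pcs(data.select_variants(ok), k=thr.n_pcs, outlier_sd=thr.pc_outlier_sd)
            if pcs.outlier.any():
                coords = pcs.coordinates
                zmax = (
                    np.abs(
                        (coords.iloc[:, 1:] - coords.iloc[:, 1:].mean())
                        / coords.iloc[:, 1:].std(ddof=1)
                    ).max(axis=1).to_numpy()
                )
                for i in np.flatnonzero(pcs.outlier):
                    log.append(
                        {"id": coords["sample_id"].iloc[i], "kind": "sample",
                         "stage": "pc_outliers", "reason": "pc_outlier",
                         "value": zmax[i]}
                    )
                data = data.select_samples(~pcs.outlier)
                if data.n_samples == 0:
                    raise ValueError("all samples excluded as PC outliers")

    variant_stats = compute_variant_stats(data, batch_labels=batch_labels)
    maf = variant_stats["maf"].to_numpy()
    vcr = variant_stats["call_rate"].to_numpy()
    hwe = variant_stats["hwe_p"].to_numpy()
    batch_p = variant_stats["batch_missingness_p"].to_numpy()

    keep_variants = np.ones(data.n_variants, dtype=bool)
    checks = [
        ("all_missing", np.isnan(maf), maf),
        ("maf", ~np.isnan(maf) & (maf < thr.maf), maf),
        ("variant_call_rate", vcr < thr.variant_call_rate, vcr),
        ("hwe", ~np.isnan(hwe) & (hwe < thr.hwe_p), hwe),
        ("batch_missingness", ~np.isnan(batch_p) & (batch_p < thr.batch_missingness_p), batch_p),
    ]
    for reason, failing, values in checks:
        for j in np.flatnonzero(failing & keep_variants):
            log.append(
                {"id": variant_stats["variant_id"].iloc[j], "kind": "variant",
                 "stage": "variant_filters", "reason": reason, "value": values[j]}
            )
        keep_variants &= ~failing
    data = data.select_variants(keep_variants)

    exclusions = pd.DataFrame(log, columns=["id", "kind", "stage", "reason", "value"])
    return QCResult(data, exclusions, sample_stats, variant_stats, pcs)
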