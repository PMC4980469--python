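"""Per-variant linear models with covariates.

Ordinary least squares of a continuous outcome on minor-allele dosage
(additive model), on a dosage-by-exposure interaction, plus stratification
helpers and the allele-frequency gene-environment-correlation check.
Missing genotypes are handled by per-variant casewise deletion; two-sided
p-values use the t distribution with residual degrees of freedom.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import GenotypeDataset


@dataclasses.dataclass
class AssociationRecord:
    """Regression output for one tested term at one variant."""

    variant_id: str
    model: str          # additive_main | interaction | allele_freq_diff
    n_used: int
    beta: float
    se: float
    stat: float
    p: float
    flag: str = ""      # "", "monomorphic", "degenerate", "zero_margin"


def _as_matrix(covariates) -> np.ndarray | None:
    if covariates is None:
        return None
    if isinstance(covariates, pd.DataFrame):
        covariates = covariates.to_numpy(dtype=float)
    covariates = np.asarray(covariates, dtype=float)
    if covariates.ndim == 1:
        covariates = covariates[:, None]
    return covariates


def _ols_term(design: np.ndarray, y: np.ndarray, term: int) -> tuple[float, float, float, float]:
    """(beta, se, t, p) for one column of an OLS design, via QR."""
    n, k = design.shape
    df = n - k
    if df < 1:
        return np.nan, np.nan, np.nan, np.nan
    q, r = np.linalg.qr(design)
    beta = np.linalg.solve(r, q.T @ y)
    resid = y - design @ beta
    sigma2 = float(resid @ resid) / df
    rinv = np.linalg.inv(r)
    cov = rinv @ rinv.T * sigma2
    se = float(np.sqrt(cov[term, term]))
    t = float(beta[term] / se)
    p = float(2.0 * stats.t.sf(abs(t), df))
    return float(beta[term]), se, t, p


def _complete_mask(*arrays) -> np.ndarray:
    mask = np.ones(arrays[0].shape[0], dtype=bool)
    for a in arrays:
        if a is None:
            continue
        if a.ndim == 1:
            mask &= ~np.isnan(a)
        else:
            mask &= ~np.isnan(a).any(axis=1)
    return mask


def fit_additive(
    y, g, covariates=None, variant_id: str = ""
) -> AssociationRecord:
    """OLS of y on [1, dosage, covariates] over complete cases.

    Reports the dosage coefficient with its SE and a two-sided t-test p.
    A variant monomorphic in the analysis sample is flagged and gets an
    undefined p.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    covariates = _as_matrix(covariates)
    mask = _complete_mask(y, g, covariates)
    n_used = int(mask.sum())
    yy, gg = y[mask], g[mask]
    if n_used < 3 or np.ptp(gg) == 0.0:
        return AssociationRecord(variant_id, "additive_main", n_used,
                                 np.nan, np.nan, np.nan, np.nan, "monomorphic")
    cols = [np.ones(n_used), gg]
    if covariates is not None:
        cols.append(covariates[mask])
    design = np.column_stack(cols)
    beta, se, t, p = _ols_term(design, yy, term=1)
    return AssociationRecord(variant_id, "additive_main", n_used, beta, se, t, p)


def fit_interaction(
    y, g, e, covariates=None, variant_id: str = ""
) -> AssociationRecord:
    """OLS of y on [1, g, E, gxE, covariates]; reports the gxE term."""
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    e = np.asarray(e, dtype=float)
    if not np.isin(e[~np.isnan(e)], (0.0, 1.0)).all():
        raise ValueError("exposure E must be binary (0/1)")
    covariates = _as_matrix(covariates)
    mask = _complete_mask(y, g, e, covariates)
    n_used = int(mask.sum())
    yy, gg, ee = y[mask], g[mask], e[mask]
    gxe = gg * ee
    if n_used < 5 or np.ptp(gg) == 0.0 or np.ptp(ee) == 0.0 or np.ptp(gxe) == 0.0:
        return AssociationRecord(variant_id, "interaction", n_used,
                                 np.nan, np.nan, np.nan, np.nan, "degenerate")
    cols = [np.ones(n_used), gg, ee, gxe]
    if covariates is not None:
        cols.append(covariates[mask])
    design = np.column_stack(cols)
    beta, se, t, p = _ols_term(design, yy, term=3)
    return AssociationRecord(variant_id, "interaction", n_used, beta, se, t, p)


def stratify(e) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks (E==0, E==1): a disjoint, exhaustive partition.

    Raises if E has missing values or either stratum is empty.
    """
    e = np.asarray(e, dtype=float)
    if np.isnan(e).any():
        raise ValueError("exposure E must be defined for all samples")
    if not np.isin(e, (0.0, 1.0)).all():
        raise ValueError("exposure E must be binary (0/1)")
    mask0, mask1 = e == 0.0, e == 1.0
    if not mask0.any() or not mask1.any():
        raise ValueError("a stratum is empty: E is constant")
    return mask0, mask1


def stratify_dataset(
    dataset: GenotypeDataset, e
) -> tuple[GenotypeDataset, GenotypeDataset]:
    """Split a genotype dataset into the E=0 and E=1 strata."""
    mask0, mask1 = stratify(e)
    return dataset.select_samples(mask0), dataset.select_samples(mask1)


def allele_freq_diff_test(genotypes: GenotypeDataset, e) -> pd.DataFrame:
    """Per-variant 2x2 chi-square test of allele counts between strata.

    The rGE (gene-environment correlation) check: 2N alleles per stratum,
    Pearson chi-square without continuity correction.  Variants with a
    zero margin get p = 1 and a ``zero_margin`` flag.
    """
    mask0, mask1 = stratify(e)
    g = genotypes.genotypes
    records = []
    for j, vid in enumerate(genotypes.variant_ids):
        rows = []
        for mask in (mask0, mask1):
            col = g[mask, j]
            col = col[~np.isnan(col)]
            a1 = float(col.sum())
            rows.append((a1, 2.0 * col.size - a1))
        (a, b), (c, d) = rows
        n = a + b + c + d
        margins = np.array([a + b, c + d, a + c, b + d])
        if n == 0 or (margins == 0).any():
            records.append(AssociationRecord(vid, "allele_freq_diff", int(mask0.sum() + mask1.sum()),
                                             np.nan, np.nan, 0.0, 1.0, "zero_margin"))
            continue
        chi2 = n * (a * d - b * c) ** 2 / np.prod(margins)
        p = float(stats.chi2.sf(chi2, df=1))
        records.append(AssociationRecord(vid, "allele_freq_diff",
                                         int(mask0.sum() + mask1.sum()),
                                         np.nan, np.nan, float(chi2), p))
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


def association_table(records: list[AssociationRecord], variants: pd.DataFrame) -> pd.DataFrame:
    """Join records with the variant map into the standard results table."""
    frame = pd.DataFrame([dataclasses.asdict(r) for r in records])
    return frame.merge(
        variants[["variant_id", "chrom", "pos"]], on="variant_id", how="left"
    )[["variant_id", "chrom", "pos", "model", "n_used", "beta", "se", "stat", "p", "flag"]]
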