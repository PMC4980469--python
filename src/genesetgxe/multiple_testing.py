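"""Effective-number-of-tests bookkeeping and Bonferroni thresholds.

Gene level: genes separated by less than a minimum base-pair gap (default
5 Mb, single linkage between closest transcription boundaries) are
counted as one independent unit.  SNP level: the effective count is the
number of variants surviving sliding-window LD pruning (window 50, step
5, r^2 ceiling 0.20, the PLINK ``--indep-pairwise`` convention).  The
family-wise alpha of 0.05 is divided by the effective count.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import GeneRecord
from .datasets import GenotypeDataset


@dataclasses.dataclass
class MultipleTestingPlan:
    level: str            # "gene" or "snp"
    m_nominal: int
    m_effective: int
    alpha_family: float = 0.05

    @property
    def alpha_per_test(self) -> float:
        return bonferroni(self.alpha_family, self.m_effective)


def bonferroni(alpha: float, m_effective: int) -> float:
    """Per-test alpha = family alpha / effective test count."""
    if m_effective < 1:
        raise ValueError("m_effective must be >= 1")
    return alpha / m_effective


def independent_gene_count(
    genes: Sequence[GeneRecord], min_separation: int = 5_000_000
) -> tuple[int, dict[str, int]]:
    """Count independent gene clusters under a base-pair separation rule.

    Genes on different chromosomes are independent; on the same
    chromosome two genes link when the gap between their closest
    boundaries is below ``min_separation`` (overlap counts as gap 0), and
    single-linkage chaining merges linked genes into one cluster.
    Returns the cluster count and each gene's cluster label.
    """
    n = len(genes)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    for i in range(n):
        for j in range(i + 1, n):
            a, b = genes[i], genes[j]
            if a.chromosome != b.chromosome:
                continue
            gap = max(a.tss - b.tes, b.tss - a.tes, 0)
            if gap < min_separation:
                union(i, j)

    roots = sorted({find(i) for i in range(n)})
    label_of_root = {r: k for k, r in enumerate(roots)}
    labels = {genes[i].name: label_of_root[find(i)] for i in range(n)}
    return len(roots), labels


def _pairwise_r2(g: np.ndarray) -> np.ndarray:
    """Squared genotype correlation between columns, mean-imputed."""
    g = g.copy()
    col_means = np.nanmean(g, axis=0)
    nan_rows, nan_cols = np.nonzero(np.isnan(g))
    g[nan_rows, nan_cols] = col_means[nan_cols]
    g = g - g.mean(axis=0)
    norms = np.sqrt(np.einsum("ij,ij->j", g, g))
    norms[norms == 0] = np.inf
    r = (g.T @ g) / np.outer(norms, norms)
    return r**2


def ld_prune(
    genotypes: GenotypeDataset,
    window: int = 50,
    step: int = 5,
    r2_max: float = 0.20,
) -> list[str]:
    """Greedy sliding-window LD pruning; returns retained variant ids.

    Windows of ``window`` variants (map order, per chromosome) advance by
    ``step``.  While any retained within-window pair exceeds ``r2_max``,
    the pair with the highest r^2 loses its lower-MAF member (ties: the
    later map position).  Deterministic; the output satisfies
    r^2 <= r2_max for every retained within-window pair by construction.
    """
    if genotypes.n_variants < 2:
        return list(genotypes.variant_ids)
    maf = genotypes.maf()
    ids = genotypes.variant_ids.to_numpy()
    chroms = genotypes.variants["chrom"].to_numpy()
    retained = np.ones(genotypes.n_variants, dtype=bool)

    for chrom in pd.unique(chroms):
        on_chrom = np.flatnonzero(chroms == chrom)
        for start in range(0, max(1, on_chrom.size - 1), step):
            win = on_chrom[start : start + window]
            while True:
                active = win[retained[win]]
                if active.size < 2:
                    break
                r2 = _pairwise_r2(genotypes.genotypes[:, active])
                np.fill_diagonal(r2, 0.0)
                worst = np.unravel_index(np.argmax(r2), r2.shape)
                if r2[worst] <= r2_max:
                    break
                i, j = active[worst[0]], active[worst[1]]
                if maf[i] < maf[j] or (maf[i] == maf[j] and i > j):
                    retained[i] = False
                else:
                    retained[j] = False
            if start + window >= on_chrom.size:
                break
    return list(ids[retained])


def plan_summary(plans: Sequence[MultipleTestingPlan]) -> pd.DataFrame:
    """Tabulate plans; per-test alpha reported at 4 decimal places."""
    return pd.DataFrame(
        {
            "level": [p.level for p in plans],
            "m_nominal": [p.m_nominal for p in plans],
            "m_effective": [p.m_effective for p in plans],
            "alpha_family": [p.alpha_family for p in plans],
            "alpha_per_test": [round(p.alpha_per_test, 4) for p in plans],
        }
    )
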