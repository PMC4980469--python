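"""Self-contained and competitive gene-set permutation tests.

The set statistic is T = sum over member variants of -log10 of the
single-variant additive-model p-value.  Self-contained empirical p-values
come from phenotype permutations (the empirical p is the fraction of
permuted statistics at least as large as the observed one); competitive
p-values compare the focal set's self-contained p against those of random
gene-sets of equal gene count drawn from a gene universe.

The model/results pair :class:`GeneSetPermutationTest` /
:class:`GeneSetPermutationResults` is the primary interface; the
module-level functions (`set_statistic`, `self_contained_test`,
`gene_based_tests`, `competitive_test`) are thin functional wrappers.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneSet
from .datasets import GenotypeDataset
from .permutation import PermutationEngine


def set_statistic(p_values) -> float:
    """T = sum of -log10(p) over member variants.

    Any p <= 0 is an error: undefined p-values must be excluded upstream,
    and parametric p-values are floored (see ``permutation.P_FLOOR``)
    before they reach the log.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) <= 0.0 or np.nanmax(p) > 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    return float(np.sum(-np.log10(p)))


@dataclasses.dataclass
class GeneSetTestResult:
    """One self-contained permutation test (a gene or the whole set)."""

    unit: str
    observed_T: float
    n_variants_used: int
    n_perm: int
    empirical_p: float
    seed: int | None = None
    flag: str = ""


@dataclasses.dataclass
class CompetitiveResult:
    """Competitive comparison against random equal-size gene-sets."""

    focal_self_p: float
    n_random_sets: int
    random_self_ps: np.ndarray
    competitive_p: float
    seed: int | None = None


def _empirical_p(t_obs: float, t_perm: np.ndarray, correction: bool) -> float:
    hits = int(np.sum(t_perm >= t_obs))
    if correction:
        return (hits + 1.0) / (t_perm.shape[0] + 1.0)
    return hits / t_perm.shape[0]


class GeneSetPermutationTest:
    """Permutation test of a gene-set against a continuous outcome.

    Parameters
    ----------
    y : array (n,)
        Continuous outcome, complete.
    genotypes : GenotypeDataset
        Post-QC genotypes for (at least) the member variants.
    geneset : GeneSet or mapping gene -> variant ids or sequence of ids
        Membership; a bare sequence is treated as a single anonymous set.
    covariates : array (n, k), optional
        Complete covariates included in every single-variant model.
    """

    def __init__(self, y, genotypes: GenotypeDataset, geneset, covariates=None,
                 set_name: str | None = None):
        if isinstance(geneset, GeneSet):
            membership = {g: list(v) for g, v in geneset.membership.items()}
            name = set_name or geneset.name
        elif isinstance(geneset, Mapping):
            membership = {g: list(v) for g, v in geneset.items()}
            name = set_name or "gene-set"
        else:
            membership = {set_name or "gene-set": list(geneset)}
            name = set_name or "gene-set"
        self.set_name = name
        self.membership = membership
        self.genotypes = genotypes
        self.y = np.asarray(y, dtype=float)
        self.covariates = covariates

        seen: dict[str, None] = {}
        for ids in membership.values():
            for vid in ids:
                seen.setdefault(vid, None)
        self.variant_ids = list(seen)
        if not self.variant_ids:
            raise ValueError("gene-set has no member variants")
        cols = [genotypes.variant_index(v) for v in self.variant_ids]
        self._engine = PermutationEngine(
            genotypes.genotypes[:, cols], self.y, covariates
        )
        self._col_of = {v: i for i, v in enumerate(self.variant_ids)}

    def fit(
        self,
        n_perm: int = 9000,
        seed: int | None = None,
        method: str = "phenotype",
        correction: bool = False,
        include_genes: bool = True,
    ) -> "GeneSetPermutationResults":
        """Run the permutation test.

        One shared permutation stream serves the full set and every gene,
        so per-gene and set-level empirical p-values are mutually
        consistent.  ``correction=True`` applies the (hits+1)/(B+1)
        small-sample adjustment; the default reports the plain fraction.
        """
        rng = np.random.default_rng(seed)
        obs = self._engine.observed()
        perm = self._engine.permuted(n_perm, rng, method=method)
        usable = self._engine.usable

        def _stat(cols: np.ndarray) -> tuple[float, np.ndarray, int]:
            cols = cols[usable[cols]]
            if cols.size == 0:
                return np.nan, np.empty(0), 0
            t_obs = float(np.sum(obs[cols]))
            t_perm = perm[:, cols].sum(axis=1)
            if not np.isfinite(t_perm).all():
                raise FloatingPointError(
                    f"non-finite permutation statistic for {self.set_name}"
                )
            return t_obs, t_perm, int(cols.size)

        all_cols = np.arange(len(self.variant_ids))
        t_obs, t_perm, n_used = _stat(all_cols)
        if n_used == 0:
            raise ValueError("zero usable variants in the gene-set")
        set_result = GeneSetTestResult(
            self.set_name, t_obs, n_used, n_perm,
            _empirical_p(t_obs, t_perm, correction), seed,
        )

        gene_results: dict[str, GeneSetTestResult] = {}
        if include_genes and list(self.membership) != [self.set_name]:
            for gene, ids in self.membership.items():
                cols = np.array([self._col_of[v] for v in ids], dtype=int)
                g_obs, g_perm, g_used = _stat(cols)
                if g_used == 0:
                    gene_results[gene] = GeneSetTestResult(
                        gene, np.nan, 0, n_perm, np.nan, seed, "no_usable_variants"
                    )
                else:
                    gene_results[gene] = GeneSetTestResult(
                        gene, g_obs, g_used, n_perm,
                        _empirical_p(g_obs, g_perm, correction), seed,
                    )
        return GeneSetPermutationResults(self, set_result, gene_results,
                                         n_perm, seed, method, correction)


class GeneSetPermutationResults:
    """Results of a gene-set permutation test, with per-gene breakdown."""

    def __init__(self, model, set_result, gene_results, n_perm, seed, method, correction):
        self.model = model
        self.set_result: GeneSetTestResult = set_result
        self.gene_results: dict[str, GeneSetTestResult] = gene_results
        self.n_perm = n_perm
        self.seed = seed
        self.method = method
        self.correction = correction

    @property
    def empirical_p(self) -> float:
        return self.set_result.empirical_p

    def table(self) -> pd.DataFrame:
        rows = [self.set_result] + list(self.gene_results.values())
        frame = pd.DataFrame([dataclasses.asdict(r) for r in rows])
        return frame[["unit", "n_variants_used", "observed_T", "n_perm",
                      "empirical_p", "flag"]]

    def summary(self) -> str:
        lines = [
            f"Gene-set permutation test: {self.set_result.unit}",
            f"  permutations: {self.n_perm} ({self.method}), seed={self.seed}",
            f"  observed T = {self.set_result.observed_T:.3f} over "
            f"{self.set_result.n_variants_used} variants",
            f"  empirical p = {self.set_result.empirical_p:.4f}",
        ]
        for gene, res in self.gene_results.items():
            if res.flag:
                lines.append(f"  {gene:>12}: {res.flag}")
            else:
                lines.append(
                    f"  {gene:>12}: T = {res.observed_T:7.3f} "
                    f"({res.n_variants_used:3d} variants), p = {res.empirical_p:.4f}"
                )
        return "\n".join(lines)

    def competitive(
        self,
        gene_universe: Mapping[str, Sequence[str]],
        n_random: int = 150,
        seed: int | None = None,
        n_perm: int | None = None,
    ) -> CompetitiveResult:
        """Competitive test against random gene-count-matched sets.

        ``gene_universe`` maps candidate genes (excluding the focal genes)
        to their member variants; each random set draws the focal gene
        count without replacement.  Random sets are matched on gene count
        only; note the set statistic scales with variant count, so
        variant-rich random sets are not penalised.
        """
        model = self.model
        focal_genes = [g for g in model.membership if model.membership[g]]
        n_genes = max(1, len(focal_genes))
        universe_genes = [g for g in gene_universe if g not in model.membership]
        if len(universe_genes) < n_genes:
            raise ValueError(
                f"gene universe too small: {len(universe_genes)} < {n_genes}"
            )
        rng = np.random.default_rng(seed)
        n_perm = n_perm or self.n_perm

        seen: dict[str, None] = {}
        for g in universe_genes:
            for vid in gene_universe[g]:
                seen.setdefault(vid, None)
        universe_variants = list(seen)
        cols_for = {v: i for i, v in enumerate(universe_variants)}
        cols = [model.genotypes.variant_index(v) for v in universe_variants]
        engine = PermutationEngine(
            model.genotypes.genotypes[:, cols], model.y, model.covariates
        )
        obs = engine.observed()
        perm = engine.permuted(n_perm, rng)

        random_ps = np.empty(n_random)
        for r in range(n_random):
            chosen = rng.choice(len(universe_genes), size=n_genes, replace=False)
            idx = np.array(
                [cols_for[v] for gi in chosen for v in gene_universe[universe_genes[gi]]],
                dtype=int,
            )
            idx = np.unique(idx)
            idx = idx[engine.usable[idx]]
            if idx.size == 0:
                random_ps[r] = 1.0
                continue
            t_obs = float(np.sum(obs[idx]))
            t_perm = perm[:, idx].sum(axis=1)
            random_ps[r] = _empirical_p(t_obs, t_perm, self.correction)

        focal_p = self.set_result.empirical_p
        competitive_p = float(np.mean(random_ps < focal_p))
        return CompetitiveResult(focal_p, n_random, random_ps, competitive_p, seed)


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def self_contained_test(
    genotypes: GenotypeDataset, y, covariates, member_variants: Sequence[str],
    n_perm: int = 9000, seed: int | None = None, method: str = "phenotype",
    correction: bool = False, set_name: str = "gene-set",
) -> GeneSetTestResult:
    """Self-contained permutation test for one variant collection."""
    model = GeneSetPermutationTest(
        y, genotypes, list(member_variants), covariates, set_name=set_name
    )
    return model.fit(
        n_perm=n_perm, seed=seed, method=method, correction=correction,
        include_genes=False,
    ).set_result


def gene_based_tests(
    genotypes: GenotypeDataset, y, covariates, geneset: GeneSet,
    n_perm: int = 9000, seed: int | None = None, method: str = "phenotype",
    correction: bool = False,
) -> dict[str, GeneSetTestResult]:
    """Per-gene self-contained tests sharing one permutation stream."""
    model = GeneSetPermutationTest(y, genotypes, geneset, covariates)
    return model.fit(
        n_perm=n_perm, seed=seed, method=method, correction=correction
    ).gene_results


def competitive_test(
    focal_result: GeneSetPermutationResults,
    gene_universe: Mapping[str, Sequence[str]],
    n_random: int = 150,
    seed: int | None = None,
) -> CompetitiveResult:
    """Competitive test for a fitted self-contained result."""
    return focal_result.competitive(gene_universe, n_random=n_random, seed=seed)
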