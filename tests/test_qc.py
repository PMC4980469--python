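"""Quality-control statistics, filters and ancestry PCs."""

from fractions import Fraction
from math import factorial

import numpy as np
import pytest

from genesetgxe.qc import (
    QCThresholds,
    ancestry_pcs,
    apply_qc,
    compute_sample_stats,
    compute_variant_stats,
    hwe_exact_test,
)
from genesetgxe.simulate import SimConfig, simulate_genotypes

from conftest import make_dataset


# --- call rates ------------------------------------------------------------

def test_call_rate_arithmetic(rng):
    g = rng.integers(0, 3, size=(5, 100)).astype(float)
    g[0, :5] = np.nan  # 5 missing of 100
    ds = make_dataset(g)
    stats_ = compute_sample_stats(ds)
    assert stats_["call_rate"].iloc[0] == pytest.approx(0.95)
    assert (stats_["call_rate"].iloc[1:] == 1.0).all()


def test_call_rate_matches_brute_force_count(rng):
    g = rng.integers(0, 3, size=(30, 50)).astype(float)
    mask = rng.random(g.shape) < 0.2
    g[mask] = np.nan
    ds = make_dataset(g)
    sample = compute_sample_stats(ds)["call_rate"].to_numpy()
    variant = compute_variant_stats(ds)["call_rate"].to_numpy()
    for i in range(30):
        assert sample[i] == pytest.approx(
            sum(not np.isnan(g[i, j]) for j in range(50)) / 50
        )
    for j in range(50):
        assert variant[j] == pytest.approx(
            sum(not np.isnan(g[i, j]) for i in range(30)) / 30
        )


# --- HWE exact test --------------------------------------------------------

def _hwe_enumeration_oracle(n_het, n_hom_rare, n_hom_common):
    """Exact-rational enumeration of the conditional null distribution."""
    n = n_het + n_hom_rare + n_hom_common
    rare = 2 * min(n_hom_rare, n_hom_common) + n_het

    def prob(h):
        r = (rare - h) // 2
        c = n - h - r
        return (
            Fraction(factorial(n) * 2**h, factorial(r) * factorial(h) * factorial(c))
            * Fraction(factorial(rare) * factorial(2 * n - rare), factorial(2 * n))
        )

    support = [
        h for h in range(rare % 2, min(rare, 2 * n - rare) + 1, 2)
        if n - h - (rare - h) // 2 >= 0
    ]
    probs = {h: prob(h) for h in support}
    p_obs = probs[n_het]
    return float(sum(p for p in probs.values() if p <= p_obs))


def test_hwe_exact_matches_enumeration_oracle(rng):
    for _ in range(60):
        n = int(rng.integers(4, 50))
        f = rng.uniform(0.05, 0.5)
        g = (rng.random((n, 2)) < f).sum(axis=1)
        counts = (int(np.sum(g == 1)), int(np.sum(g == 2)), int(np.sum(g == 0)))
        assert hwe_exact_test(*counts) == pytest.approx(
            _hwe_enumeration_oracle(*counts), abs=1e-12
        )


def test_hwe_equilibrium_proportions_give_p_one():
    assert hwe_exact_test(50, 25, 25) > 0.9


def test_hwe_all_heterozygous_fails_filter():
    assert hwe_exact_test(100, 0, 0) < 1e-6


def test_hwe_invalid_counts():
    with pytest.raises(ValueError):
        hwe_exact_test(-1, 0, 0)
    assert np.isnan(hwe_exact_test(0, 0, 0))


# --- variant stats ---------------------------------------------------------

def test_variant_stats_maf_and_hwe(rng):
    # (AA, Aa, aa) = (25, 50, 25): MAF 0.5, perfect HWE proportions
    g = np.concatenate([np.zeros(25), np.ones(50), np.full(25, 2.0)])
    ds = make_dataset(g[rng.permutation(100)][:, None])
    stats_ = compute_variant_stats(ds)
    assert stats_["maf"].iloc[0] == pytest.approx(0.5)
    assert stats_["hwe_p"].iloc[0] > 0.9


def test_identical_missingness_across_batches_gives_p_one(rng):
    g = rng.integers(0, 3, size=(40, 6)).astype(float)
    g[:4, 2] = np.nan
    g[20:24, 2] = np.nan  # same pattern in each half
    batches = np.repeat(["A", "B"], 20)
    stats_ = compute_variant_stats(make_dataset(g), batch_labels=batches)
    assert stats_["batch_missingness_p"].iloc[2] == pytest.approx(1.0)
    with pytest.raises(ValueError, match="two levels"):
        compute_variant_stats(make_dataset(g), batch_labels=np.arange(40))


# --- apply_qc --------------------------------------------------------------

def _clean_dataset(seed=11, n=300, m=60):
    cfg = SimConfig(n_samples=n, n_variants=m, n_genes=6,
                    maf_range=(0.05, 0.5), seed=seed)
    return simulate_genotypes(cfg)


def test_clean_cohort_passes_qc_nearly_intact():
    ds = _clean_dataset()
    result = apply_qc(ds)
    assert result.dataset.n_variants >= 0.99 * ds.n_variants
    assert result.dataset.n_samples == ds.n_samples


def test_injected_low_maf_variant_excluded_with_reason():
    ds = _clean_dataset()
    rare = np.zeros(ds.n_samples)
    rare[:2] = 1.0  # MAF ~ 0.003
    ds = ds.add_variant("rare1", rare, chrom=1, pos=999_999)
    result = apply_qc(ds)
    log = result.exclusions
    assert ((log["id"] == "rare1") & (log["reason"] == "maf")).any()
    assert "rare1" not in set(result.dataset.variant_ids)


def test_low_call_rate_sample_excluded_with_reason(rng):
    ds = _clean_dataset()
    g = ds.genotypes.copy()
    g[0, rng.choice(ds.n_variants, size=int(0.1 * ds.n_variants), replace=False)] = np.nan
    ds = make_dataset(g)
    result = apply_qc(ds)
    log = result.exclusions
    assert ((log["id"] == "s0") & (log["reason"] == "sample_call_rate")).any()


def test_qc_is_idempotent_and_bookkeeping_balances():
    ds = _clean_dataset(seed=12)
    g = ds.genotypes.copy()
    g[0, :30] = np.nan
    ds = make_dataset(g)
    once = apply_qc(ds)
    twice = apply_qc(once.dataset)
    assert np.array_equal(
        once.dataset.genotypes, twice.dataset.genotypes, equal_nan=True
    )
    assert len(twice.exclusions) == 0

    log = once.exclusions
    n_samples_excl = (log["kind"] == "sample").sum()
    n_variants_excl = (log["kind"] == "variant").sum()
    assert n_samples_excl + once.dataset.n_samples == ds.n_samples
    assert n_variants_excl + once.dataset.n_variants == ds.n_variants


def test_all_samples_excluded_is_hard_error():
    g = np.full((4, 10), np.nan)
    g[:, 0] = 1.0  # 10% call rate everywhere
    with pytest.raises(ValueError, match="all samples"):
        apply_qc(make_dataset(g))


# --- ancestry PCs ----------------------------------------------------------

def test_pc1_separates_divergent_subpopulations(rng):
    n, m = 200, 80
    labels = np.repeat([0, 1], n // 2)
    p0 = rng.uniform(0.1, 0.5, size=m)
    shift = np.clip(p0 + rng.choice([-0.25, 0.25], size=m), 0.05, 0.95)
    freqs = np.where(labels[:, None] == 0, p0[None, :], shift[None, :])
    g = rng.binomial(2, freqs).astype(float)
    result = ancestry_pcs(make_dataset(g), k=4)
    pc1 = result.coordinates["PC1"].to_numpy()
    r = np.corrcoef(pc1, labels)[0, 1]
    assert abs(r) > 0.9


def test_homogeneous_cohort_has_few_outliers():
    ds = _clean_dataset(seed=13, n=400, m=100)
    result = ancestry_pcs(ds, k=4)
    # 4-SD outliers should be about the normal tail expectation (~0 of 400)
    assert result.outlier.sum() <= 3


def test_duplicate_sample_gets_nearly_identical_coordinates():
    ds = _clean_dataset(seed=14, n=100, m=60)
    g = np.vstack([ds.genotypes, ds.genotypes[0][None, :]])
    result = ancestry_pcs(make_dataset(g), k=4)
    coords = result.coordinates.iloc[:, 1:].to_numpy()
    span = coords.max(axis=0) - coords.min(axis=0)
    assert np.all(np.abs(coords[0] - coords[-1]) < 1e-6 * span)


def test_k_larger_than_matrix_errors():
    ds = _clean_dataset(n=10, m=5)
    with pytest.raises(ValueError, match="exceeds"):
        ancestry_pcs(ds, k=6)
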