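"""Self-contained and competitive permutation tests."""

import numpy as np
import pytest
from scipy import stats

from genesetgxe.geneset import (
    GeneSetPermutationTest,
    gene_based_tests,
    self_contained_test,
    set_statistic,
)
from genesetgxe.annotation import GeneSet
from genesetgxe.simulate import SimConfig, simulate_genotypes

from conftest import make_dataset


# --- set statistic ---------------------------------------------------------

def test_set_statistic_exact_values():
    assert set_statistic([1.0, 1.0, 1.0]) == 0.0
    assert set_statistic([0.1, 0.01]) == pytest.approx(3.0, abs=1e-12)


def test_set_statistic_matches_independent_log_sum(rng):
    p = rng.uniform(1e-8, 1.0, size=50)
    independent = -sum(np.log(x) for x in p) / np.log(10.0)
    assert set_statistic(p) == pytest.approx(independent, abs=1e-12)


def test_set_statistic_rejects_out_of_range():
    with pytest.raises(ValueError):
        set_statistic([0.5, 0.0])
    with pytest.raises(ValueError):
        set_statistic([1.5])


# --- self-contained test ---------------------------------------------------

def _toy_problem(rng, n=60, m=6, beta=0.0):
    g = rng.binomial(2, 0.3, size=(n, m)).astype(float)
    y = beta * g[:, :3].sum(axis=1) + rng.standard_normal(n)
    return make_dataset(g), y


def test_seed_reproduces_empirical_p_exactly(rng):
    ds, y = _toy_problem(rng)
    a = self_contained_test(ds, y, None, list(ds.variant_ids), n_perm=499, seed=7)
    b = self_contained_test(ds, y, None, list(ds.variant_ids), n_perm=499, seed=7)
    assert a.empirical_p == b.empirical_p
    assert a.observed_T == b.observed_T


def test_sampled_p_matches_exhaustive_enumeration(rng):
    """At n=8, the sampled empirical p converges to the exhaustive one."""
    import itertools

    n, m = 8, 3
    g = rng.integers(0, 3, (n, m)).astype(float)
    y = rng.standard_normal(n)
    ds = make_dataset(g)

    # independent oracle: textbook correlation -> t -> p per permutation
    def t_stat(yy):
        total = 0.0
        df = n - 2
        for j in range(m):
            r = np.corrcoef(g[:, j], yy)[0, 1]
            t = r * np.sqrt(df / (1.0 - r * r))
            total += -np.log10(2.0 * stats.t.sf(abs(t), df))
        return total

    t_obs = t_stat(y)
    hits = sum(
        t_stat(y[list(perm)]) >= t_obs - 1e-12
        for perm in itertools.permutations(range(n))
    )
    import math
    exhaustive = hits / math.factorial(n)

    n_perm = 9000
    res = self_contained_test(ds, y, None, list(ds.variant_ids), n_perm=n_perm, seed=5)
    assert abs(res.empirical_p - exhaustive) <= 2.0 / np.sqrt(n_perm)


def test_exchangeability_relabeling_leaves_observed_T_unchanged(rng):
    ds, y = _toy_problem(rng, n=80)
    c = rng.standard_normal((80, 2))
    perm = rng.permutation(80)
    a = GeneSetPermutationTest(y, ds, list(ds.variant_ids), c).fit(
        n_perm=1, seed=0, include_genes=False
    )
    b = GeneSetPermutationTest(
        y[perm], ds.select_samples(perm), list(ds.variant_ids), c[perm]
    ).fit(n_perm=1, seed=0, include_genes=False)
    assert a.set_result.observed_T == pytest.approx(b.set_result.observed_T, rel=1e-10)


def test_empirical_p_monotone_in_observed_statistic():
    from genesetgxe.geneset import _empirical_p

    t_perm = np.array([0.5, 1.0, 2.0, 3.0, 4.0])
    ps = [_empirical_p(t, t_perm, False) for t in (0.0, 1.5, 3.5, 9.0)]
    assert ps == sorted(ps, reverse=True)


def test_plus_one_correction_flag():
    from genesetgxe.geneset import _empirical_p

    t_perm = np.arange(9.0)
    assert _empirical_p(100.0, t_perm, False) == 0.0
    assert _empirical_p(100.0, t_perm, True) == pytest.approx(1.0 / 10.0)


def test_zero_usable_variants_errors(rng):
    ds = make_dataset(np.ones((30, 2)))  # monomorphic everywhere
    with pytest.raises(ValueError, match="usable"):
        self_contained_test(ds, rng.standard_normal(30), None, ["v1", "v2"], n_perm=9)


def test_power_with_no_exposure_effect_at_study_scale(rng):
    """10 causal SNPs of beta 0.3 at n~1100: set test rejects in most reps."""
    hits = 0
    reps = 10
    for rep in range(reps):
        r = np.random.default_rng(500 + rep)
        g = r.binomial(2, 0.3, size=(1100, 10)).astype(float)
        y = 0.3 * g.sum(axis=1) + r.standard_normal(1100)
        res = self_contained_test(make_dataset(g), y, None,
                                  [f"v{j+1}" for j in range(10)],
                                  n_perm=199, seed=rep)
        hits += res.empirical_p <= 0.05
    assert hits >= reps // 2 + 1


# --- gene-based tests ------------------------------------------------------

def test_set_T_is_sum_of_gene_T_for_partition(rng):
    ds, y = _toy_problem(rng, n=100, m=6)
    gs = GeneSet("s", ["g1", "g2"], {"g1": ["v1", "v2", "v3"], "g2": ["v4", "v5", "v6"]})
    model = GeneSetPermutationTest(y, ds, gs)
    res = model.fit(n_perm=99, seed=3)
    total = res.gene_results["g1"].observed_T + res.gene_results["g2"].observed_T
    assert res.set_result.observed_T == pytest.approx(total, rel=1e-12)


def test_single_variant_gene_approximates_parametric_p(rng):
    from genesetgxe.association import fit_additive

    n = 400
    g = rng.binomial(2, 0.3, size=(n, 1)).astype(float)
    y = 0.15 * g[:, 0] + rng.standard_normal(n)
    ds = make_dataset(g)
    parametric = fit_additive(y, g[:, 0]).p
    res = self_contained_test(ds, y, None, ["v1"], n_perm=4999, seed=11)
    assert res.empirical_p == pytest.approx(parametric, abs=3.0 / np.sqrt(4999) + 0.01)


def test_gene_with_no_usable_variants_is_flagged(rng):
    g = np.column_stack([rng.binomial(2, 0.3, 50), np.ones(50)]).astype(float)
    ds = make_dataset(g)
    gs = GeneSet("s", ["ok", "mono"], {"ok": ["v1"], "mono": ["v2"]})
    out = gene_based_tests(ds, rng.standard_normal(50), None, gs, n_perm=49, seed=1)
    assert out["mono"].flag == "no_usable_variants"
    assert np.isnan(out["mono"].empirical_p)
    assert out["ok"].flag == ""


def test_freedman_lane_variant_runs_and_is_calibrated(rng):
    ds, y = _toy_problem(rng, n=80)
    c = rng.standard_normal((80, 2))
    res = GeneSetPermutationTest(y, ds, list(ds.variant_ids), c).fit(
        n_perm=199, seed=4, method="freedman_lane", include_genes=False
    )
    assert 0.0 <= res.empirical_p <= 1.0


# --- competitive test ------------------------------------------------------

def _universe_problem(seed, signal_beta=0.0):
    cfg = SimConfig(n_samples=400, n_variants=80, n_genes=16, ld_block_size=5,
                    seed=seed)
    ds = simulate_genotypes(cfg)
    rng = np.random.default_rng(seed + 1)
    membership = {
        f"GENE{k + 1:03d}": [f"snp{j + 1:05d}" for j in range(5 * k, 5 * (k + 1))]
        for k in range(16)
    }
    focal = GeneSet("focal", list(membership)[:4],
                    {g: membership[g] for g in list(membership)[:4]})
    universe = {g: membership[g] for g in list(membership)[4:]}
    y = rng.standard_normal(400)
    if signal_beta:
        cols = [ds.variant_index(v) for g in focal.genes for v in focal.membership[g]]
        y = y + signal_beta * np.nan_to_num(ds.genotypes[:, cols]).sum(axis=1)
    return ds, y, focal, universe


def test_competitive_p_near_zero_when_focal_carries_all_signal():
    ds, y, focal, universe = _universe_problem(21, signal_beta=0.25)
    res = GeneSetPermutationTest(y, ds, focal).fit(n_perm=299, seed=2)
    comp = res.competitive(universe, n_random=60, seed=3)
    assert res.empirical_p < 0.05
    assert comp.competitive_p <= 0.05
    assert comp.n_random_sets == 60


def test_competitive_p_moderate_under_null():
    values = []
    for seed in range(8):
        ds, y, focal, universe = _universe_problem(40 + seed)
        res = GeneSetPermutationTest(y, ds, focal).fit(n_perm=199, seed=seed)
        comp = res.competitive(universe, n_random=40, seed=seed)
        values.append(comp.competitive_p)
    assert 0.15 < np.mean(values) < 0.85


def test_competitive_universe_too_small_errors():
    ds, y, focal, universe = _universe_problem(60)
    res = GeneSetPermutationTest(y, ds, focal).fit(n_perm=49, seed=0)
    tiny = {k: universe[k] for k in list(universe)[:2]}
    with pytest.raises(ValueError, match="universe too small"):
        res.competitive(tiny, n_random=5, seed=0)
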