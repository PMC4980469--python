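"""Properties of the synthetic cohort generator."""

import numpy as np
import pytest
from scipy import stats

from genesetgxe.qc import hwe_exact_test
from genesetgxe.simulate import (
    SimConfig,
    dopamine_gene_table,
    dopamine_synthetic_variants,
    harsh_dichotomy,
    simulate_cohort,
    simulate_exposures,
    simulate_genotypes,
    write_plink_dataset,
)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError, match="ld_rho"):
        SimConfig(ld_rho=1.0)
    with pytest.raises(ValueError, match="maf_range"):
        SimConfig(maf_range=(0.0, 0.5))
    with pytest.raises(ValueError, match="probability"):
        SimConfig(missing_outcome_rate=1.5)


def test_fixed_seed_reproduces_cohort_bitwise():
    cfg = SimConfig(n_samples=120, n_variants=30, n_genes=6, seed=42)
    a, b = simulate_cohort(cfg), simulate_cohort(cfg)
    assert np.array_equal(a.genotypes.genotypes, b.genotypes.genotypes, equal_nan=True)
    assert a.phenotypes.equals(b.phenotypes)
    assert a.exposures.equals(b.exposures)


def test_maf_hits_target_within_binomial_bound():
    cfg = SimConfig(n_samples=5000, n_variants=40, n_genes=4,
                    maf_range=(0.3, 0.3), seed=5)
    ds = simulate_genotypes(cfg)
    assert np.all(np.abs(ds.maf() - 0.3) < 0.02)


def test_zero_ld_gives_independent_genotypes():
    cfg = SimConfig(n_samples=2000, n_variants=40, ld_block_size=10, ld_rho=0.0,
                    n_genes=4, maf_range=(0.2, 0.4), seed=6)
    ds = simulate_genotypes(cfg)
    r = np.corrcoef(ds.genotypes, rowvar=False)
    off = r[np.triu_indices_from(r, k=1)]
    assert np.mean(np.abs(off)) < 0.05


def test_ld_blocks_are_correlated_within_and_not_between():
    cfg = SimConfig(n_samples=3000, n_variants=20, ld_block_size=10, ld_rho=0.8,
                    n_genes=2, maf_range=(0.3, 0.4), seed=7)
    ds = simulate_genotypes(cfg)
    r = np.corrcoef(ds.genotypes, rowvar=False)
    within = r[:10, :10][np.triu_indices(10, k=1)]
    between = r[:10, 10:]
    assert within.mean() > 0.3
    assert abs(between.mean()) < 0.05


def test_hwe_holds_under_random_mating():
    """Randomized exact-test p-values are uniform; plain p superuniform."""
    cfg = SimConfig(n_samples=2000, n_variants=1000, ld_block_size=1, ld_rho=0.0,
                    n_genes=20, maf_range=(0.1, 0.5), seed=4)
    ds = simulate_genotypes(cfg)
    u = np.random.default_rng(99).random(ds.n_variants)
    randomized, plain = [], []
    for j in range(ds.n_variants):
        g = ds.genotypes[:, j]
        p, p_strict = hwe_exact_test(
            int(np.sum(g == 1)), int(np.sum(g == 2)), int(np.sum(g == 0)),
            with_strict=True,
        )
        plain.append(p)
        randomized.append(p_strict + u[j] * (p - p_strict))
    assert stats.kstest(randomized, "uniform").pvalue > 0.01
    # discrete exact p may only be conservative, never anti-conservative
    assert np.mean(np.asarray(plain) <= 0.05) <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / 1000)


def test_phi_calibration_hits_target():
    cfg = SimConfig(n_samples=10, n_variants=4, n_genes=2, seed=7,
                    parent_phi_target=0.27)
    e = simulate_exposures(cfg, 10000)
    f, m = harsh_dichotomy(e, "father"), harsh_dichotomy(e, "mother")
    pf, pm = f.mean(), m.mean()
    p11 = np.mean((f == 1) & (m == 1))
    phi = (p11 - pf * pm) / np.sqrt(pf * (1 - pf) * pm * (1 - pm))
    assert 0.22 <= phi <= 0.32
    assert abs(pf - cfg.exposure_prevalence_father) < 0.03
    assert abs(pm - cfg.exposure_prevalence_mother) < 0.03


def test_phi_zero_means_independent_parents():
    cfg = SimConfig(n_samples=10, n_variants=4, n_genes=2, seed=8,
                    parent_phi_target=0.0)
    e = simulate_exposures(cfg, 10000)
    f, m = harsh_dichotomy(e, "father"), harsh_dichotomy(e, "mother")
    pf, pm = f.mean(), m.mean()
    p11 = np.mean((f == 1) & (m == 1))
    phi = (p11 - pf * pm) / np.sqrt(pf * (1 - pf) * pm * (1 - pm))
    assert abs(phi) < 0.03


def test_phi_monotone_in_family_loading():
    from genesetgxe.simulate import _calibrate_threshold, _phi_for_loading
    tau = _calibrate_threshold(0.35, 0.7, 5)
    phis = [_phi_for_loading(a, tau, tau, 0.7, 5) for a in (0.0, 0.3, 0.6, 0.9)]
    assert all(b > a for a, b in zip(phis, phis[1:]))


def test_zero_prevalence_puts_everyone_in_no_exposure_group():
    cfg = SimConfig(n_samples=10, n_variants=4, n_genes=2, seed=9,
                    exposure_prevalence_father=0.0,
                    exposure_prevalence_mother=0.0,
                    parent_phi_target=0.0)
    e = simulate_exposures(cfg, 500)
    assert harsh_dichotomy(e, "father").sum() == 0
    assert harsh_dichotomy(e, "mother").sum() == 0


def test_unreachable_phi_target_errors():
    cfg = SimConfig(n_samples=10, n_variants=4, n_genes=2, parent_phi_target=0.95)
    with pytest.raises(ValueError, match="unreachable"):
        simulate_exposures(cfg, 100)


def test_missing_outcome_rate_and_wave_correlation():
    cfg = SimConfig(n_samples=4000, n_variants=10, n_genes=2, seed=10,
                    missing_outcome_rate=0.07)
    cohort = simulate_cohort(cfg)
    age5 = cohort.phenotypes["externalizing_age5"]
    assert abs(age5.isna().mean() - 0.07) < 0.005
    observed = age5.notna()
    r = np.corrcoef(age5[observed], cohort.phenotypes["externalizing_36m"][observed])[0, 1]
    assert abs(r - cfg.wave_correlation) < 0.08


def test_unknown_effect_snp_named_in_error():
    cfg = SimConfig(n_samples=50, n_variants=10, n_genes=2, seed=1,
                    effect_snps=(("snp99999", 0.3, 0.0),))
    with pytest.raises(ValueError, match="snp99999"):
        simulate_cohort(cfg)


def test_stratum_specific_effect_raises_no_exposure_statistic():
    """With effects only off-exposure, that stratum's set signal dominates."""
    from genesetgxe.geneset import GeneSetPermutationTest
    wins = 0
    reps = 20
    for rep in range(reps):
        cfg = SimConfig(n_samples=500, n_variants=40, n_genes=4, seed=3000 + rep,
                        effect_snps=tuple((f"snp{j:05d}", 0.3, 0.0) for j in range(1, 11)))
        cohort = simulate_cohort(cfg)
        y = cohort.phenotypes["externalizing_age5"].to_numpy()
        e = cohort.truth["father_harsh"]
        ok = ~np.isnan(y)
        members = [f"snp{j:05d}" for j in range(1, 41)]
        ts = {}
        for label, mask in (("noexp", ok & (e == 0)), ("exp", ok & (e == 1))):
            model = GeneSetPermutationTest(
                y[mask], cohort.genotypes.select_samples(mask), members
            )
            ts[label] = model.fit(n_perm=1, seed=0, include_genes=False).set_result.observed_T
        wins += ts["noexp"] > ts["exp"]
    assert wins >= reps * 0.8


def test_table2_fixture_matches_printed_annotation():
    table, counts = dopamine_gene_table()
    drd1 = table.set_index("gene").loc["DRD1"]
    assert (drd1["chrom"], drd1["tss"], drd1["tes"]) == (5, 174_867_675, 174_871_163)
    assert counts["DRD1"] == 2
    assert counts["DDC"] == 32
    assert counts["DRD4"] == 0 and counts["DRD5"] == 0 and counts["DARPP-32"] == 0
    assert counts.sum() == 150  # the VNTR is added manually downstream
    assert (counts > 0).sum() == 11  # 12 genes with variants incl. manual DRD4


def test_synthetic_variant_fixture_respects_boundaries_and_counts():
    table, counts = dopamine_gene_table()
    variants = dopamine_synthetic_variants(seed=3)
    assert len(variants) == 150
    for rec in table.itertuples():
        inside = variants[
            (variants["chrom"] == rec.chrom)
            & (variants["pos"] >= rec.tss)
            & (variants["pos"] <= rec.tes)
        ]
        assert len(inside) >= counts[rec.gene]


def test_write_plink_dataset_roundtrip(tmp_path):
    from genesetgxe.datasets import read_plink
    cfg = SimConfig(n_samples=40, n_variants=12, n_genes=3, seed=2)
    cohort = simulate_cohort(cfg)
    paths = write_plink_dataset(cohort, tmp_path / "cohort")
    back = read_plink(tmp_path / "cohort")
    assert np.array_equal(back.genotypes, cohort.genotypes.genotypes, equal_nan=True)
    for key in ("phenotypes", "exposures", "covariates", "genes"):
        assert paths[key].exists()
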