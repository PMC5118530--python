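import numpy as np
import pandas as pd
import pytest

from famvc.errors import ConfigurationError, DomainError
from famvc.genotypes import maf_bin_summary
from famvc.kinship import pedigree_kinship
from famvc.simdata import (
    DEFAULT_MAF_BINS,
    PedigreeTemplate,
    SimConfig,
    binned_mafs,
    classify_t2d,
    cohort_counts,
    derive_homa_beta,
    derive_homa_ir,
    simulate_genotypes,
    simulate_pedigrees,
    simulate_quantitative_trait,
    simulate_traits,
)

from .conftest import small_config


# ---------------------------------------------------------------- pedigrees


def test_degenerate_template_yields_founder_couples():
    cfg = SimConfig(
        n_pedigrees=3,
        pedigree_template=PedigreeTemplate(n_children=0),
        rng_seed=1,
    )
    ped = simulate_pedigrees(cfg)
    assert ped.n == 6
    assert len(ped.founders()) == 6


def test_invalid_template_rejected():
    with pytest.raises(ConfigurationError):
        PedigreeTemplate(n_children=-1).validate()
    with pytest.raises(ConfigurationError):
        PedigreeTemplate(grandchildren_choices=(-2,)).validate()


def test_pedigree_determinism_under_fixed_seed():
    cfg1 = SimConfig(n_pedigrees=42, rng_seed=1)
    cfg2 = SimConfig(n_pedigrees=42, rng_seed=1)
    p1 = simulate_pedigrees(cfg1)
    p2 = simulate_pedigrees(cfg2)
    pd.testing.assert_frame_equal(p1.table, p2.table)


def test_default_sizing_close_to_target_cohort():
    ped = simulate_pedigrees(SimConfig(n_pedigrees=42, rng_seed=1))
    assert len(ped.families) == 42
    assert abs(ped.n - 1383) <= 0.05 * 1383


def test_pedigree_structure_valid():
    ped = simulate_pedigrees(SimConfig(n_pedigrees=4, rng_seed=5))
    # every non-founder has both parents in the same family; sexes consistent
    fam_of = dict(zip(ped.table.iid, ped.table.fam))
    sex_of = dict(zip(ped.table.iid, ped.table.sex))
    for iid, (f, m) in ped.parents.items():
        if f is None:
            assert m is None
        else:
            assert fam_of[f] == fam_of[iid] == fam_of[m]
            assert sex_of[f] == 1 and sex_of[m] == 2


# ---------------------------------------------------------------- genotypes


def test_genotype_determinism(sim_small):
    cfg = sim_small["config"]
    gm2 = simulate_genotypes(sim_small["pedigree"], cfg)
    np.testing.assert_array_equal(sim_small["genotypes"].dosages, gm2.dosages)


def test_dosages_in_range_and_polymorphic(sim_small):
    d = sim_small["genotypes"].dosages
    assert set(np.unique(d)) <= {0.0, 1.0, 2.0}
    maf = sim_small["genotypes"].maf()
    assert np.all(maf > 0)


def test_mendelian_consistency(sim_small):
    ped, gm = sim_small["pedigree"], sim_small["genotypes"]
    dos = {iid: gm.dosages[i] for i, iid in enumerate(gm.samples)}
    for iid, (f, m) in ped.parents.items():
        if f is None:
            continue
        lo = (dos[f] == 2).astype(int) + (dos[m] == 2).astype(int)
        hi = (dos[f] >= 1).astype(int) + (dos[m] >= 1).astype(int)
        assert np.all(dos[iid] >= lo) and np.all(dos[iid] <= hi)


def test_zero_rho_blocks_give_uncorrelated_founder_pool():
    # all-founder pedigree: template with no offspring
    cfg = SimConfig(
        n_pedigrees=3000,
        pedigree_template=PedigreeTemplate(n_children=0),
        n_snps=12,
        ld_blocks=[(1, 0.0)] * 12,
        maf_spectrum=list(np.linspace(0.2, 0.45, 12)),
        rng_seed=3,
    )
    ped = simulate_pedigrees(cfg)
    gm = simulate_genotypes(ped, cfg)
    C = np.corrcoef(gm.dosages, rowvar=False)
    off = np.abs(C[np.triu_indices(12, 1)])
    assert off.mean() < 0.05


def test_ld_blocks_show_within_block_correlation(sim_small):
    gm = sim_small["genotypes"]
    C = np.corrcoef(gm.dosages, rowvar=False)
    within = [abs(C[i, j]) for i in range(6) for j in range(i + 1, 6)]
    across = [abs(C[i, j]) for i in range(6) for j in range(12, 18)]
    assert np.mean(within) > np.mean(across) + 0.2


def test_monomorphic_maf_rejected():
    cfg = small_config(n_snps=6, maf_spectrum=[0.0, 0.1, 0.2, 0.3, 0.4, 0.2])
    ped = simulate_pedigrees(cfg)
    with pytest.raises(ConfigurationError):
        simulate_genotypes(ped, cfg)


def test_maf_spectrum_bin_fractions():
    mafs = binned_mafs(DEFAULT_MAF_BINS, np.random.default_rng(0))
    summary = maf_bin_summary(mafs)
    assert summary["count"].tolist() == [10, 13, 95]
    assert summary["percent"].tolist() == [8.47, 11.02, 80.51]


def test_realized_mafs_track_spectrum():
    # a large founder pool reproduces the common-SNP fraction of the spectrum
    cfg = SimConfig(n_pedigrees=42, rng_seed=1)
    ped = simulate_pedigrees(cfg)
    gm = simulate_genotypes(ped, cfg)
    frac_common = np.mean(gm.maf() > 0.05)
    assert abs(frac_common - 0.805) < 0.08


# ------------------------------------------------------------------- traits


def test_trait_determinism(sim_small):
    ph2 = simulate_traits(
        sim_small["pedigree"],
        sim_small["genotypes"],
        sim_small["phi"],
        sim_small["config"],
    )
    pd.testing.assert_frame_equal(sim_small["pheno"], ph2)


def test_homa_columns_reproducible(sim_small):
    ph = sim_small["pheno"]
    expect_ir = ph.fasting_glucose * ph.fasting_insulin / 22.5
    np.testing.assert_allclose(ph.homa_ir, expect_ir, rtol=1e-12)
    ok = ph.fasting_glucose > 3.5
    expect_beta = 20.0 * ph.fasting_insulin[ok] / (ph.fasting_glucose[ok] - 3.5)
    np.testing.assert_allclose(ph.homa_beta[ok], expect_beta, rtol=1e-12)
    assert ph.homa_beta[~ok].isna().all()


def test_incident_missing_for_prevalent(sim_small):
    ph = sim_small["pheno"]
    assert ph.loc[ph.prevalent_t2d == 1.0, "incident_t2d"].isna().all()
    assert ph.loc[ph.prevalent_t2d == 0.0, "incident_t2d"].notna().all()
    # ever = prevalent OR incident
    expect = (ph.prevalent_t2d == 1.0) | (ph.incident_t2d == 1.0)
    np.testing.assert_array_equal(ph.ever_t2d.to_numpy(), expect.astype(float))


def test_prevalence_calibration_large_sample():
    # ~3,200 individuals; the quantile threshold makes prevalence near-exact,
    # so this comfortably covers the +/- 0.01 target at a desk-scale n
    cfg = SimConfig(
        n_pedigrees=100,
        rng_seed=2,
        n_snps=6,
        ld_blocks=[(6, 0.5)],
        maf_spectrum=[0.1, 0.2, 0.3, 0.4, 0.25, 0.35],
    )
    ped = simulate_pedigrees(cfg)
    gm = simulate_genotypes(ped, cfg)
    phi = pedigree_kinship(ped)
    ph = simulate_traits(ped, gm, phi, cfg)
    assert ped.n > 3000
    assert abs(ph.prevalent_t2d.mean() - 0.15) < 0.01
    at_risk = ph.incident_t2d.dropna()
    assert abs(at_risk.mean() - 0.163) < 0.01


def test_zero_h2_gives_uncorrelated_relatives(rng):
    cfg = SimConfig(
        n_pedigrees=150,
        pedigree_template=PedigreeTemplate(n_children=2, grandchildren_choices=(0,)),
        rng_seed=5,
    )
    ped = simulate_pedigrees(cfg)
    phi = pedigree_kinship(ped)
    K2 = phi.matrix2()
    sibs = _sib_pairs(ped)
    cors = []
    for _ in range(40):
        y = simulate_quantitative_trait(K2, 0.0, rng)
        a = np.array([y[i] for i, _ in sibs])
        b = np.array([y[j] for _, j in sibs])
        cors.append(np.corrcoef(a, b)[0, 1])
    assert abs(np.mean(cors)) < 0.05


def _sib_pairs(ped):
    index = {iid: i for i, iid in enumerate(ped.ids)}
    by_parents = {}
    for iid, (f, m) in ped.parents.items():
        if f is not None:
            by_parents.setdefault((f, m), []).append(iid)
    pairs = []
    for kids in by_parents.values():
        if len(kids) >= 2:
            pairs.append((index[kids[0]], index[kids[1]]))
    return pairs


def test_sib_correlation_matches_closed_form(rng):
    # 2 * phi_sib * h2 = 2 * 0.25 * 0.6 = 0.30
    cfg = SimConfig(
        n_pedigrees=200,
        pedigree_template=PedigreeTemplate(n_children=2, grandchildren_choices=(0,)),
        rng_seed=6,
    )
    ped = simulate_pedigrees(cfg)
    K2 = pedigree_kinship(ped).matrix2()
    sibs = _sib_pairs(ped)
    assert len(sibs) == 200
    cors = []
    for _ in range(50):
        y = simulate_quantitative_trait(K2, 0.6, rng)
        a = np.array([y[i] for i, _ in sibs])
        b = np.array([y[j] for _, j in sibs])
        cors.append(np.corrcoef(a, b)[0, 1])
    assert np.mean(cors) == pytest.approx(0.30, abs=0.03)


def test_variance_fractions_over_one_rejected(sim_small, rng):
    with pytest.raises(ConfigurationError):
        simulate_quantitative_trait(
            sim_small["phi"].matrix2(),
            0.8,
            rng,
            dosages=sim_small["genotypes"].dosages[:, :2],
            effects=[1.0, 1.0],
        )


# ------------------------------------------------- formulas and accounting


def test_homa_ir_examples():
    assert derive_homa_ir(5.0, 9.0) == pytest.approx(2.0)
    assert derive_homa_ir(22.5, 1.0) == pytest.approx(1.0)
    assert derive_homa_ir(6.3, 0.0) == 0.0


def test_homa_ir_domain():
    with pytest.raises(DomainError):
        derive_homa_ir(0.0, 5.0)
    with pytest.raises(DomainError):
        derive_homa_ir(-1.0, 5.0)


def test_homa_beta_examples():
    assert derive_homa_beta(5.5, 10.0) == pytest.approx(100.0)
    assert derive_homa_beta(4.5, 1.0) == pytest.approx(20.0)


def test_homa_beta_singularity():
    with pytest.raises(DomainError):
        derive_homa_beta(3.5, 10.0)
    with pytest.raises(DomainError):
        derive_homa_beta(2.0, 10.0)


def test_classify_t2d_thresholds():
    assert classify_t2d(6.9, 11.0, False) == 0.0
    assert classify_t2d(7.0, None, False) == 1.0  # boundary inclusive
    assert classify_t2d(5.0, 11.1, False) == 1.0
    assert classify_t2d(5.0, 5.0, True) == 1.0
    assert np.isnan(classify_t2d(None, None, False))
    assert classify_t2d(None, None, True) == 1.0


def test_cohort_counts_validation():
    with pytest.raises(DomainError):
        cohort_counts(100, 150, 50, 10)
    res = cohort_counts(1000, 100, 800, 80)
    assert res["ever_count"] == 180
    assert res["ever_percent"] == 18.0
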