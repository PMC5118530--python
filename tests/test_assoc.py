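import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from famvc.assoc import (
    corrected_threshold,
    dosage_abs_correlation,
    genotype_pcs,
    interaction_scan,
    inverse_normalize,
    li_ji_meff,
    mga_scan,
    ps_score,
    subgroup_fit,
)
from famvc.errors import DimensionError, DomainError, TransformationError
from famvc.genotypes import GenotypeMatrix
from famvc.kinship import KinshipMatrix

from .conftest import unrelated_genotypes


def _unrelated_setup(n=150, seed=5, beta=0.2):
    rng = np.random.default_rng(seed)
    x = rng.binomial(2, 0.3, n).astype(float)
    age = rng.uniform(20, 70, n)
    sex = rng.integers(1, 3, n)
    y = beta * x + rng.standard_normal(n)
    ids = [f"I{i}" for i in range(n)]
    gm = GenotypeMatrix(
        x[:, None],
        ids,
        pd.DataFrame({"snp": ["s1"], "chrom": ["1"], "pos": [100]}),
    )
    phi = KinshipMatrix(0.5 * np.eye(n), ids, "pedigree")
    pheno = pd.DataFrame({"iid": ids, "age": age, "sex": sex, "y": y})
    return gm, phi, pheno


# -------------------------------------------------------- inverse normalize


def test_inverse_normalize_hand_example():
    out = inverse_normalize([1.0, 5.0, 2.0])
    from scipy.stats import norm

    expect = norm.ppf([(1 - 0.375) / 3.25, (3 - 0.375) / 3.25, (2 - 0.375) / 3.25])
    np.testing.assert_allclose(out, expect, atol=1e-4)
    np.testing.assert_allclose(out, [-0.8694, 0.8694, 0.0], atol=2e-4)


def test_inverse_normalize_moments():
    rng = np.random.default_rng(0)
    out = inverse_normalize(rng.exponential(size=500))
    assert abs(out.mean()) < 1e-8
    assert abs(out.std() - 1.0) < 1e-2


def test_inverse_normalize_missing_preserved():
    x = np.array([3.0, np.nan, 1.0, 2.0])
    out = inverse_normalize(x)
    assert np.isnan(out[1])
    assert np.isfinite(out[[0, 2, 3]]).all()


def test_inverse_normalize_improves_normality():
    from scipy.stats import kstest

    rng = np.random.default_rng(1)
    x = rng.gamma(1.5, size=400)
    before = kstest((x - x.mean()) / x.std(), "norm").statistic
    after = kstest(inverse_normalize(x), "norm").statistic
    assert after <= before


def test_inverse_normalize_errors():
    with pytest.raises(TransformationError):
        inverse_normalize([1.0, 2.0])
    with pytest.raises(TransformationError):
        inverse_normalize([3.0, 3.0, 3.0])


@settings(max_examples=30, deadline=None)
@given(
    st.lists(
        st.floats(-1e6, 1e6, allow_nan=False), min_size=4, max_size=40, unique=True
    )
)
def test_inverse_normalize_rank_monotone(values):
    x = np.array(values)
    out = inverse_normalize(x)
    order = np.argsort(x)
    assert np.all(np.diff(out[order]) > 0)


# --------------------------------------------------------------------- PCs


def test_pcs_separate_subpopulations():
    rng = np.random.default_rng(7)
    n = 120
    m = 40
    pop = np.repeat([0, 1], n // 2)
    p = np.where(pop[:, None] == 0, 0.15, 0.65)
    dosages = rng.binomial(2, np.broadcast_to(p, (n, m))).astype(float)
    gm = GenotypeMatrix(
        dosages,
        [f"I{i}" for i in range(n)],
        pd.DataFrame({"snp": [f"s{j}" for j in range(m)], "chrom": "1", "pos": range(m)}),
    )
    pcs = genotype_pcs(gm, 4)
    r = np.corrcoef(pcs[:, 0], pop)[0, 1]
    assert abs(r) > 0.9


def test_pcs_duplicate_individuals_identical_scores():
    gm0 = unrelated_genotypes(30, np.linspace(0.2, 0.45, 10), seed=2)
    dup = np.vstack([gm0.dosages, gm0.dosages[0]])
    gm = GenotypeMatrix(dup, gm0.samples + ["dup"], gm0.snps)
    pcs = genotype_pcs(gm, 3)
    np.testing.assert_allclose(pcs[0], pcs[-1], atol=1e-10)


def test_pcs_dimension_contract():
    gm = unrelated_genotypes(50, np.linspace(0.2, 0.45, 12), seed=3)
    assert genotype_pcs(gm, 4).shape == (50, 4)
    with pytest.raises(DimensionError):
        genotype_pcs(gm, 13)


# -------------------------------------------------------------------- M_eff


def test_meff_identity():
    res = li_ji_meff(np.eye(10))
    assert res.meff == 10
    assert res.meff_raw == pytest.approx(10.0)


def test_meff_perfect_ld():
    res = li_ji_meff(np.ones((10, 10)))
    assert res.meff == 1


def test_meff_two_blocks_closed_form():
    # two independent 5-blocks with rho 0.9: eigenvalues {1+4*0.9} x2, {0.1} x8
    # contributions: 2 * (1 + 0.6) + 8 * 0.1 = 4.0
    C = np.kron(np.eye(2), np.full((5, 5), 0.9) + 0.1 * np.eye(5))
    np.fill_diagonal(C, 1.0)
    res = li_ji_meff(C)
    assert res.meff_raw == pytest.approx(4.0, abs=1e-9)
    assert res.meff == 4


def test_meff_monotone_in_exchangeable_correlation():
    last = np.inf
    for rho in np.linspace(0.0, 0.95, 20):
        C = np.full((12, 12), rho)
        np.fill_diagonal(C, 1.0)
        meff = li_ji_meff(C).meff
        assert meff <= last
        last = meff


def test_meff_rejects_bad_input():
    with pytest.raises(DomainError):
        li_ji_meff(np.arange(9.0).reshape(3, 3))


# --------------------------------------------------------------- thresholds


def test_threshold_values():
    res = corrected_threshold(0.05, 49)
    assert res.per_test_alpha == pytest.approx(0.05 / 49)
    assert round(res.per_test_alpha, 4) == 0.0010
    assert round(res.neglog10, 2) == 2.99


def test_threshold_liberal_alpha():
    assert corrected_threshold(0.2, 49).per_test_alpha == pytest.approx(0.00408, abs=2e-5)


def test_threshold_single_test():
    assert corrected_threshold(0.123, 1).per_test_alpha == pytest.approx(0.123)


def test_threshold_sidak_and_errors():
    sid = corrected_threshold(0.05, 49, method="sidak")
    assert sid.per_test_alpha == pytest.approx(1 - 0.95 ** (1 / 49))
    with pytest.raises(DomainError):
        corrected_threshold(0.05, 0)
    with pytest.raises(DomainError):
        corrected_threshold(1.5, 10)


# ------------------------------------------------------------------ PS score


def test_ps_uniform_contributions():
    ps = ps_score({f"t{i}": 0.1 for i in range(8)})
    assert ps.ps == pytest.approx(8.0)


def test_ps_null_floor():
    assert ps_score({f"t{i}": 1.0 for i in range(8)}).ps == 0.0


def test_ps_threshold_flag():
    res = ps_score({"a": 1e-3, "b": 1e-2}, threshold=4.3010)
    assert res.significant is (res.ps > 4.3010)
    assert res.ps == pytest.approx(5.0)


def test_ps_additivity_over_partition():
    rng = np.random.default_rng(11)
    pvals = {f"t{i}": float(p) for i, p in enumerate(rng.uniform(1e-6, 1, 8))}
    full = ps_score(pvals).ps
    keys = list(pvals)
    part1 = ps_score({k: pvals[k] for k in keys[:3]}).ps
    part2 = ps_score({k: pvals[k] for k in keys[3:]}).ps
    assert full == pytest.approx(part1 + part2, rel=1e-12)


def test_ps_zero_p_clipped_with_warning():
    with pytest.warns(UserWarning):
        res = ps_score({"a": 0.0})
    assert np.isfinite(res.ps)
    with pytest.raises(DomainError):
        ps_score({"a": 1.5})


# ---------------------------------------------------------------- MGA scan


def test_mga_unrelated_limit_matches_ols_lr():
    gm, phi, pheno = _unrelated_setup()
    scan = mga_scan("y", gm, pheno, phi, compute_meff=False)
    yt = inverse_normalize(pheno["y"].to_numpy())
    age = pheno["age"].to_numpy()
    az = (age - age.mean()) / age.std()
    fem = (pheno["sex"].to_numpy() == 2).astype(float)
    X0 = np.column_stack([np.ones(len(az)), az, az**2, fem, az * fem, az**2 * fem])
    X1 = np.column_stack([X0, gm.dosages[:, 0]])
    lr, p, _ = sm.OLS(yt, X1).fit().compare_lr_test(sm.OLS(yt, X0).fit())
    assert scan.table.p[0] == pytest.approx(p, abs=1e-6)
    assert scan.table.beta[0] == pytest.approx(sm.OLS(yt, X1).fit().params[-1], abs=1e-6)


def test_mga_allele_flip_equivariance():
    gm, phi, pheno = _unrelated_setup(seed=9)
    scan1 = mga_scan("y", gm, pheno, phi, compute_meff=False)
    gm_flipped = GenotypeMatrix(2.0 - gm.dosages, gm.samples, gm.snps)
    scan2 = mga_scan("y", gm_flipped, pheno, phi, compute_meff=False)
    assert scan2.table.beta[0] == pytest.approx(-scan1.table.beta[0], abs=1e-5)
    assert scan2.table.p[0] == pytest.approx(scan1.table.p[0], abs=1e-6)


def test_mga_scan_on_pedigree_data(sim_small):
    scan = mga_scan(
        "fasting_glucose",
        sim_small["genotypes"],
        sim_small["pheno"],
        sim_small["phi"],
        genotype_pcs(sim_small["genotypes"], 4),
    )
    t = scan.table
    assert len(t) == sim_small["genotypes"].m
    assert ((t.p > 0) & (t.p <= 1)).all()
    np.testing.assert_allclose(t.neglog10p, -np.log10(t.p), atol=1e-10)
    assert (t.n <= sim_small["pedigree"].n).all()
    assert scan.meff is not None and 1 <= scan.meff.meff <= scan.meff.m


def test_mga_skips_low_n_and_monomorphic(sim_small):
    gm = sim_small["genotypes"]
    dosages = gm.dosages.copy()
    dosages[:, 0] = 0.0  # monomorphic
    dosages[5:, 1] = np.nan  # nearly all missing
    gm2 = GenotypeMatrix(dosages, gm.samples, gm.snps)
    scan = mga_scan(
        "fasting_glucose", gm2, sim_small["pheno"], sim_small["phi"], compute_meff=False
    )
    assert gm.snp_ids[0] in scan.skipped
    assert gm.snp_ids[1] in scan.skipped
    assert len(scan.table) == gm.m - 2


def test_mga_power_at_planted_effect(rng):
    """0.3-SD per-allele effect at MAF ~0.3 and n ~ 1,200: power > 0.8 at
    alpha = 0.001 (10-replicate spot check of the full-scale design)."""
    from famvc.kinship import pedigree_kinship
    from famvc.simdata import (
        SimConfig,
        simulate_genotypes,
        simulate_pedigrees,
        simulate_quantitative_trait,
    )

    cfg = SimConfig(
        rng_seed=17, n_pedigrees=38, n_snps=6, ld_blocks=[(6, 0.4)],
        maf_spectrum=[0.3, 0.2, 0.35, 0.25, 0.3, 0.4],
    )
    ped = simulate_pedigrees(cfg)
    gm = simulate_genotypes(ped, cfg)
    phi = pedigree_kinship(ped)
    K2 = phi.matrix2()
    assert ped.n > 1100
    x = gm.dosages[:, 0]
    hits = 0
    for _ in range(10):
        y = simulate_quantitative_trait(K2, 0.3, rng, covariate_part=0.3 * x)
        pheno = pd.DataFrame(
            {
                "iid": gm.samples,
                "age": rng.uniform(20, 70, len(y)),
                "sex": np.tile([1, 2], len(y))[: len(y)],
                "trait": y,
            }
        )
        scan = mga_scan("trait", gm.subset_snps([gm.snp_ids[0]]), pheno, phi,
                        compute_meff=False)
        hits += scan.table.p[0] < 1e-3
    assert hits >= 8


# -------------------------------------------------------------- interaction


def test_interaction_degenerate_stratum_skipped(sim_small):
    pheno = sim_small["pheno"].copy()
    pheno["age"] = 30.0  # nobody >= 45
    res = interaction_scan(
        "fasting_glucose",
        sim_small["genotypes"],
        pheno,
        sim_small["phi"],
        "age45",
        compute_meff=False,
    )
    assert len(res.table) == 0
    assert "*" in res.skipped


def test_interaction_detects_stratum_specific_effect(sim_mid, rng):
    from famvc.simdata import simulate_quantitative_trait

    gm = sim_mid["genotypes"]
    phi = sim_mid["phi"]
    K2 = phi.matrix2()
    n = gm.n
    age = np.where(np.arange(n) % 2 == 0, 30.0, 55.0) + rng.uniform(-3, 3, n)
    x = gm.dosages[:, 5]
    z = (age >= 45).astype(float)
    y = simulate_quantitative_trait(K2, 0.3, rng, covariate_part=0.5 * x * z)
    pheno = pd.DataFrame(
        {"iid": gm.samples, "age": age, "sex": sim_mid["pedigree"].table["sex"],
         "trait": y}
    )
    res = interaction_scan(
        "trait", gm.subset_snps([gm.snp_ids[5]]), pheno, phi, "age45",
        compute_meff=False,
    )
    assert res.table.p[0] < 0.01


def test_interaction_unknown_modifier(sim_small):
    with pytest.raises(DomainError):
        interaction_scan(
            "fasting_glucose",
            sim_small["genotypes"],
            sim_small["pheno"],
            sim_small["phi"],
            "bmi",
        )


# ----------------------------------------------------------------- subgroup


def test_subgroup_full_sample_matches_scan(sim_small):
    gm = sim_small["genotypes"]
    snp = gm.snp_ids[3]
    scan = mga_scan(
        "fasting_glucose", gm, sim_small["pheno"], sim_small["phi"], compute_meff=False
    )
    row = scan.table.set_index("snp").loc[snp]
    res = subgroup_fit("fasting_glucose", snp, gm, sim_small["pheno"], sim_small["phi"])
    assert res["beta"] == pytest.approx(row.beta, abs=1e-8)
    assert res["p"] == pytest.approx(row.p, abs=1e-8)
    assert res["n"] == row.n


def test_subgroup_partition_accounting(sim_small):
    gm = sim_small["genotypes"]
    snp = gm.snp_ids[0]
    full = subgroup_fit("fasting_glucose", snp, gm, sim_small["pheno"], sim_small["phi"])
    males = subgroup_fit(
        "fasting_glucose", snp, gm, sim_small["pheno"], sim_small["phi"],
        stratum=("sex", "male"),
    )
    females = subgroup_fit(
        "fasting_glucose", snp, gm, sim_small["pheno"], sim_small["phi"],
        stratum=("sex", "female"),
    )
    assert males["n"] + females["n"] == full["n"]


def test_dosage_abs_correlation_unit_diagonal(sim_small):
    C = dosage_abs_correlation(sim_small["genotypes"])
    assert np.allclose(np.diag(C), 1.0)
    assert C.min() >= 0.0
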