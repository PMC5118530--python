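"""Shared simulation-study helpers for calibration and recovery tests."""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np

from famvc.assoc import covariate_design, genotype_pcs, inverse_normalize
from famvc.kinship import empirical_kinship, pedigree_kinship
from famvc.simdata import (
    SimConfig,
    simulate_genotypes,
    simulate_pedigrees,
    simulate_quantitative_trait,
)
from famvc.vcmodels import VarianceModel, fit_ml, lrt, mixture_p
from famvc._cache import cholesky_psd_cached


def build_dataset(
    seed: int,
    n_pedigrees: int = 19,
    n_snps: int = 24,
    unlinked: bool = False,
    with_pcs: bool = True,
) -> SimpleNamespace:
    """Pedigreed dataset with genotypes, kinship and covariate design."""
    if unlinked:
        ld = [(1, 0.0)] * n_snps
        mafs = list(np.linspace(0.1, 0.49, n_snps))
    else:
        ld = [(6, 0.7)] * (n_snps // 6)
        mafs = [(0.05, 0.499, n_snps)]
    cfg = SimConfig(
        rng_seed=seed,
        n_pedigrees=n_pedigrees,
        n_snps=n_snps,
        ld_blocks=ld,
        maf_spectrum=mafs,
    )
    ped = simulate_pedigrees(cfg)
    gm = simulate_genotypes(ped, cfg)
    phi = pedigree_kinship(ped)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 77]))
    n = ped.n
    age = 18.0 + rng.gamma(3.0, 7.0, n)
    sex = ped.table["sex"].to_numpy()
    import pandas as pd

    pheno_base = pd.DataFrame({"iid": ped.ids, "age": age, "sex": sex})
    pcs = genotype_pcs(gm, 4) if with_pcs else None
    X, _ = covariate_design(pheno_base, pcs)
    return SimpleNamespace(
        config=cfg,
        pedigree=ped,
        genotypes=gm,
        phi=phi,
        K2=phi.matrix2(),
        pheno_base=pheno_base,
        X=X,
        age=age,
        n=n,
    )


def mga_null_pvalues(ds, n_reps: int, seed: int, h2: float = 0.3) -> np.ndarray:
    """Type-I simulation of the full measured-genotype pipeline for one SNP.

    Each replicate draws a fresh polygenic trait with no SNP effect (but with
    real covariate effects), applies the inverse-normal transform, and runs
    the covariates-only vs covariates+dosage LRT.
    """
    rng = np.random.default_rng(seed)
    x = ds.genotypes.dosages[:, 0]
    cov_effect = 0.2 * ds.X[:, 1] + 0.1 * ds.X[:, 3]
    ps = np.empty(n_reps)
    for r in range(n_reps):
        y_raw = simulate_quantitative_trait(
            ds.K2, h2, rng, covariate_part=cov_effect
        )
        y = inverse_normalize(y_raw)
        fit0 = fit_ml(VarianceModel(y, ds.X, [ds.K2]))
        fit1 = fit_ml(VarianceModel(y, np.column_stack([ds.X, x]), [ds.K2]))
        ps[r] = lrt(fit1, fit0).p
    return ps


def interaction_null_pvalues(
    ds, n_reps: int, seed: int, h2: float = 0.3, main_effect: float = 0.2
) -> np.ndarray:
    """Interaction LRT under a null with a real (stratum-constant) main effect.

    The most common SNP is used so the dosage x modifier column is well
    populated in both strata (a sparse interaction column degrades the
    chi-square approximation at this sample size).
    """
    rng = np.random.default_rng(seed)
    x = ds.genotypes.dosages[:, int(np.argmax(ds.genotypes.maf()))]
    z = (ds.age >= 45.0).astype(float)
    Xmain = np.column_stack([ds.X, x])
    Xint = np.column_stack([Xmain, x * z])
    ps = np.empty(n_reps)
    for r in range(n_reps):
        y_raw = simulate_quantitative_trait(
            ds.K2, h2, rng, covariate_part=main_effect * x
        )
        y = inverse_normalize(y_raw)
        fit0 = fit_ml(VarianceModel(y, Xmain, [ds.K2]))
        fit1 = fit_ml(VarianceModel(y, Xint, [ds.K2]))
        ps[r] = lrt(fit1, fit0).p
    return ps


def burden_null_stats(ds_unlinked, n_reps: int, seed: int, h2: float = 0.4):
    """Mixture-LRT statistics under h_geff^2 = 0 (polygenic-only traits)."""
    E = empirical_kinship(ds_unlinked.genotypes)
    K2e = 2.0 * E.values
    K1 = ds_unlinked.K2
    rng = np.random.default_rng(seed)
    X = np.ones((ds_unlinked.n, 1))
    stats = np.empty(n_reps)
    for r in range(n_reps):
        y = simulate_quantitative_trait(K1, h2, rng)
        f1 = fit_ml(VarianceModel(y, X, [K1, K2e]), refine_w=False)
        f0 = fit_ml(VarianceModel(y, X, [K1]))
        stats[r] = max(2.0 * (f1.loglik - f0.loglik), 0.0)
    return stats


def burden_null_pvalues(ds_unlinked, n_reps: int, seed: int) -> np.ndarray:
    return np.array(
        [mixture_p(s) for s in burden_null_stats(ds_unlinked, n_reps, seed)]
    )


def simulate_two_component_trait(K1, K2e, h_r2, h_geff2, rng) -> np.ndarray:
    """Trait with polygenic + gene-specific + environmental decomposition."""
    n = K1.shape[0]
    L1 = cholesky_psd_cached(K1)
    L2 = cholesky_psd_cached(K2e)
    e2 = 1.0 - h_r2 - h_geff2
    return (
        np.sqrt(h_r2) * (L1 @ rng.standard_normal(n))
        + np.sqrt(h_geff2) * (L2 @ rng.standard_normal(n))
        + np.sqrt(e2) * rng.standard_normal(n)
    )
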