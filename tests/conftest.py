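import numpy as np
import pandas as pd
import pytest

from famvc.genotypes import GenotypeMatrix
from famvc.kinship import pedigree_kinship
from famvc.pedigree import Pedigree
from famvc.simdata import (
    SimConfig,
    PedigreeTemplate,
    simulate_genotypes,
    simulate_pedigrees,
    simulate_traits,
)


@pytest.fixture(scope="session")
def hand_pedigree() -> Pedigree:
    """Six-member family with full sibs and a half sib, plus one singleton.

    A x B -> C1, C2 (full sibs); A x B2 -> H (half sib of C1/C2).
    """
    rows = [
        ("FAM1", "A", "0", "0", 1),
        ("FAM1", "B", "0", "0", 2),
        ("FAM1", "B2", "0", "0", 2),
        ("FAM1", "C1", "A", "B", 1),
        ("FAM1", "C2", "A", "B", 2),
        ("FAM1", "H", "A", "B2", 1),
        ("FAM2", "Z", "0", "0", 2),
    ]
    return Pedigree(pd.DataFrame(rows, columns=["fam", "iid", "father", "mother", "sex"]))


def small_config(seed=11, n_pedigrees=6, n_snps=24, **kw) -> SimConfig:
    defaults = dict(
        n_pedigrees=n_pedigrees,
        n_snps=n_snps,
        ld_blocks=[(6, 0.7)] * (n_snps // 6),
        maf_spectrum=[(0.05, 0.499, n_snps)],
        rng_seed=seed,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def sim_small():
    """~190 individuals in 6 families with 24 SNPs; full phenotype table."""
    cfg = small_config()
    ped = simulate_pedigrees(cfg)
    gm = simulate_genotypes(ped, cfg)
    phi = pedigree_kinship(ped)
    pheno = simulate_traits(ped, gm, phi, cfg)
    return {"config": cfg, "pedigree": ped, "genotypes": gm, "phi": phi, "pheno": pheno}


@pytest.fixture(scope="session")
def sim_mid():
    """~600 individuals in 19 families; used by the variance-model tests."""
    cfg = small_config(seed=4, n_pedigrees=19)
    ped = simulate_pedigrees(cfg)
    gm = simulate_genotypes(ped, cfg)
    phi = pedigree_kinship(ped)
    return {"config": cfg, "pedigree": ped, "genotypes": gm, "phi": phi}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def unrelated_genotypes(n, mafs, seed=0) -> GenotypeMatrix:
    rng = np.random.default_rng(seed)
    mafs = np.asarray(mafs, dtype=float)
    dosages = rng.binomial(2, mafs, size=(n, len(mafs))).astype(float)
    snps = pd.DataFrame(
        {
            "snp": [f"u{j+1:03d}" for j in range(len(mafs))],
            "chrom": ["1"] * len(mafs),
            "pos": np.arange(1, len(mafs) + 1) * 100,
        }
    )
    return GenotypeMatrix(dosages, [f"I{i:04d}" for i in range(n)], snps)
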