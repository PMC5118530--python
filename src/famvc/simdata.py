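"""Synthetic pedigrees, LD-structured genotypes, covariates and phenotypes.

The generator emulates the statistical structure the downstream analyses
assume: a few dozen extended outbred families, a single ~100 kb locus of
SNPs with block-exchangeable linkage disequilibrium and a wide minor-allele
frequency spectrum, age/sex covariates, quantitative metabolic traits with a
polygenic variance decomposition, and binary disease status generated under
a liability-threshold model.

Everything is driven by :class:`SimConfig`; a fixed ``rng_seed`` makes all
outputs bit-identical across runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._cache import cholesky_psd_cached
from .errors import ConfigurationError, DomainError, StructuralError
from .genotypes import GenotypeMatrix
from .kinship import KinshipMatrix
from .pedigree import MISSING_PARENT, SEX_FEMALE, SEX_MALE, Pedigree

# MAF spectrum with 10 rare (<1%), 13 low-frequency (1-5%) and 95 common
# (>5%) SNPs out of 118, spanning 0.007-0.4989.
DEFAULT_MAF_BINS: tuple[tuple[float, float, int], ...] = (
    (0.007, 0.01, 10),
    (0.01, 0.05, 13),
    (0.05, 0.4989, 95),
)

CONTINUOUS_TRAITS = (
    "fasting_glucose",
    "fasting_insulin",
    "glucose_2h",
    "insulin_2h",
    "homa_ir",
    "homa_beta",
)
BINARY_TRAITS = ("ever_t2d", "incident_t2d")
ALL_TRAITS = BINARY_TRAITS + CONTINUOUS_TRAITS


@dataclass(frozen=True)
class PedigreeTemplate:
    """Three-generation outbred family template.

    A founder couple has ``n_children`` children; each child marries an
    unrelated founder spouse and the couple has a number of children drawn
    uniformly from ``grandchildren_choices``. ``n_children = 0`` degenerates
    to a two-founder family.
    """

    n_children: int = 5
    grandchildren_choices: tuple[int, ...] = (3, 4, 5)
    p_female: float = 0.594

    def validate(self) -> None:
        if self.n_children < 0:
            raise ConfigurationError("n_children must be >= 0")
        if not self.grandchildren_choices or any(
            g < 0 for g in self.grandchildren_choices
        ):
            raise ConfigurationError("grandchildren_choices must be non-negative")
        if not 0.0 <= self.p_female <= 1.0:
            raise ConfigurationError("p_female must be in [0, 1]")


@dataclass
class SimConfig:
    """Full specification of one synthetic dataset."""

    n_pedigrees: int = 42
    pedigree_template: PedigreeTemplate = field(default_factory=PedigreeTemplate)
    n_snps: int = 118
    ld_blocks: list[tuple[int, float]] | None = None  # (block size, latent rho)
    maf_spectrum: object = DEFAULT_MAF_BINS  # bins spec or explicit MAF array
    h2_polygenic: float = 0.35
    qtn_effects: dict[str, float] = field(default_factory=dict)
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {
            "age": 0.15,
            "age2": 0.05,
            "sex": 0.10,
            "age_sex": 0.0,
            "age2_sex": 0.0,
        }
    )
    prevalence_baseline: float = 0.15
    prevalence_incident: float = 0.163
    mean_age: float = 39.17
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_pedigrees < 1:
            raise ConfigurationError("n_pedigrees must be >= 1")
        self.pedigree_template.validate()
        if self.n_snps < 1:
            raise ConfigurationError("n_snps must be >= 1")
        for frac, name in (
            (self.h2_polygenic, "h2_polygenic"),
            (self.prevalence_baseline, "prevalence_baseline"),
            (self.prevalence_incident, "prevalence_incident"),
        ):
            if not 0.0 <= frac < 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1)")
        for size, rho in self.resolved_ld_blocks():
            if size < 1:
                raise ConfigurationError("LD block sizes must be >= 1")
            if not 0.0 <= rho < 1.0:
                raise ConfigurationError("LD block rho must be in [0, 1)")

    def resolved_ld_blocks(self) -> list[tuple[int, float]]:
        if self.ld_blocks is not None:
            if sum(s for s, _ in self.ld_blocks) != self.n_snps:
                raise ConfigurationError("LD block sizes must sum to n_snps")
            return list(self.ld_blocks)
        return default_ld_blocks(self.n_snps)

    def resolved_mafs(self, rng: np.random.Generator) -> np.ndarray:
        spec = self.maf_spectrum
        if isinstance(spec, (list, tuple)) and spec and np.isscalar(spec[0]):
            mafs = np.asarray(spec, dtype=float)
        elif isinstance(spec, np.ndarray):
            mafs = spec.astype(float)
        else:
            mafs = binned_mafs(spec, rng)
        if len(mafs) != self.n_snps:
            raise ConfigurationError(
                f"maf spectrum yields {len(mafs)} values for {self.n_snps} SNPs"
            )
        if np.any(mafs <= 0.0) or np.any(mafs > 0.5):
            raise ConfigurationError("MAF values must lie in (0, 0.5]")
        return mafs


def default_ld_blocks(
    n_snps: int, block_size: int = 8, rho: float = 0.8
) -> list[tuple[int, float]]:
    """Contiguous blocks of ``block_size`` SNPs sharing latent correlation rho."""
    blocks = []
    left = n_snps
    while left > 0:
        s = min(block_size, left)
        blocks.append((s, rho))
        left -= s
    return blocks


def binned_mafs(
    bins=DEFAULT_MAF_BINS, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Draw a MAF spectrum with exact per-bin counts, uniform within bins."""
    rng = rng or np.random.default_rng(0)
    parts = []
    for lo, hi, count in bins:
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError("MAF bin edges must satisfy 0 < lo <= hi <= 0.5")
        if count < 0:
            raise ConfigurationError("MAF bin counts must be non-negative")
        parts.append(rng.uniform(lo, hi, size=count))
    mafs = np.concatenate(parts) if parts else np.array([])
    return rng.permutation(mafs)


# ---------------------------------------------------------------------------
# pedigrees
# ---------------------------------------------------------------------------


def simulate_pedigrees(config: SimConfig) -> Pedigree:
    """Generate ``n_pedigrees`` independent families from the template."""
    config.validate()
    tpl = config.pedigree_template
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 1]))
    rows = []

    def sex_draw() -> int:
        return SEX_FEMALE if rng.random() < tpl.p_female else SEX_MALE

    for f in range(1, config.n_pedigrees + 1):
        fam = f"F{f:03d}"
        counter = 0

        def new_id() -> str:
            nonlocal counter
            counter += 1
            return f"{fam}-{counter:03d}"

        father0, mother0 = new_id(), new_id()
        rows.append((fam, father0, MISSING_PARENT, MISSING_PARENT, SEX_MALE))
        rows.append((fam, mother0, MISSING_PARENT, MISSING_PARENT, SEX_FEMALE))
        for _ in range(tpl.n_children):
            child = new_id()
            child_sex = sex_draw()
            rows.append((fam, child, father0, mother0, child_sex))
            spouse = new_id()
            spouse_sex = SEX_MALE if child_sex == SEX_FEMALE else SEX_FEMALE
            rows.append((fam, spouse, MISSING_PARENT, MISSING_PARENT, spouse_sex))
            dad, mom = (child, spouse) if child_sex == SEX_MALE else (spouse, child)
            n_grand = int(rng.choice(tpl.grandchildren_choices))
            for _ in range(n_grand):
                rows.append((fam, new_id(), dad, mom, sex_draw()))

    table = pd.DataFrame(rows, columns=["fam", "iid", "father", "mother", "sex"])
    return Pedigree(table)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def _founder_haplotypes(
    n_haps: int, mafs: np.ndarray, blocks: list[tuple[int, float]], rng
) -> np.ndarray:
    """Haplotype pool via a Gaussian copula with block-exchangeable correlation.

    Each haplotype draws one shared latent factor per LD block; SNP k carries
    the minor allele when its latent value falls below the MAF quantile.
    """
    m = len(mafs)
    z = np.empty((n_haps, m))
    start = 0
    for size, rho in blocks:
        shared = rng.standard_normal((n_haps, 1))
        eps = rng.standard_normal((n_haps, size))
        z[:, start : start + size] = math.sqrt(rho) * shared + math.sqrt(1 - rho) * eps
        start += size
    thresholds = norm.ppf(mafs)
    return (z < thresholds).astype(np.int8)


def simulate_genotypes(pedigree: Pedigree, config: SimConfig) -> GenotypeMatrix:
    """Founder haplotypes from the copula pool, then whole-haplotype dropping.

    Each non-founder inherits one complete parental haplotype per parent
    (no within-locus recombination: the locus spans ~100 kb, so transmitted
    haplotypes are effectively intact), which preserves the founder LD
    structure down the pedigree. Mendelian transmission therefore holds at
    every SNP by construction.

    SNPs that end up monomorphic among founders are redrawn (independently,
    outside the block copula) until polymorphic.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 2]))
    mafs = config.resolved_mafs(rng)
    blocks = config.resolved_ld_blocks()

    order = pedigree.topological_order()
    parents = pedigree.parents
    founders = [i for i in order if parents[i] == (None, None)]
    n_f = len(founders)

    pool = _founder_haplotypes(2 * n_f, mafs, blocks, rng)
    # guarantee founder-pool polymorphism (founders are part of the sample,
    # so this guarantees sample polymorphism as well)
    for _ in range(100):
        counts = pool.sum(axis=0)
        bad = np.where((counts == 0) | (counts == 2 * n_f))[0]
        if len(bad) == 0:
            break
        z = rng.standard_normal((2 * n_f, len(bad)))
        pool[:, bad] = (z < norm.ppf(mafs[bad])).astype(np.int8)
    else:  # pragma: no cover - astronomically unlikely for valid configs
        raise ConfigurationError("could not realize polymorphic founder pool")

    haps: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    next_pool = iter(range(2 * n_f))
    for iid in order:
        f, m = parents[iid]
        if f is None and m is None:
            haps[iid] = (pool[next(next_pool)], pool[next(next_pool)])
        elif f is None or m is None:
            raise StructuralError(f"individual {iid!r} has exactly one parent")
        else:
            hf = haps[f][rng.integers(2)]
            hm = haps[m][rng.integers(2)]
            haps[iid] = (hf, hm)

    samples = pedigree.ids
    dosages = np.array(
        [haps[i][0] + haps[i][1] for i in samples], dtype=float
    )
    m = len(mafs)
    snps = pd.DataFrame(
        {
            "snp": [f"snp{j+1:04d}" for j in range(m)],
            "chrom": ["8"] * m,
            "pos": (1_000_000 + 850 * np.arange(m)).astype(int),
        }
    )
    return GenotypeMatrix(dosages, list(samples), snps)


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------


def simulate_quantitative_trait(
    kinship: KinshipMatrix | np.ndarray,
    h2: float,
    rng: np.random.Generator,
    *,
    dosages: np.ndarray | None = None,
    effects: np.ndarray | None = None,
    covariate_part: np.ndarray | None = None,
    family_blocks: list[np.ndarray] | None = None,
) -> np.ndarray:
    """One standardized trait with the additive variance decomposition.

    ``y = covariate_part + X_qtn @ effects + g + e`` where ``g`` has
    covariance ``h2 * 2Phi`` and the residual absorbs what the polygenic and
    QTN parts leave of the unit variance. Raises
    :class:`ConfigurationError` when the genetic fractions reach 1.

    ``family_blocks`` (lists of row indices of mutually unrelated groups)
    lets the polygenic draw factor the kinship block-by-block, which is much
    faster on large multi-family pedigrees where 2*Phi is block diagonal.
    """
    K2 = kinship.matrix2() if isinstance(kinship, KinshipMatrix) else np.asarray(kinship)
    n = K2.shape[0]
    if not 0.0 <= h2 < 1.0:
        raise ConfigurationError("h2 must be in [0, 1)")

    qtn_part = np.zeros(n)
    qtn_var = 0.0
    if dosages is not None and effects is not None:
        dosages = np.atleast_2d(np.asarray(dosages, dtype=float))
        if dosages.shape[0] == n and dosages.shape[1] != n:
            pass
        elif dosages.shape[1] == n:
            dosages = dosages.T
        effects = np.asarray(effects, dtype=float).ravel()
        centred = dosages - dosages.mean(axis=0)
        qtn_part = centred @ effects
        qtn_var = float(np.sum((effects**2) * centred.var(axis=0)))

    e2 = 1.0 - h2 - qtn_var
    if e2 <= 0.0:
        raise ConfigurationError(
            f"variance fractions sum to >= 1 (h2={h2}, qtn={qtn_var:.3f})"
        )

    if family_blocks is not None:
        g = np.empty(n)
        for idx in family_blocks:
            L = cholesky_psd_cached(K2[np.ix_(idx, idx)])
            g[idx] = L @ rng.standard_normal(len(idx))
        g *= math.sqrt(h2)
    else:
        L = cholesky_psd_cached(K2)
        g = math.sqrt(h2) * (L @ rng.standard_normal(n))
    e = math.sqrt(e2) * rng.standard_normal(n)
    y = qtn_part + g + e
    if covariate_part is not None:
        y = y + np.asarray(covariate_part, dtype=float)
    return y


def _liability_status(liability: np.ndarray, prevalence: float) -> np.ndarray:
    """Threshold a liability at the quantile matching the target prevalence."""
    if len(liability) == 0:
        return np.zeros(0)
    cut = np.quantile(liability, 1.0 - prevalence)
    return (liability > cut).astype(float)


def simulate_traits(
    pedigree: Pedigree,
    genotypes: GenotypeMatrix,
    kinship: KinshipMatrix,
    config: SimConfig,
) -> pd.DataFrame:
    """Phenotype/covariate table for every pedigree member.

    Continuous metabolic traits are monotone maps of standardized latent
    traits sharing the configured variance decomposition; the insulin-based
    measures are log-normal to mimic their right skew. Binary status uses a
    liability threshold at the configured baseline prevalence, and incident
    status applies a second threshold within the initially unaffected set.
    Derived indices are reproducible from the stored glucose/insulin columns
    through :func:`derive_homa_ir` / :func:`derive_homa_beta`.
    """
    config.validate()
    if kinship.ids != pedigree.ids:
        kinship = kinship.subset(pedigree.ids)
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 3]))
    n = pedigree.n

    age = 18.0 + rng.gamma(shape=3.0, scale=(config.mean_age - 18.0) / 3.0, size=n)
    sex = pedigree.table["sex"].to_numpy()
    female = (sex == SEX_FEMALE).astype(float)

    age_z = (age - age.mean()) / age.std()
    age2_z = (age_z**2 - np.mean(age_z**2)) / np.std(age_z**2)
    ce = config.covariate_effects
    covariate_part = (
        ce.get("age", 0.0) * age_z
        + ce.get("age2", 0.0) * age2_z
        + ce.get("sex", 0.0) * female
        + ce.get("age_sex", 0.0) * age_z * female
        + ce.get("age2_sex", 0.0) * age2_z * female
    )

    qtn_x = qtn_b = None
    if config.qtn_effects:
        ids = list(config.qtn_effects)
        qtn_x = genotypes.subset_snps(ids).dosages
        qtn_b = np.array([config.qtn_effects[s] for s in ids])

    fams = pedigree.table["fam"].to_numpy()
    blocks = [np.where(fams == f)[0] for f in pd.unique(fams)]

    def latent() -> np.ndarray:
        return simulate_quantitative_trait(
            kinship,
            config.h2_polygenic,
            rng,
            dosages=qtn_x,
            effects=qtn_b,
            covariate_part=covariate_part,
            family_blocks=blocks,
        )

    z_fg, z_fi, z_2hg, z_2hi = (latent() for _ in range(4))
    fasting_glucose = 4.82 + 0.65 * z_fg
    glucose_2h = 5.61 + 1.30 * z_2hg
    fasting_insulin = np.exp(2.30 + 0.55 * z_fi)
    insulin_2h = np.exp(3.80 + 0.80 * z_2hi)

    homa_ir = np.where(
        fasting_glucose > 0, fasting_glucose * fasting_insulin / 22.5, np.nan
    )
    homa_beta = np.where(
        fasting_glucose > 3.5,
        20.0 * fasting_insulin / (fasting_glucose - 3.5),
        np.nan,
    )

    liab_prev = latent()
    prevalent = _liability_status(liab_prev, config.prevalence_baseline)
    at_risk = prevalent == 0.0
    liab_inc = latent()
    incident = np.full(n, np.nan)
    incident[at_risk] = _liability_status(
        liab_inc[at_risk], config.prevalence_incident
    )
    ever = np.where(prevalent == 1.0, 1.0, np.nan_to_num(incident, nan=0.0))
    medication = np.where(
        (prevalent == 1.0) & (rng.random(n) < 0.3), 1.0, 0.0
    )

    return pd.DataFrame(
        {
            "iid": pedigree.ids,
            "fam": pedigree.table["fam"].to_numpy(),
            "age": age,
            "sex": sex,
            "prevalent_t2d": prevalent,
            "incident_t2d": incident,
            "ever_t2d": ever,
            "fasting_glucose": fasting_glucose,
            "fasting_insulin": fasting_insulin,
            "glucose_2h": glucose_2h,
            "insulin_2h": insulin_2h,
            "homa_ir": homa_ir,
            "homa_beta": homa_beta,
            "medication_flag": medication,
        }
    )


# ---------------------------------------------------------------------------
# trait-derivation formulas and cohort accounting
# ---------------------------------------------------------------------------


def derive_homa_ir(fasting_glucose: float, fasting_insulin: float) -> float:
    """Insulin-resistance index: glucose [mmol/L] x insulin [uU/mL] / 22.5."""
    if not fasting_glucose > 0:
        raise DomainError("fasting glucose must be positive")
    if fasting_insulin < 0:
        raise DomainError("fasting insulin must be non-negative")
    return fasting_glucose * fasting_insulin / 22.5


def derive_homa_beta(fasting_glucose: float, fasting_insulin: float) -> float:
    """Beta-cell function index: 20 x insulin / (glucose - 3.5).

    Undefined (singular) at glucose <= 3.5 mmol/L.
    """
    if not fasting_glucose > 3.5:
        raise DomainError("fasting glucose must exceed 3.5 mmol/L")
    if fasting_insulin < 0:
        raise DomainError("fasting insulin must be non-negative")
    return 20.0 * fasting_insulin / (fasting_glucose - 3.5)


def classify_t2d(
    fasting_glucose: float | None,
    glucose_2h: float | None,
    on_medication: bool | None,
) -> float:
    """Diabetes status from glucose criteria and medication use.

    Positive (1.0) when fasting glucose >= 7.0 mmol/L, 2-hour glucose >=
    11.1 mmol/L, or antidiabetic medication is in use; both thresholds are
    inclusive. Without any glucose measurement a negative status cannot be
    asserted: the result is NaN unless medication use makes it positive.
    """

    def val(x):
        if x is None:
            return None
        x = float(x)
        return None if math.isnan(x) else x

    fg, g2 = val(fasting_glucose), val(glucose_2h)
    med = bool(on_medication) if on_medication is not None else False
    if med:
        return 1.0
    if fg is not None and fg >= 7.0:
        return 1.0
    if g2 is not None and g2 >= 11.1:
        return 1.0
    if fg is None and g2 is None:
        return float("nan")
    return 0.0


def cohort_counts(
    n_baseline: int, n_prevalent: int, n_followed: int, n_incident: int
) -> dict[str, float]:
    """Ever-affected accounting from prevalent and incident counts.

    Combines baseline-prevalent cases with incident cases detected among the
    followed-up (initially unaffected) subset and reports the percentages on
    their respective denominators, rounded to two decimals.
    """
    if min(n_baseline, n_prevalent, n_followed, n_incident) < 0:
        raise DomainError("counts must be non-negative")
    if n_prevalent > n_baseline or n_incident > n_followed:
        raise DomainError("case counts exceed their denominators")
    ever = n_prevalent + n_incident
    return {
        "ever_count": ever,
        "ever_percent": round(100.0 * ever / n_baseline, 2),
        "prevalent_percent": round(100.0 * n_prevalent / n_baseline, 2),
        "incident_percent": round(100.0 * n_incident / n_followed, 2),
    }
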