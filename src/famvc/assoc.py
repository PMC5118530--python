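"""Per-SNP association layer.

Implements the measured-genotype scan: each SNP's additive dosage enters a
polygenic variance-components model as a fixed effect alongside the standard
covariate set (age, age^2, sex, age x sex, age^2 x sex, top genotype PCs) and
is tested with a 1-df likelihood-ratio test against the covariates-only
model. Supporting machinery: rank-based inverse-normal transformation,
genotype principal components, the eigenvalue-based effective number of
independent tests, per-test significance thresholds, a cross-trait summary
probability score, and genotype x age/sex interaction scans with subgroup
refits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from ._cache import array_key
from .errors import (
    DimensionError,
    DomainError,
    EstimationError,
    TransformationError,
)
from .genotypes import GenotypeMatrix
from .kinship import KinshipMatrix
from .vcmodels import VarianceModel, VCFit, fit_ml, lrt

log = logging.getLogger(__name__)

MIN_COMPLETE_CASES = 30
AGE_CUT = 45.0

COVARIATE_NAMES = ("intercept", "age", "age2", "sex", "age_sex", "age2_sex")


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------


@dataclass
class MEffResult:
    """Effective number of independent tests from an LD correlation matrix."""

    m: int
    eigenvalues: np.ndarray = field(repr=False)
    meff_raw: float = 0.0
    meff: int = 0


@dataclass
class ThresholdResult:
    global_alpha: float
    m_eff: int
    per_test_alpha: float
    neglog10: float
    method: str = "bonferroni"


@dataclass
class PSResult:
    """Cross-trait summary probability score for one SNP."""

    ps: float
    contributions: dict[str, float]
    threshold: float | None = None

    @property
    def significant(self) -> bool | None:
        if self.threshold is None:
            return None
        return self.ps > self.threshold


@dataclass
class ScanResult:
    """Per-SNP association table plus scan-level multiplicity quantities."""

    trait: str
    table: pd.DataFrame = field(repr=False)
    meff: MEffResult | None = None
    threshold: ThresholdResult | None = None
    skipped: dict[str, str] = field(default_factory=dict)


@dataclass
class InteractionResult:
    trait: str
    modifier: str
    table: pd.DataFrame = field(repr=False)
    meff: MEffResult | None = None
    threshold: ThresholdResult | None = None
    skipped: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# transformations and covariates
# ---------------------------------------------------------------------------


def inverse_normalize(values) -> np.ndarray:
    """Rank-based inverse-normal transform with Blom offsets.

    Non-missing entries are mapped to ``Phi^-1((r - 3/8) / (n + 1/4))`` using
    average ranks for ties; missing entries stay missing. The result is a
    monotone function of the input ranks with mean ~0 and SD ~1.
    """
    x = np.asarray(values, dtype=float)
    out = np.full(x.shape, np.nan)
    mask = np.isfinite(x)
    n = int(mask.sum())
    if n < 3:
        raise TransformationError("need at least 3 non-missing values")
    if np.nanstd(x[mask]) == 0:
        raise TransformationError("cannot inverse-normalize a constant vector")
    r = rankdata(x[mask], method="average")
    out[mask] = norm.ppf((r - 0.375) / (n + 0.25))
    return out


def genotype_pcs(genotypes: GenotypeMatrix, k: int = 4) -> np.ndarray:
    """Top-k principal components of the column-standardized dosage matrix.

    Missing dosages are mean-imputed before standardization. Scores are
    unit-norm columns ordered by decreasing eigenvalue, with a deterministic
    sign convention (largest-magnitude loading positive).
    """
    X = genotypes.dosages.copy()
    col_mean = np.nanmean(X, axis=0)
    nan_at = np.isnan(X)
    if nan_at.any():
        X[nan_at] = np.take(col_mean, np.nonzero(nan_at)[1])
    sd = X.std(axis=0)
    keep = sd > 1e-12
    X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    n, m_kept = X.shape
    if m_kept < k:
        raise DimensionError(f"only {m_kept} polymorphic SNPs for k={k} components")
    if n <= k:
        raise DimensionError(f"n={n} samples cannot support k={k} components")
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-10)) if len(s) else 0
    if rank < k:
        raise DimensionError(f"dosage matrix rank {rank} below requested k={k}")
    scores = U[:, :k]
    flip = np.sign(scores[np.argmax(np.abs(scores), axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    return scores * flip


def covariate_design(
    phenotypes: pd.DataFrame, pcs: np.ndarray | None = None
) -> tuple[np.ndarray, list[str]]:
    """Standard fixed-effect design: intercept, age terms, sex, and PCs.

    Age enters standardized (the LRTs are invariant to this affine
    rescaling, which only improves conditioning). Sex is a female indicator
    from the 1/2 pedigree coding.
    """
    age = phenotypes["age"].to_numpy(dtype=float)
    female = (phenotypes["sex"].to_numpy() == 2).astype(float)
    mu, sd = np.nanmean(age), np.nanstd(age)
    az = (age - mu) / (sd if sd > 0 else 1.0)
    cols = [np.ones(len(age)), az, az**2, female, az * female, (az**2) * female]
    names = list(COVARIATE_NAMES)
    if pcs is not None:
        pcs = np.atleast_2d(np.asarray(pcs, dtype=float))
        if pcs.shape[0] != len(age):
            raise DimensionError("PC rows do not match phenotype rows")
        for j in range(pcs.shape[1]):
            cols.append(pcs[:, j])
            names.append(f"pc{j+1}")
    return np.column_stack(cols), names


def _drop_constant(X: np.ndarray, names: list[str]):
    """Drop non-intercept columns with zero variance (e.g. sex in a stratum)."""
    keep = [0] + [
        j for j in range(1, X.shape[1]) if np.std(X[:, j]) > 1e-12
    ]
    return X[:, keep], [names[j] for j in keep]


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------


def li_ji_meff(dosage_correlation: np.ndarray) -> MEffResult:
    """Effective test count from the eigenvalues of the |correlation| matrix.

    Each eigenvalue lambda contributes ``I(lambda >= 1) + (lambda -
    floor(lambda))``; the contributions are summed and floored to an integer
    test count.
    """
    C = np.asarray(dosage_correlation, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise DomainError("correlation matrix must be square")
    if not np.allclose(C, C.T, atol=1e-8):
        raise DomainError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(C), 1.0, atol=1e-6):
        raise DomainError("correlation matrix must have unit diagonal")
    lam = np.linalg.eigvalsh(np.abs(C))
    lam = np.clip(lam, 0.0, None)
    contrib = (lam >= 1.0).astype(float) + (lam - np.floor(lam))
    raw = float(np.sum(contrib))
    return MEffResult(
        m=C.shape[0],
        eigenvalues=lam[::-1].copy(),
        meff_raw=raw,
        meff=int(np.floor(raw + 1e-9)),
    )


def corrected_threshold(
    global_alpha: float, m_eff: int, method: str = "bonferroni"
) -> ThresholdResult:
    """Per-test significance level for ``m_eff`` effective independent tests."""
    if not 0.0 < global_alpha < 1.0:
        raise DomainError("global alpha must be in (0, 1)")
    if m_eff < 1:
        raise DomainError("m_eff must be >= 1")
    if method == "bonferroni":
        per_test = global_alpha / m_eff
    elif method == "sidak":
        per_test = 1.0 - (1.0 - global_alpha) ** (1.0 / m_eff)
    else:
        raise DomainError(f"unknown correction method {method!r}")
    return ThresholdResult(
        global_alpha=global_alpha,
        m_eff=m_eff,
        per_test_alpha=per_test,
        neglog10=float(-np.log10(per_test)),
        method=method,
    )


def ps_score(pvalues: dict[str, float], threshold: float | None = None) -> PSResult:
    """Summary probability score: sum of -log10 p over the trait set."""
    contributions = {}
    tiny = np.nextafter(0.0, 1.0)
    for trait, p in pvalues.items():
        if not np.isfinite(p) or p < 0 or p > 1:
            raise DomainError(f"p-value for {trait!r} outside [0, 1]: {p}")
        if p == 0.0:
            warnings.warn(
                f"p = 0 for trait {trait!r}: clipped to the smallest positive float"
            )
            p = tiny
        contributions[trait] = float(-np.log10(p))
    return PSResult(
        ps=float(sum(contributions.values())),
        contributions=contributions,
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# scans
# ---------------------------------------------------------------------------


def is_binary_trait(values: np.ndarray) -> bool:
    obs = np.unique(values[np.isfinite(values)])
    return len(obs) <= 2 and np.all(np.isin(obs, (0.0, 1.0)))


def _prepare_trait(
    trait: str,
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    phi: KinshipMatrix,
    pcs: np.ndarray | None,
):
    """Align everything on the genotype sample order; build y, X, K, mask."""
    pheno = phenotypes.set_index("iid").loc[genotypes.samples].reset_index()
    y_raw = pheno[trait].to_numpy(dtype=float)
    binary = is_binary_trait(y_raw)
    X, names = covariate_design(pheno, pcs)
    mask = np.isfinite(y_raw) & np.all(np.isfinite(X), axis=1)
    y = y_raw.copy()
    if not binary:
        y[~mask] = np.nan
        y = inverse_normalize(y)
        mask &= np.isfinite(y)
    K = phi.subset(genotypes.samples).matrix2()
    return y, X, names, K, mask, binary


def _null_fit_cache(y, X, K):
    cache: dict[str, VCFit] = {}

    def null_for(mask: np.ndarray) -> VCFit:
        key = array_key(mask.astype(np.int8))
        if key not in cache:
            idx = np.where(mask)[0]
            cache[key] = fit_ml(
                VarianceModel(y[idx], X[idx], [K[np.ix_(idx, idx)]], names=["poly"])
            )
        return cache[key]

    return null_for


def mga_scan(
    trait: str,
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    phi: KinshipMatrix,
    pcs: np.ndarray | None = None,
    *,
    global_alpha: float = 0.05,
    min_n: int = MIN_COMPLETE_CASES,
    compute_meff: bool = True,
) -> ScanResult:
    """Measured-genotype association scan of every SNP against one trait.

    Continuous traits are inverse-normalized on the analyzed subset first.
    Each SNP is tested by a 1-df LRT between the polygenic model with and
    without its dosage term; the dosage coefficient B is reported in
    transformed-trait SD units per allele. SNPs monomorphic in the analyzed
    subset or with fewer than ``min_n`` complete cases are skipped with a
    logged reason.
    """
    y, X, names, K, mask0, _ = _prepare_trait(trait, genotypes, phenotypes, phi, pcs)
    null_for = _null_fit_cache(y, X, K)

    rows, skipped = [], {}
    for j, snp in enumerate(genotypes.snp_ids):
        x = genotypes.dosages[:, j]
        mask = mask0 & np.isfinite(x)
        n = int(mask.sum())
        if n < min_n:
            skipped[snp] = f"only {n} complete cases"
            log.info("skipping %s: %s", snp, skipped[snp])
            continue
        p_allele = x[mask].mean() / 2.0
        maf = min(p_allele, 1.0 - p_allele)
        if maf <= 0.0:
            skipped[snp] = "monomorphic in analyzed subset"
            log.info("skipping %s: %s", snp, skipped[snp])
            continue
        idx = np.where(mask)[0]
        Ksub = K[np.ix_(idx, idx)]
        fit0 = null_for(mask)
        Xfull = np.column_stack([X[idx], x[idx]])
        fit1 = fit_ml(VarianceModel(y[idx], Xfull, [Ksub], names=["poly"]))
        res = lrt(fit1, fit0, df=1)
        p = max(res.p, np.nextafter(0.0, 1.0))
        rows.append(
            {
                "snp": snp,
                "chrom": genotypes.snps["chrom"].iloc[j],
                "pos": genotypes.snps["pos"].iloc[j],
                "maf": maf,
                "n": n,
                "beta": float(fit1.beta[-1]),
                "se": float(fit1.beta_se[-1]),
                "lrt": res.stat,
                "p": p,
                "neglog10p": float(-np.log10(p)),
            }
        )

    table = pd.DataFrame(
        rows,
        columns=[
            "snp", "chrom", "pos", "maf", "n", "beta", "se", "lrt", "p", "neglog10p",
        ],
    )
    meff = threshold = None
    if compute_meff and len(table) >= 2:
        meff = li_ji_meff(dosage_abs_correlation(genotypes, list(table["snp"])))
        threshold = corrected_threshold(global_alpha, max(meff.meff, 1))
    return ScanResult(
        trait=trait, table=table, meff=meff, threshold=threshold, skipped=skipped
    )


def dosage_abs_correlation(
    genotypes: GenotypeMatrix, snp_ids: list[str] | None = None
) -> np.ndarray:
    """Absolute-value composite-LD correlation matrix of dosage columns."""
    gm = genotypes if snp_ids is None else genotypes.subset_snps(snp_ids)
    X = gm.dosages.copy()
    col_mean = np.nanmean(X, axis=0)
    nan_at = np.isnan(X)
    if nan_at.any():
        X[nan_at] = np.take(col_mean, np.nonzero(nan_at)[1])
    with np.errstate(invalid="ignore"):
        C = np.corrcoef(X, rowvar=False)
    C = np.nan_to_num(C, nan=0.0)
    np.fill_diagonal(C, 1.0)
    return np.abs(C)


def interaction_scan(
    trait: str,
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    phi: KinshipMatrix,
    modifier: str,
    pcs: np.ndarray | None = None,
    *,
    global_alpha: float = 0.2,
    min_n: int = MIN_COMPLETE_CASES,
    compute_meff: bool = True,
) -> InteractionResult:
    """Genotype x modifier interaction scan (modifier: ``age45`` or ``sex``).

    Age is binarized at 45 years; sex uses the female indicator. The
    interaction p comes from a 1-df LRT constraining the dosage x modifier
    product to zero in the measured-genotype model. Scans with an empty or
    undersized modifier stratum are skipped with a reason, not an error.
    """
    y, X, names, K, mask0, _ = _prepare_trait(trait, genotypes, phenotypes, phi, pcs)
    pheno = phenotypes.set_index("iid").loc[genotypes.samples].reset_index()
    if modifier == "age45":
        z = (pheno["age"].to_numpy(dtype=float) >= AGE_CUT).astype(float)
    elif modifier == "sex":
        z = (pheno["sex"].to_numpy() == 2).astype(float)
    else:
        raise DomainError(f"unknown modifier {modifier!r}; use 'age45' or 'sex'")

    rows, skipped = [], {}
    strata_ok = True
    n0 = int(np.sum(mask0 & (z == 0.0)))
    n1 = int(np.sum(mask0 & (z == 1.0)))
    if n0 < min_n or n1 < min_n:
        strata_ok = False
        reason = f"modifier strata sizes {n0}/{n1} below {min_n}"
        log.warning("interaction scan for %s skipped: %s", trait, reason)
        skipped["*"] = reason

    if strata_ok:
        for j, snp in enumerate(genotypes.snp_ids):
            x = genotypes.dosages[:, j]
            mask = mask0 & np.isfinite(x)
            n = int(mask.sum())
            if n < min_n:
                skipped[snp] = f"only {n} complete cases"
                continue
            idx = np.where(mask)[0]
            Ksub = K[np.ix_(idx, idx)]
            Xmain = np.column_stack([X[idx], x[idx]])
            Xint = np.column_stack([Xmain, x[idx] * z[idx]])
            fit0 = fit_ml(VarianceModel(y[idx], Xmain, [Ksub], names=["poly"]))
            fit1 = fit_ml(VarianceModel(y[idx], Xint, [Ksub], names=["poly"]))
            res = lrt(fit1, fit0, df=1)
            p = max(res.p, np.nextafter(0.0, 1.0))
            rows.append(
                {
                    "snp": snp,
                    "modifier": modifier,
                    "n": n,
                    "beta_interaction": float(fit1.beta[-1]),
                    "se": float(fit1.beta_se[-1]),
                    "lrt": res.stat,
                    "p": p,
                    "neglog10p": float(-np.log10(p)),
                }
            )

    table = pd.DataFrame(
        rows,
        columns=[
            "snp", "modifier", "n", "beta_interaction", "se", "lrt", "p", "neglog10p",
        ],
    )
    meff = threshold = None
    if compute_meff and len(table) >= 2:
        meff = li_ji_meff(dosage_abs_correlation(genotypes, list(table["snp"])))
        threshold = corrected_threshold(global_alpha, max(meff.meff, 1))
    return InteractionResult(
        trait=trait,
        modifier=modifier,
        table=table,
        meff=meff,
        threshold=threshold,
        skipped=skipped,
    )


def subgroup_fit(
    trait: str,
    snp: str,
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    phi: KinshipMatrix,
    stratum: tuple[str, str] | None = None,
    pcs: np.ndarray | None = None,
    *,
    min_n: int = MIN_COMPLETE_CASES,
) -> dict:
    """Measured-genotype fit of one SNP within a modifier stratum.

    ``stratum`` is ``(modifier, level)`` with modifier ``age45`` (levels
    ``"<45"``/``">=45"``) or ``sex`` (``"male"``/``"female"``); ``None``
    means the full sample. Returns B, SE, p and n; a singular in-stratum
    design is flagged rather than fatal.
    """
    pheno = phenotypes.set_index("iid").loc[genotypes.samples].reset_index()
    keep = np.ones(len(pheno), dtype=bool)
    if stratum is not None:
        modifier, level = stratum
        if modifier == "age45":
            age = pheno["age"].to_numpy(dtype=float)
            keep = age >= AGE_CUT if level in (">=45", "ge45") else age < AGE_CUT
        elif modifier == "sex":
            female = pheno["sex"].to_numpy() == 2
            keep = female if level == "female" else ~female
        else:
            raise DomainError(f"unknown modifier {modifier!r}")

    sample_ids = [s for s, k in zip(genotypes.samples, keep) if k]
    if len(sample_ids) < min_n:
        return {"snp": snp, "trait": trait, "n": len(sample_ids), "flag": "undersized"}
    gm = genotypes.subset_samples(sample_ids)
    sub_pheno = pheno[keep].reset_index(drop=True)
    sub_pcs = pcs[keep] if pcs is not None else None

    y, X, names, K, mask0, _ = _prepare_trait(trait, gm, sub_pheno, phi, sub_pcs)
    X, names = _drop_constant(X, names)
    x = gm.column(snp)
    mask = mask0 & np.isfinite(x)
    n = int(mask.sum())
    if n < min_n:
        return {"snp": snp, "trait": trait, "n": n, "flag": "undersized"}
    idx = np.where(mask)[0]
    Ksub = K[np.ix_(idx, idx)]
    try:
        fit0 = fit_ml(VarianceModel(y[idx], X[idx], [Ksub], names=["poly"]))
        Xfull = np.column_stack([X[idx], x[idx]])
        fit1 = fit_ml(VarianceModel(y[idx], Xfull, [Ksub], names=["poly"]))
        res = lrt(fit1, fit0, df=1)
    except (np.linalg.LinAlgError, EstimationError) as exc:
        return {"snp": snp, "trait": trait, "n": n, "flag": f"singular: {exc}"}
    return {
        "snp": snp,
        "trait": trait,
        "stratum": stratum,
        "n": n,
        "beta": float(fit1.beta[-1]),
        "se": float(fit1.beta_se[-1]),
        "p": float(res.p),
        "flag": "",
    }
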