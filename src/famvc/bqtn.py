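"""Exhaustive SNP-subset model search scored by a likelihood-ratio BIC.

For a candidate set of s SNPs every one of the 2^s subsets (including the
empty null) enters the measured-genotype model jointly; model k is scored by

    BIC_k = -Lambda_k0 + df_k * ln(N_e)

where Lambda_k0 is the LRT statistic of model k against the covariates-only
polygenic null, df_k the number of SNP terms, and N_e the effective sample
size (defaulting to the complete-case count). The null model scores 0 by
definition; the best model minimizes BIC, and the "window" collects models
that beat the null.

Sub-model log-likelihoods are cached across the enumeration, which makes
each drop-one per-SNP test a pair of table lookups.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.stats import chi2

from .errors import ConfigurationError, DomainError
from .genotypes import GenotypeMatrix
from .kinship import KinshipMatrix
from .vcmodels import VarianceModel, fit_ml

from .assoc import _prepare_trait

log = logging.getLogger(__name__)

MAX_EXHAUSTIVE_SNPS = 20


@dataclass
class BQTNModel:
    """One scored SNP-subset model."""

    subset: tuple[str, ...]
    loglik: float
    lrt_stat: float  # vs the covariates-only null
    df: int
    bic: float
    snp_pvalues: dict[str, float] = field(default_factory=dict)
    weight: float | None = None
    rank_deficient: bool = False


@dataclass
class BQTNReport:
    """Best-model selection summary for one trait."""

    trait: str
    h_r2: float
    n_e: float
    n_used: int
    n_models: int
    best: BQTNModel
    delta_bic_vs_null: float
    window: list[tuple[str, ...]]
    models: list[BQTNModel] = field(repr=False, default_factory=list)

    @property
    def n_window(self) -> int:
        return len(self.window)


def enumerate_models(
    snps: list[str], cap: int = MAX_EXHAUSTIVE_SNPS
) -> list[tuple[str, ...]]:
    """All 2^s subsets of the candidate SNPs, deterministically ordered.

    Ordering is by subset size, then by position in the input list. Refuses
    more than ``cap`` SNPs: the search is exhaustive by design, so larger
    candidate sets should be pre-screened (e.g. by the cross-trait summary
    score) before entering it.
    """
    snps = list(snps)
    if len(set(snps)) != len(snps):
        raise ConfigurationError("candidate SNP list contains duplicates")
    if len(snps) > cap:
        raise ConfigurationError(
            f"{len(snps)} SNPs exceed the exhaustive-search cap of {cap}; "
            "pre-screen the candidate set before model search"
        )
    out: list[tuple[str, ...]] = []
    for size in range(len(snps) + 1):
        out.extend(combinations(snps, size))
    return out


class BQTNContext:
    """Shared fitting state for scoring subsets of one candidate SNP set.

    Builds the aligned response/design/kinship once, fits the covariates-only
    polygenic null, and memoizes the log-likelihood of every subset model it
    is asked to fit.
    """

    def __init__(
        self,
        trait: str,
        snps: list[str],
        genotypes: GenotypeMatrix,
        phenotypes,
        phi: KinshipMatrix,
        pcs: np.ndarray | None = None,
        n_e: float | None = None,
    ):
        self.trait = trait
        self.snps = list(snps)
        y, X, names, K, mask, _ = _prepare_trait(
            trait, genotypes, phenotypes, phi, pcs
        )
        dos = genotypes.subset_snps(self.snps).dosages
        mask = mask & np.all(np.isfinite(dos), axis=1)
        idx = np.where(mask)[0]
        self.y = y[idx]
        self.X = X[idx]
        self.K = K[np.ix_(idx, idx)]
        self.dosages = dos[idx]
        self.n_used = len(idx)
        self.n_e = float(n_e) if n_e is not None else float(self.n_used)
        self._loglik: dict[frozenset, float] = {}
        self._flags: dict[frozenset, bool] = {}
        null_fit = fit_ml(VarianceModel(self.y, self.X, [self.K], names=["poly"]))
        self.null_loglik = null_fit.loglik
        self.h_r2 = null_fit.fractions[0]
        self._loglik[frozenset()] = null_fit.loglik

    def loglik(self, subset) -> float:
        key = frozenset(subset)
        if key not in self._loglik:
            cols = [self.snps.index(s) for s in subset]
            Xk = np.column_stack([self.X, self.dosages[:, cols]])
            rank_def = np.linalg.matrix_rank(Xk) < Xk.shape[1]
            fit = fit_ml(VarianceModel(self.y, Xk, [self.K], names=["poly"]))
            self._loglik[key] = fit.loglik
            self._flags[key] = rank_def
            if rank_def:
                log.warning("collinear SNP subset %s: reduced-rank design", subset)
        return self._loglik[key]

    def rank_deficient(self, subset) -> bool:
        return self._flags.get(frozenset(subset), False)


def score_model(subset, ctx: BQTNContext) -> BQTNModel:
    """Score one subset: BIC vs the null plus drop-one per-SNP p-values."""
    subset = tuple(subset)
    ll = ctx.loglik(subset)
    stat = max(2.0 * (ll - ctx.null_loglik), 0.0)
    df = len(subset)
    bic = -stat + df * math.log(ctx.n_e)
    pvals = {}
    for s in subset:
        reduced = tuple(x for x in subset if x != s)
        drop_stat = max(2.0 * (ll - ctx.loglik(reduced)), 0.0)
        pvals[s] = float(chi2.sf(drop_stat, 1))
    return BQTNModel(
        subset=subset,
        loglik=ll,
        lrt_stat=stat,
        df=df,
        bic=float(bic),
        snp_pvalues=pvals,
        rank_deficient=ctx.rank_deficient(subset),
    )


def select_best(
    models: list[BQTNModel],
    window_rule: str | float = "below_null",
) -> tuple[BQTNModel, list[tuple[str, ...]]]:
    """Pick the minimum-BIC model and the window of competitive models.

    Tie-break on equal BIC: fewer SNPs, then lexicographic subset. The
    default window contains non-null models with BIC strictly below the
    null's (0); a float rule keeps models within that BIC distance of the
    best. BIC weights ``w_k ~ exp(-BIC_k / 2)`` are written onto the models.
    """
    if not models:
        raise DomainError("no scored models to select from")
    best = min(models, key=lambda m: (m.bic, m.df, m.subset))
    bics = np.array([m.bic for m in models])
    w = np.exp(-(bics - bics.min()) / 2.0)
    w /= w.sum()
    for m, wk in zip(models, w):
        m.weight = float(wk)
    if window_rule == "below_null":
        window = [m.subset for m in models if m.df > 0 and m.bic < 0.0]
    else:
        delta = float(window_rule)
        window = [
            m.subset for m in models if m.df > 0 and m.bic <= best.bic + delta
        ]
    return best, window


def run_bqtn(
    trait: str,
    snps: list[str],
    genotypes: GenotypeMatrix,
    phenotypes,
    phi: KinshipMatrix,
    pcs: np.ndarray | None = None,
    *,
    n_e: float | None = None,
    window_rule: str | float = "below_null",
    keep_models: bool = True,
) -> BQTNReport:
    """Exhaustive BQTN search for one trait over the candidate SNP set."""
    subsets = enumerate_models(snps)
    ctx = BQTNContext(trait, snps, genotypes, phenotypes, phi, pcs, n_e=n_e)
    models = [score_model(sub, ctx) for sub in subsets]
    best, window = select_best(models, window_rule)
    log.info("scored %d models for trait %s", len(models), trait)
    return BQTNReport(
        trait=trait,
        h_r2=float(ctx.h_r2),
        n_e=ctx.n_e,
        n_used=ctx.n_used,
        n_models=len(models),
        best=best,
        delta_bic_vs_null=float(best.bic),
        window=window,
        models=models if keep_models else [],
    )
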