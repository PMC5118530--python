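"""Kinship matrices: theoretical (from pedigree) and empirical (from dosages).

Both are returned on the kinship-coefficient scale, i.e. an outbred
individual has diagonal 0.5 and a parent-offspring pair 0.25, so that twice
the matrix is the expected additive genetic relationship matrix used by the
variance-components engine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import EstimationError, ModelError
from .genotypes import GenotypeMatrix
from .pedigree import Pedigree

log = logging.getLogger(__name__)


@dataclass
class KinshipMatrix:
    """Symmetric n x n matrix of kinship coefficients with an id index."""

    values: np.ndarray = field(repr=False)
    ids: list[str]
    source: str  # "pedigree" | "empirical"
    snps: list[str] | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ModelError("kinship matrix must be square")
        if v.shape[0] != len(self.ids):
            raise ModelError("id index does not match matrix dimension")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ModelError("kinship matrix must be symmetric")
        self.values = (v + v.T) / 2.0

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def matrix2(self) -> np.ndarray:
        """2x kinship: the expected additive relationship matrix."""
        return 2.0 * self.values

    def subset(self, ids: list[str]) -> "KinshipMatrix":
        index = {s: i for i, s in enumerate(self.ids)}
        unknown = [s for s in ids if s not in index]
        if unknown:
            raise KeyError(f"ids not in kinship index: {unknown[:5]}")
        rows = np.array([index[s] for s in ids])
        return KinshipMatrix(
            self.values[np.ix_(rows, rows)], list(ids), self.source, self.snps
        )

    def pair(self, a: str, b: str) -> float:
        ia, ib = self.ids.index(a), self.ids.index(b)
        return float(self.values[ia, ib])


def pedigree_kinship(pedigree: Pedigree) -> KinshipMatrix:
    """Kinship coefficients from pedigree structure by the tabular recursion.

    Individuals are processed parents-first; for individual ``i`` with parents
    (f, m):

    * ``phi(i, i) = 0.5 * (1 + phi(f, m))`` (missing parents contribute 0),
    * ``phi(i, j) = 0.5 * (phi(f, j) + phi(m, j))`` for every earlier ``j``.

    Founders are mutually unrelated; individuals in different families have
    kinship 0 (the per-family blocks are computed independently).
    """
    order = pedigree.topological_order()
    parents = pedigree.parents
    fam_of = dict(zip(pedigree.table["iid"], pedigree.table["fam"]))

    want = pedigree.ids
    full_pos = {iid: k for k, iid in enumerate(want)}
    n = len(want)
    phi_full = np.zeros((n, n))

    # families are mutually unrelated: fill one dense block per family
    by_family: dict[str, list[str]] = {}
    for iid in order:
        by_family.setdefault(fam_of[iid], []).append(iid)

    for members in by_family.values():
        pos = {iid: k for k, iid in enumerate(members)}
        nf = len(members)
        phi = np.zeros((nf, nf))
        for i, i_id in enumerate(members):
            f, m = parents[i_id]
            fi = pos[f] if f is not None else None
            mi = pos[m] if m is not None else None
            phi_fm = phi[fi, mi] if fi is not None and mi is not None else 0.0
            phi[i, i] = 0.5 * (1.0 + phi_fm)
            row = np.zeros(i)
            if fi is not None:
                row += 0.5 * phi[fi, :i]
            if mi is not None:
                row += 0.5 * phi[mi, :i]
            phi[i, :i] = row
            phi[:i, i] = row
        idx = np.array([full_pos[iid] for iid in members])
        phi_full[np.ix_(idx, idx)] = phi

    return KinshipMatrix(phi_full, want, source="pedigree")


def empirical_kinship(
    genotypes: GenotypeMatrix,
    snp_subset: list[str] | None = None,
    *,
    freq_from: str = "all",
    founder_ids: list[str] | None = None,
    grm_style: str = "standardized",
    condition: bool = True,
) -> KinshipMatrix:
    """Empirical kinship from SNP dosages (allele-frequency scaled GRM / 2).

    For the ``standardized`` style with subset SNPs k = 1..m and sample
    frequencies p_k of the counted allele::

        E_ij = (1 / 2m) * sum_k (x_ik - 2 p_k)(x_jk - 2 p_k) / (2 p_k (1 - p_k))

    so 2E lives on the same scale as the pedigree relationship matrix 2*Phi.
    The ``covariance`` dialect replaces the per-SNP standardization by a
    single average-heterozygosity scaling.

    Missing dosages are mean-imputed. Monomorphic SNPs in the subset are
    dropped with a warning; an all-monomorphic subset raises
    :class:`EstimationError`. If numerical noise produces a negative
    eigenvalue, the smallest ridge restoring PSD is added (logged).
    """
    gm = genotypes if snp_subset is None else genotypes.subset_snps(list(snp_subset))
    X = gm.dosages.copy()
    # mean imputation of missing genotypes (documented policy)
    col_mean = np.nanmean(X, axis=0)
    nan_at = np.isnan(X)
    if nan_at.any():
        X[nan_at] = np.take(col_mean, np.nonzero(nan_at)[1])

    if freq_from == "founders":
        if not founder_ids:
            raise ModelError("freq_from='founders' requires founder_ids")
        rows = [gm.samples.index(s) for s in founder_ids]
        p = X[rows].mean(axis=0) / 2.0
    elif freq_from == "all":
        p = X.mean(axis=0) / 2.0
    else:
        raise ModelError(f"unknown freq_from {freq_from!r}")

    poly = (p > 0.0) & (p < 1.0)
    n_mono = int(np.sum(~poly))
    if n_mono:
        log.warning("excluding %d monomorphic SNP(s) from empirical kinship", n_mono)
    if not poly.any():
        raise EstimationError("all SNPs in the subset are monomorphic")
    X = X[:, poly]
    p = p[poly]
    m = X.shape[1]

    centred = X - 2.0 * p
    if grm_style == "standardized":
        Z = centred / np.sqrt(2.0 * p * (1.0 - p))
        E = (Z @ Z.T) / (2.0 * m)
    elif grm_style == "covariance":
        het = np.mean(2.0 * p * (1.0 - p))
        E = (centred @ centred.T) / (2.0 * m * het)
    else:
        raise ModelError(f"unknown grm_style {grm_style!r}")

    if condition:
        lam_min = float(np.linalg.eigvalsh(E)[0])
        if lam_min < -1e-10:
            delta = -lam_min + 1e-10
            log.info("ridge-conditioning empirical kinship: +%.3e * I", delta)
            E = E + delta * np.eye(E.shape[0])

    used = list(np.asarray(gm.snp_ids)[poly])
    return KinshipMatrix(E, list(gm.samples), source="empirical", snps=used)
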