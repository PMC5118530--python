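"""Additive SNP dosage matrix with per-SNP metadata."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DimensionError

MAF_BIN_EDGES = (0.01, 0.05)  # rare (<1%), low-frequency (1-5%), common (>5%)


@dataclass
class GenotypeMatrix:
    """n individuals x m SNPs matrix of additive dosages on the 0-2 scale.

    ``dosages`` may contain NaN for missing genotypes. ``snps`` carries one
    row per SNP (columns ``snp``, ``chrom``, ``pos``; positions are 1-based).
    """

    dosages: np.ndarray = field(repr=False)
    samples: list[str]
    snps: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise DimensionError("dosage matrix must be 2-D")
        n, m = self.dosages.shape
        if len(self.samples) != n:
            raise DimensionError(f"{len(self.samples)} sample ids for {n} rows")
        if len(self.snps) != m:
            raise DimensionError(f"{len(self.snps)} SNP records for {m} columns")
        self.snps = self.snps.reset_index(drop=True)

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return list(self.snps["snp"])

    def allele_freq(self) -> np.ndarray:
        """Frequency of the counted (dosage) allele, per SNP."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Folded minor allele frequency, per SNP."""
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    # ------------------------------------------------------------- subsetting
    def subset_snps(self, snp_ids: list[str]) -> "GenotypeMatrix":
        index = {s: j for j, s in enumerate(self.snps["snp"])}
        unknown = [s for s in snp_ids if s not in index]
        if unknown:
            raise KeyError(f"unknown SNP ids: {unknown[:5]}")
        cols = [index[s] for s in snp_ids]
        return GenotypeMatrix(
            self.dosages[:, cols], list(self.samples), self.snps.iloc[cols]
        )

    def subset_samples(self, sample_ids: list[str]) -> "GenotypeMatrix":
        index = {s: i for i, s in enumerate(self.samples)}
        unknown = [s for s in sample_ids if s not in index]
        if unknown:
            raise KeyError(f"unknown sample ids: {unknown[:5]}")
        rows = [index[s] for s in sample_ids]
        return GenotypeMatrix(self.dosages[rows], list(sample_ids), self.snps)

    def column(self, snp_id: str) -> np.ndarray:
        j = self.snp_ids.index(snp_id)
        return self.dosages[:, j]


def maf_bin_summary(
    mafs: np.ndarray | list[float], edges: tuple[float, float] = MAF_BIN_EDGES
) -> pd.DataFrame:
    """Summarize a minor-allele-frequency spectrum into frequency bins.

    Returns a table with one row per bin (``< edges[0]``, ``edges[0]-edges[1]``,
    ``> edges[1]``) giving the SNP count and its percentage of the total,
    rounded to two decimals.
    """
    mafs = np.asarray(mafs, dtype=float)
    if mafs.ndim != 1 or len(mafs) == 0:
        raise DimensionError("maf spectrum must be a non-empty 1-D array")
    lo, hi = edges
    counts = [
        int(np.sum(mafs < lo)),
        int(np.sum((mafs >= lo) & (mafs <= hi))),
        int(np.sum(mafs > hi)),
    ]
    total = len(mafs)
    labels = [f"<{lo:g}", f"{lo:g}-{hi:g}", f">{hi:g}"]
    return pd.DataFrame(
        {
            "bin": labels,
            "count": counts,
            "percent": [round(100.0 * c / total, 2) for c in counts],
        }
    )
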