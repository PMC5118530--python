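"""Readers and writers for the pipeline's plain-text file formats.

Formats: FAM-style pedigree TSV, dosage TSV (individuals x SNPs), VCF 4.2
with a per-genotype DS field (1-based positions), headered phenotype CSV
with ``NA`` as the missing token, and labeled kinship-matrix TSV. Lines
starting with ``#`` before the header row carry provenance and are ignored
on read.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from ..errors import ParseError, ReconciliationError
from ..genotypes import GenotypeMatrix
from ..kinship import KinshipMatrix
from ..pedigree import COLUMNS, Pedigree

log = logging.getLogger(__name__)

NA_TOKEN = "NA"


def _write_with_header(path, text_lines, provenance: list[str] | None):
    with open(path, "w") as fh:
        for line in provenance or []:
            fh.write(f"# {line}\n")
        for line in text_lines:
            fh.write(line + "\n")


# ------------------------------------------------------------------ pedigree


def read_pedigree(path) -> Pedigree:
    """Read a FAM-style TSV (fam, iid, father, mother, sex; 0 = missing parent).

    Parsing is order-independent: children may be listed before their
    parents. Duplicate individual ids are reported with their line numbers.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: pedigree file lacks columns {missing}")
    dup = df["iid"].duplicated(keep=False)
    if dup.any():
        lines = (df.index[dup] + 2).tolist()  # 1-based, after header
        raise ParseError(f"{path}: duplicate individual ids at lines {lines[:6]}")
    df["sex"] = df["sex"].astype(int)
    return Pedigree(df)


def write_pedigree(pedigree: Pedigree, path, provenance: list[str] | None = None):
    lines = ["\t".join(COLUMNS)]
    for row in pedigree.table.itertuples(index=False):
        lines.append(f"{row.fam}\t{row.iid}\t{row.father}\t{row.mother}\t{row.sex}")
    _write_with_header(path, lines, provenance)


# ----------------------------------------------------------------- genotypes


def read_genotypes(path, fmt: str | None = None) -> GenotypeMatrix:
    """Read genotypes from VCF (``.vcf``) or a dosage TSV (anything else)."""
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix == ".vcf" else "dosage_tsv"
    if fmt == "vcf":
        return read_vcf(path)
    if fmt == "dosage_tsv":
        return read_dosage_tsv(path)
    raise ParseError(f"unknown genotype format {fmt!r}")


def read_vcf(path) -> GenotypeMatrix:
    """VCF 4.2 reader: DS field when present, else GT summed to dosage.

    Multi-allelic records are rejected (counted and logged). Positions are
    kept 1-based as in the file.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, snp_ids, chroms, poss = [], [], [], []
    n_multi = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_multi += 1
            continue
        try:
            ds = variant.format("DS")
        except KeyError:  # DS absent from the header entirely
            ds = None
        if ds is not None:
            dosage = np.asarray(ds, dtype=float).ravel()
            dosage = np.where((dosage < 0) | (dosage > 2), np.nan, dosage)
        else:
            # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
            gt = variant.gt_types
            dosage = np.choose(gt, [0.0, 1.0, np.nan, 2.0])
        rows.append(dosage)
        snp_ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        chroms.append(str(variant.CHROM))
        poss.append(int(variant.POS))
    vcf.close()
    if n_multi:
        log.warning("rejected %d multi-allelic record(s)", n_multi)
    if not rows:
        raise ParseError(f"{path}: no usable biallelic records")
    snps = pd.DataFrame({"snp": snp_ids, "chrom": chroms, "pos": poss})
    return GenotypeMatrix(np.array(rows).T, samples, snps)


def write_vcf(genotypes: GenotypeMatrix, path, provenance: list[str] | None = None):
    """Write a VCF 4.2 with GT (rounded) and DS (exact dosage) per genotype."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for line in provenance or []:
            fh.write(f"##famvc={line}\n")
        for chrom in dict.fromkeys(genotypes.snps["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Additive dosage">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.samples)
            + "\n"
        )
        gts = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j in range(genotypes.m):
            rec = genotypes.snps.iloc[j]
            cells = []
            for d in genotypes.dosages[:, j]:
                if np.isnan(d):
                    cells.append("./.:.")
                else:
                    cells.append(f"{gts.get(int(round(d)), './.')}:{d:g}")
            fh.write(
                f"{rec.chrom}\t{int(rec.pos)}\t{rec.snp}\tA\tG\t.\t.\t.\tGT:DS\t"
                + "\t".join(cells)
                + "\n"
            )


def read_dosage_tsv(path) -> GenotypeMatrix:
    """Headered dosage TSV: first column ``iid``, one column per SNP."""
    df = pd.read_csv(path, sep="\t", comment="#", na_values=[NA_TOKEN])
    if df.columns[0] != "iid":
        raise ParseError(f"{path}: first column of a dosage TSV must be 'iid'")
    samples = df["iid"].astype(str).tolist()
    snp_ids = list(df.columns[1:])
    dosages = df[snp_ids].to_numpy(dtype=float)
    if np.nanmin(dosages, initial=0) < 0 or np.nanmax(dosages, initial=0) > 2:
        raise ParseError(f"{path}: dosages outside the 0-2 scale")
    snps = pd.DataFrame(
        {"snp": snp_ids, "chrom": ["?"] * len(snp_ids), "pos": np.arange(1, len(snp_ids) + 1)}
    )
    return GenotypeMatrix(dosages, samples, snps)


def write_dosage_tsv(
    genotypes: GenotypeMatrix, path, provenance: list[str] | None = None
):
    lines = ["\t".join(["iid"] + genotypes.snp_ids)]
    for i, s in enumerate(genotypes.samples):
        vals = [
            NA_TOKEN if np.isnan(d) else f"{d:g}" for d in genotypes.dosages[i]
        ]
        lines.append("\t".join([s] + vals))
    _write_with_header(path, lines, provenance)


def reconcile_samples(genotypes: GenotypeMatrix, pedigree: Pedigree) -> None:
    """Raise if genotype sample ids do not match the pedigree ids."""
    g, p = set(genotypes.samples), set(pedigree.ids)
    if g != p:
        offenders = sorted(g.symmetric_difference(p))
        raise ReconciliationError(
            f"sample ids disagree between genotypes and pedigree: {offenders[:8]}"
        )


# ---------------------------------------------------------------- phenotypes


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", na_values=[NA_TOKEN])
    if "iid" not in df.columns:
        raise ParseError(f"{path}: phenotype CSV must have an 'iid' column")
    df["iid"] = df["iid"].astype(str)
    return df


def write_phenotypes(df: pd.DataFrame, path, provenance: list[str] | None = None):
    with open(path, "w") as fh:
        for line in provenance or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, na_rep=NA_TOKEN, float_format="%.10g")


# ------------------------------------------------------------------- kinship


def read_kinship_tsv(path, source: str = "pedigree") -> KinshipMatrix:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    ids = [str(i) for i in df.index]
    if list(map(str, df.columns)) != ids:
        raise ParseError(f"{path}: kinship row and column labels disagree")
    return KinshipMatrix(df.to_numpy(dtype=float), ids, source=source)


def write_kinship_tsv(
    kinship: KinshipMatrix, path, provenance: list[str] | None = None
):
    lines = ["\t".join(["id"] + kinship.ids)]
    for i, s in enumerate(kinship.ids):
        vals = [f"{v:.10g}" for v in kinship.values[i]]
        lines.append("\t".join([s] + vals))
    _write_with_header(path, lines, provenance)


# --------------------------------------------------------------- result I/O


def write_table(df: pd.DataFrame, path, provenance: list[str] | None = None):
    """Result table as TSV with a provenance comment header."""
    with open(path, "w") as fh:
        for line in provenance or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep=NA_TOKEN, float_format="%.6g")
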