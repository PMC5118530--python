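"""End-to-end orchestration of the analysis stages.

Stage order: data (simulate or load) -> pedigree kinship -> genotype PCs ->
per-trait measured-genotype scans -> effective-test correction -> cross-trait
summary score and candidate-SNP selection -> genotype x age/sex interaction
scans -> exhaustive subset model search on the candidate set -> locus burden
panel. Every output file carries a provenance header (package version, seed,
config digest) sufficient to reproduce it; stages never mutate earlier
outputs, and a fixed seed makes the whole result tree byte-identical across
runs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from contextlib import contextmanager
from pathlib import Path

import pandas as pd

from .. import __version__
from ..assoc import (
    corrected_threshold,
    genotype_pcs,
    interaction_scan,
    mga_scan,
    ps_score,
)
from ..bqtn import run_bqtn
from ..burden import burden_panel
from ..errors import FamvcError
from ..kinship import pedigree_kinship
from ..simdata import simulate_genotypes, simulate_pedigrees, simulate_traits
from . import io
from .config import RunConfig

log = logging.getLogger(__name__)


class StageError(FamvcError):
    """Failure inside a named pipeline stage; earlier outputs are retained."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@contextmanager
def _stage(name: str):
    """Tag any failure with the stage it occurred in; partial outputs remain."""
    try:
        yield
    except StageError:
        raise
    except Exception as exc:
        raise StageError(name, exc) from exc


def run_pipeline(config: RunConfig, out_dir, seed: int) -> dict:
    """Execute all configured stages; returns the run summary (also on disk)."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = [
        f"famvc={__version__}",
        f"seed={seed}",
        f"config_sha256={config.digest()}",
    ]
    summary: dict = {
        "provenance": {
            "famvc": __version__,
            "seed": seed,
            "config_sha256": config.digest(),
            "config": dataclasses.asdict(config),
        }
    }

    # ------------------------------------------------------------------ data
    with _stage("data"):
        if config.simulate is not None:
            sim = config.sim_config(seed)
            pedigree = simulate_pedigrees(sim)
            genotypes = simulate_genotypes(pedigree, sim)
            phi = pedigree_kinship(pedigree)
            phenotypes = simulate_traits(pedigree, genotypes, phi, sim)
            io.write_pedigree(pedigree, out / "pedigree.fam", prov)
            io.write_vcf(genotypes, out / "genotypes.vcf", prov)
            io.write_dosage_tsv(genotypes, out / "dosages.tsv", prov)
            io.write_phenotypes(phenotypes, out / "phenotypes.csv", prov)
        else:
            pedigree = io.read_pedigree(config.pedigree)
            genotypes = io.read_genotypes(config.genotypes)
            io.reconcile_samples(genotypes, pedigree)
            phenotypes = io.read_phenotypes(config.phenotypes)
            phi = pedigree_kinship(pedigree)
        io.write_kinship_tsv(phi, out / "kinship_pedigree.tsv", prov)
        summary["n_individuals"] = pedigree.n
        summary["n_snps"] = genotypes.m

        pcs = None
        if config.n_pcs > 0 and genotypes.m >= config.n_pcs:
            pcs = genotype_pcs(genotypes, k=config.n_pcs)

    # ------------------------------------------------------------- MGA scans
    with _stage("mga"):
        scans = {}
        pvalues_by_snp: dict[str, dict[str, float]] = {}
        for trait in config.traits:
            scan = mga_scan(
                trait, genotypes, phenotypes, phi, pcs, global_alpha=config.mga_alpha
            )
            scans[trait] = scan
            io.write_table(scan.table, out / f"mga_{trait}.tsv", prov)
            for row in scan.table.itertuples(index=False):
                pvalues_by_snp.setdefault(row.snp, {})[trait] = row.p
        first = scans[config.traits[0]]
        if first.meff is not None:
            summary["m"] = first.meff.m
            summary["m_eff"] = first.meff.meff
            thr = corrected_threshold(config.mga_alpha, first.meff.meff)
            summary["mga_threshold"] = {
                "per_test_alpha": thr.per_test_alpha,
                "neglog10": thr.neglog10,
            }

    # -------------------------------------------------------- summary scores
    with _stage("ps"):
        ps_rows = []
        for snp, pmap in pvalues_by_snp.items():
            if len(pmap) == len(config.traits):
                res = ps_score(pmap, threshold=config.ps_threshold)
                ps_rows.append(
                    {"snp": snp, "ps": res.ps, "significant": res.significant}
                )
        ps_table = pd.DataFrame(ps_rows, columns=["snp", "ps", "significant"])
        ps_table = ps_table.sort_values("ps", ascending=False).reset_index(drop=True)
        io.write_table(ps_table, out / "ps.tsv", prov)

        if config.msa_snps is not None:
            msa = list(config.msa_snps)
        else:
            msa = list(ps_table.loc[ps_table["significant"], "snp"][: config.msa_max])
        summary["msa_snps"] = msa

    # ----------------------------------------------------------- interaction
    if config.run_interactions:
        with _stage("interaction"):
            for modifier in config.modifiers:
                for trait in config.traits:
                    res = interaction_scan(
                        trait,
                        genotypes,
                        phenotypes,
                        phi,
                        modifier,
                        pcs,
                        global_alpha=config.interaction_alpha,
                    )
                    io.write_table(
                        res.table, out / f"interaction_{modifier}_{trait}.tsv", prov
                    )

    # ------------------------------------------------------------ model search
    if config.run_bqtn and msa:
        with _stage("bqtn"):
            ne = None if config.ne == "auto" else float(config.ne)
            counts = {}
            for trait in config.traits:
                report = run_bqtn(
                    trait, msa, genotypes, phenotypes, phi, pcs, n_e=ne,
                    keep_models=False,
                )
                counts[trait] = report.n_models
                payload = {
                    "_provenance": dict(p.split("=", 1) for p in prov),
                    "trait": trait,
                    "h_r2": report.h_r2,
                    "n_e": report.n_e,
                    "n_used": report.n_used,
                    "n_models": report.n_models,
                    "best_subset": list(report.best.subset),
                    "best_bic_vs_null": report.delta_bic_vs_null,
                    "best_snp_pvalues": report.best.snp_pvalues,
                    "n_models_in_window": report.n_window,
                    "window": [list(w) for w in report.window],
                }
                with open(out / f"bqtn_{trait}.json", "w") as fh:
                    json.dump(payload, fh, indent=1, sort_keys=True)
                log.info("bqtn[%s]: scored %d models", trait, report.n_models)
            summary["bqtn_models_per_trait"] = counts
            summary["bqtn_models_total"] = int(sum(counts.values()))

    # ---------------------------------------------------------------- burden
    if config.run_burden:
        with _stage("burden"):
            snp_sets = {"all": genotypes.snp_ids}
            if msa:
                snp_sets["msa"] = msa
            snp_sets.update(config.snp_sets)
            table = burden_panel(
                config.traits, snp_sets, genotypes, phenotypes, phi, pcs
            )
            io.write_table(table, out / "burden.tsv", prov)
            summary["burden_rows"] = len(table)

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=str)
    return summary
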