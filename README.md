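# famvc

Family-based variance-components association toolkit for a single gene
locus, with a synthetic-data generator that reproduces the statistical
structure such analyses assume (extended pedigrees, block-LD genotypes,
age/sex covariates, liability-threshold disease traits).

The analysis ladder, run per trait against a panel of SNP dosages:

1. **Measured-genotype association (MGA)** — each SNP's additive dosage
   enters a polygenic variance-components model (relationship matrix 2Φ from
   the pedigree) as a fixed effect next to age, age², sex, their
   interactions and the top genotype PCs; tested by a 1-df LRT. Continuous
   traits are inverse-normalized (Blom) first.
2. **Multiple testing** — effective number of independent tests from the
   eigenvalues of the |dosage correlation| matrix (Li–Ji style), Bonferroni
   per-test threshold (Šidák optional), plus a cross-trait summary
   probability score PS = Σ_traits −log₁₀ p per SNP.
3. **Genotype × age/sex interaction** — dosage × modifier product terms
   (age binarized at 45 y) tested by 1-df LRTs, with per-stratum subgroup
   refits.
4. **Exhaustive subset model search** — all 2^s subsets of a pre-screened
   candidate SNP set scored by BIC_k = −Λ_k0 + df_k·ln(N_e); best model,
   below-null window, BIC weights, drop-one per-SNP p-values.
5. **Gene burden test** — joint fit of Ω = σ²(2Φh_r² + 2E·h_geff² + Ie²)
   where E is the empirical (dosage-derived) kinship of the locus; h_geff²
   is tested against the ½χ²₀:½χ²₁ boundary mixture.

## CLI

```bash
famvc simulate --config cfg.yaml --out data/ --seed 1
famvc kinship  --ped data/pedigree.fam --out phi.tsv
famvc assoc    --trait fasting_glucose --ped data/pedigree.fam \
               --vcf data/genotypes.vcf --pheno data/phenotypes.csv \
               --out scan.tsv
famvc interact --trait fasting_glucose --modifier age45 ...
famvc bqtn     --trait fasting_glucose --snps snp0001,snp0002 ...
famvc burden   --trait fasting_glucose --snp-set all ...
famvc run      --config cfg.yaml --out results/ --seed 1   # full pipeline
```

File formats are plain text: FAM-style pedigree TSV (`0` = missing parent,
sex 1/2), VCF 4.2 with a `DS` dosage field (or a dosage TSV), headered
phenotype CSV (`NA` missing token), labeled kinship TSV. Every output file
carries a provenance header (version, seed, config digest); a fixed seed
makes the whole result tree byte-identical.

A minimal pipeline config:

```yaml
simulate:
  n_pedigrees: 42
  n_snps: 118
traits: [ever_t2d, incident_t2d, fasting_glucose, fasting_insulin,
         glucose_2h, insulin_2h, homa_ir, homa_beta]
ps_threshold: 4.3010
```

## Package layout

```
src/famvc/
  simdata.py      synthetic pedigrees, LD genotypes, covariates, phenotypes
  pedigree.py     pedigree container + structural validation
  genotypes.py    dosage matrix + MAF utilities
  kinship.py      pedigree (Φ) and empirical (E) kinship matrices
  vcmodels.py     ML variance-components engine, LRT, mixture null
  assoc.py        MGA scans, M_eff, thresholds, PS, interactions, subgroups
  bqtn.py         exhaustive subset model search scored by BIC
  burden.py       two-component locus burden test
  interfaces/     file formats, config, pipeline orchestration, CLI, plots
```
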