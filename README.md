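# crossprs

A tested, reusable pipeline for cross-phenotype polygenic risk score (PRS)
pleiotropy analysis: from a literature variant-association catalog through
harmonization against cohort genotype panels, priority LD pruning, PRS
construction and standardization, covariate-adjusted cross-phenotype
association scans, two-cohort fixed-effects meta-analysis, multiplicity
control (Bonferroni and Benjamini–Hochberg FDR), genomic region enrichment,
and sensitivity reruns. A first-class synthetic-data module generates
two-cohort fixtures (LD-block genotypes, logistic-model case status,
quantitative secondary traits, and catalogs with planted harmonization
traps) so the whole pipeline is testable without any access-controlled
data.

## Layout

| module | purpose |
| --- | --- |
| `crossprs.simulate` | synthetic cohorts, planted effects, trap catalogs |
| `crossprs.catalog` | catalog deduplication + eligibility filters |
| `crossprs.cohort` | sample QC, case/control assignment, secondary-trait prep |
| `crossprs.harmonize` | id/position/proxy matching, allele reconciliation, frequency filters |
| `crossprs.ld` | pairwise dosage r², LD tables, greedy priority pruning |
| `crossprs.prs` | weighted allele-dosage scores + within-cohort standardization |
| `crossprs.assoc` | logistic/linear fits, per-variant log-additive scans |
| `crossprs.meta` | inverse-variance fixed-effects meta, Q/I², Bonferroni, BH FDR |
| `crossprs.postprocess` | region enrichment, sensitivity PRS filters |
| `crossprs.pipeline` / `crossprs.cli` | orchestration, YAML config, CLI |
| `crossprs.vcfio` | VCF (DS/GT) dosage reading and writing |

## CLI

```bash
# write a two-cohort synthetic fixture (dosage/phenotype/diagnosis/catalog TSVs)
crossprs simulate --config sim.yaml --out fixture/

# run the full pipeline
crossprs run --config pipeline.yaml --seed 11 --out run/
```

Stage subcommands (`curate`, `qc`, `prune`, `meta`) operate on single TSVs
for debugging. A minimal pipeline config:

```yaml
seed: 11
catalog: fixture/catalog.tsv
cohorts:
  - {label: cohA, dir: fixture/cohA}
  - {label: cohB, dir: fixture/cohB}
cancers:
  - {site_code: siteA}
  - {site_code: siteB}
thresholds: {min_cases: 50}       # defaults: gw 5e-8, proxy r2 0.8, prune r2 0.3,
secondary_traits:                 # MAF 0.01, MAF diff 0.10, ambiguous MAF 0.45,
  - {name: traitX, family: linear}  # min_cases 650, alpha 0.05
```

Outputs are TSVs with fixed column orders; each carries a header block
(`# config_hash=…`, `# seed=…`) so reruns under the same config and seed
are byte-identical. Key files: `catalog_curated.tsv`,
`harmonization_<cohort>.tsv`, `prune_report.tsv`, `prs_definitions.tsv`,
`prs_scores_<cohort>.tsv`, `assoc_*_by_cohort.tsv`, `meta_prs.tsv`,
`meta_variants.tsv`, `region_enrichment.tsv`, `meta_sensitivity.tsv`.

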