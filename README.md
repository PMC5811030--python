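# eqtlflow

A tested, reusable pipeline for two-tissue expression-QTL studies: it goes
from SNP genotypes and per-tissue RNA-seq count matrices to filtered
cis/trans eQTLs, multi-tissue eQTL calls, trait-QTL enrichment and
candidate markers for selection against a quantitative trait, plus a
synthetic-data generator so the entire chain is exercisable offline.

## Pipeline stages

| stage        | module                | what it does |
|--------------|-----------------------|--------------|
| `simulate`   | `synthetic_data`      | genotypes (HWE, optional LD blocks), negative-binomial expression with planted cis effects, genotype-linked breeding values (EBVs), mock trait-QTL interval database |
| `qc`         | `genotype_qc`         | variant filters in fixed order: call rate > 0.95 → Hardy-Weinberg exact test p > 1e-4 → MAF > 0.05 → sliding-window LD pruning (5 kb window/step, r² > 0.8) |
| `normalize`  | `expression_prep`     | mean-count > 5 gene filter, log2-CPM transform, lowess mean-variance precision weights |
| `scan`       | `eqtl_scan`           | matrix-formulated cis/trans scan with group covariates; cis window 1 Mb around the gene body, p < 1e-3 (cis) / 1e-6 (trans), BH FDR per class |
| `multitissue`| `multi_tissue`        | empirical-Bayes mixture over tissue-activity configurations fitted by EM on scan z-statistics; local-fdr-ranked multi-tissue calls at global FDR ≤ 0.05 |
| `ebv-filter` | `ebv_filter`          | per-eQTL nested-model F tests of genotype classes against EBVs and expression (covariates: tissue yield, genotyping QC, RIN); BH per family, keep records significant in both |
| `stats`      | `genome_stats`        | chromosomal eQTL densities; Spearman co-expression network among multi-tissue eQTL genes |
| `enrich`     | `qtl_enrichment`      | breed filter (≥ 1000 QTLs), per-trait interval length over a 2.7 Gb background, one-sided binomial overlap test, BH FDR, category summary |
| `candidates` | `candidate_selection` | filtered cis eQTLs whose genotype-class median EBV ≤ the low-group maximum (−0.0699208) and whose SNP overlaps an enriched taint-relevant trait |

`io_formats` supplies PED/MAP and VCF genotype readers (PED/MAP writer),
TSV count/sample/trait tables, BED/GFF3 gene annotation, and the
`RunConfig` (YAML/JSON) holding every stage threshold.

## CLI

Each stage is a subcommand operating on one working directory with fixed
file names; `run-all` chains them end to end on simulated data:

```sh
eqtlflow run-all --workdir demo --seed 7
eqtlflow qc --workdir demo --config myconfig.yaml
```

Every run writes `resolved_config.yaml` and `run.log` (resolved
configuration + seed) into the working directory. Outputs are plain text:
`qc_report.tsv`, `eqtls_<tissue>.tsv`, `mt_model.json`, `mt_calls.tsv`,
`eqtls_filtered.tsv`, `enrichment.tsv`, `category_summary.tsv`,
`candidates.tsv`, ...

## Library use

```python
from eqtlflow.io_formats import RunConfig, read_genotypes, read_counts
from eqtlflow.genotype_qc import run_qc
from eqtlflow.eqtl_scan import ScanDesign, scan

genotypes, variants = read_genotypes("study.ped")
filtered, variants, report = run_qc(genotypes, variants, RunConfig())
```

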