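"""Stage orchestration over a working directory with fixed file names.

Every stage reads its inputs from, and writes its outputs to, one working
directory so the CLI subcommands can be chained (or `run-all` can execute
the whole chain).  All files are plain text: PED/MAP for genotypes, TSV
for everything tabular, JSON for the multi-tissue model and summaries.
"""

from __future__ import annotations


import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import (
    candidate_selection,
    ebv_filter,
    eqtl_scan,
    expression_prep,
    genome_stats,
    genotype_qc,
    io_formats,
    multi_tissue,
    qtl_enrichment,
    synthetic_data,
)
from .io_formats import GenomeBuild, RunConfig

TISSUES = ("liver", "testis")
log = logging.getLogger("eqtlflow")


def _setup_log(workdir: Path, config: RunConfig) -> None:
    workdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(workdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    log.info("resolved config: %s", json.dumps(config.to_dict(), default=str))
    log.info("seed: %d", config.seed)


def read_genome(workdir: Path) -> GenomeBuild:
    return GenomeBuild.from_frame(pd.read_csv(workdir / "genome.tsv", sep="\t"))


def stage_simulate(workdir: Path, config: RunConfig) -> None:
    """Generate a fully linked synthetic dataset into the working directory."""
    design = synthetic_data.default_planted_design(seed=config.seed)
    genotypes, variants = synthetic_data.simulate_genotypes(design)
    samples = synthetic_data.simulate_ebv(genotypes, design)
    io_formats.write_genotypes(genotypes, variants, workdir / "genotypes.ped")
    io_formats.write_samples(samples, workdir / "samples.tsv")
    design.genome.to_frame().to_csv(workdir / "genome.tsv", sep="\t", index=False)
    for tissue in TISSUES:
        genes = synthetic_data.place_genes(design, tissue)
        counts = synthetic_data.simulate_expression(genotypes, genes, design, tissue)
        io_formats.write_genes_bed(genes, workdir / f"genes_{tissue}.bed")
        io_formats.write_counts(counts, workdir / f"counts_{tissue}.tsv")
    # taint-relevant traits get compact intervals over the planted cis SNPs
    # so the enrichment and candidate stages have signal to find
    vpos = variants.set_index("variant_id")
    taint_intervals = [
        (vpos.loc[vid, "chrom"], max(int(vpos.loc[vid, "pos"]) - 25_000, 1),
         int(vpos.loc[vid, "pos"]) + 25_000)
        for _, vid, _ in design.cis_effects
    ]
    traits = synthetic_data.simulate_trait_db(
        design.genome, seed=config.seed, taint_intervals=taint_intervals
    )
    io_formats.write_trait_qtl(traits, workdir / "trait_qtls.tsv")
    log.info("simulated %d variants, %d samples", genotypes.n_variants,
             genotypes.n_samples)


def stage_qc(workdir: Path, config: RunConfig) -> genotype_qc.QcReport:
    genotypes, variants = io_formats.read_genotypes(workdir / "genotypes.ped")
    filtered, kept_variants, report = genotype_qc.run_qc(genotypes, variants, config)
    io_formats.write_genotypes(filtered, kept_variants, workdir / "genotypes_qc.ped")
    report.to_frame().to_csv(workdir / "qc_report.tsv", sep="\t", index=False)
    log.info("QC: %s", report)
    return report


def _design(workdir: Path) -> tuple[pd.DataFrame, eqtl_scan.ScanDesign]:
    samples = io_formats.read_samples(workdir / "samples.tsv")
    return samples, eqtl_scan.ScanDesign.from_groups(samples)


def stage_normalize(workdir: Path, config: RunConfig) -> None:
    samples, design = _design(workdir)
    for tissue in TISSUES:
        counts = io_formats.read_counts(workdir / f"counts_{tissue}.tsv")
        counts = counts[samples["sample_id"]]
        eset = expression_prep.prepare_expression(
            counts, tissue, design.covariates, config.mean_count_min
        )
        eset.logcpm.to_csv(workdir / f"logcpm_{tissue}.tsv", sep="\t",
                           index_label="gene_id")
        eset.weights.to_csv(workdir / f"weights_{tissue}.tsv", sep="\t",
                            index_label="gene_id")
        log.info("%s: %d genes pass the mean-count filter", tissue,
                 eset.counts.shape[0])


def _load_scan_inputs(workdir: Path, tissue: str):
    genotypes, variants = io_formats.read_genotypes(workdir / "genotypes_qc.ped")
    genes = io_formats.read_genes(workdir / f"genes_{tissue}.bed")
    logcpm = pd.read_csv(workdir / f"logcpm_{tissue}.tsv", sep="\t", index_col=0)
    return genotypes, variants, genes, logcpm


def stage_scan(workdir: Path, config: RunConfig) -> dict[str, pd.DataFrame]:
    samples, design = _design(workdir)
    out = {}
    for tissue in TISSUES:
        genotypes, variants, genes, logcpm = _load_scan_inputs(workdir, tissue)
        logcpm = logcpm[samples["sample_id"]]
        records = eqtl_scan.scan(
            genotypes, logcpm, variants, genes, design, tissue, config
        )
        io_formats.write_table(records, workdir / f"eqtls_{tissue}.tsv")
        out[tissue] = records
        log.info("%s scan: %d retained pairs", tissue, len(records))
    return out


def stage_multitissue(workdir: Path, config: RunConfig) -> pd.DataFrame:
    samples, design = _design(workdir)
    records, contexts = {}, {}
    rng = np.random.default_rng(config.seed)
    for tissue in TISSUES:
        genotypes, variants, genes, logcpm = _load_scan_inputs(workdir, tissue)
        logcpm = logcpm[samples["sample_id"]]
        retained = pd.read_csv(workdir / f"eqtls_{tissue}.tsv", sep="\t")
        # pad the row set with a uniform sample of the full pair grid so the
        # mixture sees an unselected population (null component and rho0
        # are estimated from the near-null bulk, not threshold survivors)
        n_background = min(
            20_000, genotypes.n_variants * len(logcpm.index)
        )
        background = pd.DataFrame(
            {
                "variant_id": rng.choice(genotypes.variant_ids, n_background),
                "gene_id": rng.choice(logcpm.index.to_numpy(), n_background),
            }
        )
        records[tissue] = pd.concat(
            [retained[["variant_id", "gene_id"]], background], ignore_index=True
        ).drop_duplicates(["variant_id", "gene_id"])
        contexts[tissue] = multi_tissue.TissueScanContext(genotypes, logcpm, design)
    zmatrix = multi_tissue.build_zmatrix(records, contexts)
    zmatrix.reset_index().to_csv(workdir / "zmatrix.tsv", sep="\t", index=False)
    model = multi_tissue.fit_mt_model(
        zmatrix[list(TISSUES)], seed=config.seed
    )
    model.to_json(workdir / "mt_model.json")
    calls = multi_tissue.call_multitissue(
        zmatrix[list(TISSUES)], model, config.fdr_target
    )
    io_formats.write_table(calls, workdir / "mt_calls.tsv")
    log.info("multi-tissue: %d pairs, %d called", len(calls),
             int(calls["called"].sum()))
    return calls


def stage_ebv_filter(workdir: Path, config: RunConfig) -> pd.DataFrame:
    samples, _ = _design(workdir)
    genotypes, _ = io_formats.read_genotypes(workdir / "genotypes_qc.ped")
    annotated = []
    for tissue in TISSUES:
        records = pd.read_csv(workdir / f"eqtls_{tissue}.tsv", sep="\t")
        logcpm = pd.read_csv(workdir / f"logcpm_{tissue}.tsv", sep="\t",
                             index_col=0)[samples["sample_id"]]
        annotated.append(
            ebv_filter.annotate_associations(records, genotypes, logcpm, samples)
        )
    combined = ebv_filter.filter_eqtls(
        pd.concat(annotated, ignore_index=True), config.fdr_target
    )
    io_formats.write_table(combined, workdir / "eqtls_filtered.tsv")
    counts = ebv_filter.filtered_counts(combined)
    io_formats.write_table(counts, workdir / "filtered_counts.tsv")
    log.info("filtered eQTLs:\n%s", counts)
    return combined


def stage_stats(workdir: Path, config: RunConfig) -> None:
    genome = read_genome(workdir)
    eqtls = pd.read_csv(workdir / "eqtls_filtered.tsv", sep="\t")
    density = genome_stats.chromosome_density(
        eqtls, genome, config.density_scale
    )
    io_formats.write_table(density, workdir / "densities.tsv")
    if (workdir / "mt_calls.tsv").exists():
        calls = pd.read_csv(workdir / "mt_calls.tsv", sep="\t")
        gene_set = list(calls.loc[calls["called"], "gene_id"].unique())
        edges = []
        for tissue in TISSUES:
            logcpm = pd.read_csv(workdir / f"logcpm_{tissue}.tsv", sep="\t",
                                 index_col=0)
            edges.append(genome_stats.spearman_network(
                logcpm, gene_set, tissue, config.network_threshold
            ))
        io_formats.write_table(pd.concat(edges, ignore_index=True),
                               workdir / "network.tsv")


def stage_enrich(workdir: Path, config: RunConfig) -> pd.DataFrame:
    genome = read_genome(workdir)
    traits = io_formats.read_trait_qtl(workdir / "trait_qtls.tsv", genome)
    traits = qtl_enrichment.breed_filter(traits, config.breed_min_qtls)
    eqtls = pd.read_csv(workdir / "eqtls_filtered.tsv", sep="\t")
    cis = eqtls[(eqtls["eqtl_class"] == "cis") & eqtls["filtered"]]
    _, variants = io_formats.read_genotypes(workdir / "genotypes_qc.ped")
    snps = variants[variants["variant_id"].isin(cis["variant_id"])]
    snp_genes = cis.groupby("variant_id")["gene_id"].agg(list).to_dict()
    background = config.genome_background_bp or genome.total_length
    results = qtl_enrichment.enrich_all(
        snps, traits, background, config.fdr_target,
        config.merge_trait_intervals, snp_genes,
    )
    io_formats.write_table(results, workdir / "enrichment.tsv")
    totals = traits.groupby("category")["trait"].nunique().to_dict()
    summary = qtl_enrichment.category_summary(
        results[results["enriched"]], totals
    )
    io_formats.write_table(summary, workdir / "category_summary.tsv")
    log.info("enrichment: %d traits tested, %d enriched", len(results),
             int(results["enriched"].sum()))
    return results


def stage_candidates(workdir: Path, config: RunConfig) -> pd.DataFrame:
    genome = read_genome(workdir)
    traits = io_formats.read_trait_qtl(workdir / "trait_qtls.tsv", genome)
    enrichment = pd.read_csv(workdir / "enrichment.tsv", sep="\t")
    eqtls = pd.read_csv(workdir / "eqtls_filtered.tsv", sep="\t")
    cis = eqtls[(eqtls["eqtl_class"] == "cis") & eqtls["filtered"]]
    genotypes, variants = io_formats.read_genotypes(workdir / "genotypes_qc.ped")
    samples = io_formats.read_samples(workdir / "samples.tsv")
    candidates = candidate_selection.select_candidates(
        cis, enrichment, traits, genotypes, samples, variants,
        config.candidate_ebv_max, config.boar_taint_traits, config.fdr_target,
    )
    io_formats.write_table(candidates, workdir / "candidates.tsv")
    summary = candidate_selection.summarise_candidates(candidates)
    (workdir / "candidate_summary.json").write_text(json.dumps(summary, indent=2))
    log.info("candidates: %s", summary)
    return candidates


STAGES = {
    "simulate": stage_simulate,
    "qc": stage_qc,
    "normalize": stage_normalize,
    "scan": stage_scan,
    "multitissue": stage_multitissue,
    "ebv-filter": stage_ebv_filter,
    "stats": stage_stats,
    "enrich": stage_enrich,
    "candidates": stage_candidates,
}

RUN_ALL_ORDER = (
    "simulate", "qc", "normalize", "scan", "multitissue",
    "ebv-filter", "stats", "enrich", "candidates",
)


def run_stage(name: str, workdir: str | Path, config: RunConfig):
    workdir = Path(workdir)
    if not log.handlers:
        _setup_log(workdir, config)
    return STAGES[name](workdir, config)


def run_all(workdir: str | Path, config: RunConfig, simulate: bool = True) -> None:
    workdir = Path(workdir)
    _setup_log(workdir, config)
    for name in RUN_ALL_ORDER:
        if name == "simulate" and not simulate:
            continue
        log.info("stage: %s", name)
        STAGES[name](workdir, config)
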