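"""Synthetic genotypes, two-tissue expression, EBVs and a mock trait-QTL
database with the statistical structure the downstream analysis assumes.

Genotypes are drawn per variant under Hardy-Weinberg proportions with the
allele frequency sampled from a configurable MAF range; linkage blocks
share one frequency and are generated by Markov copying between adjacent
variants on two haplotypes, which keeps each variant's marginal frequency
at its drawn value while giving tunable adjacent correlation.  Expression
counts are negative binomial with a log link: planted gene-variant pairs
shift the log2 mean by dosage x effect.  EBVs are linear in causal
dosages plus Gaussian noise, with three tertile groups.  Every generator
is deterministic under its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import (
    BOAR_TAINT_TRAITS,
    GenomeBuild,
    GenotypeMatrix,
    QTL_CATEGORIES,
    ValidationError,
    make_gene_annotation,
    make_sample_table,
    make_trait_qtl_table,
    make_variant_table,
)


@dataclass
class SimulationDesign:
    """Knobs for the generator; defaults mirror the study layout
    (48 samples in three groups of 16) at a desk-friendly panel size."""

    n_samples: int = 48
    group_sizes: tuple[int, int, int] = (16, 16, 16)
    n_variants: int = 1_000
    n_genes: dict = field(default_factory=lambda: {"liver": 300, "testis": 360})
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_length_bp: int = 0          # 0 disables linkage blocks
    ld_block_correlation: float = 0.95   # adjacent-haplotype copy probability
    genome: GenomeBuild = field(
        default_factory=lambda: GenomeBuild(
            ("1", "2", "3", "4"), (50_000_000,) * 4
        )
    )
    variant_spacing_bp: int = 10_000
    # planted effects: (gene_id, variant_id, per-allele effect on log2 mean)
    cis_effects: list = field(default_factory=list)
    trans_effects: list = field(default_factory=list)
    # EBV model: causal (variant_id, per-allele effect) + noise sd
    ebv_effects: list = field(default_factory=list)
    ebv_noise_sd: float = 0.1
    nb_dispersion: float = 0.1
    library_size_range: tuple[float, float] = (0.8e6, 1.2e6)
    baseline_log2_mean_range: tuple[float, float] = (3.0, 9.0)
    seed: int = 0

    def __post_init__(self):
        if sum(self.group_sizes) != self.n_samples:
            raise ValidationError("group sizes must sum to n_samples")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValidationError("maf range must lie within (0, 0.5]")
        if self.nb_dispersion <= 0:
            raise ValidationError("negative-binomial dispersion must be > 0")
        if not self.genome.chrom_names:
            raise ValidationError("empty genome")


def _variant_layout(design: SimulationDesign) -> pd.DataFrame:
    """Evenly spaced variants cycled across chromosomes, then sorted."""
    n_chrom = len(design.genome.chrom_names)
    per = int(np.ceil(design.n_variants / n_chrom))
    rows = []
    k = 0
    for c, (name, length) in enumerate(
        zip(design.genome.chrom_names, design.genome.chrom_lengths)
    ):
        for i in range(per):
            if k >= design.n_variants:
                break
            pos = 1 + (i * design.variant_spacing_bp) % length
            rows.append((f"snp{k:06d}", name, pos))
            k += 1
    df = pd.DataFrame(rows, columns=["variant_id", "chrom", "pos"])
    df["allele_a"] = "A"
    df["allele_b"] = "B"
    return make_variant_table(df)


def simulate_genotypes(design: SimulationDesign) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Hardy-Weinberg genotypes with optional Markov-copied LD blocks."""
    if design.n_samples < 2:
        raise ValidationError("need >= 2 samples")
    rng = np.random.default_rng(design.seed)
    variants = _variant_layout(design)
    n, m = design.n_samples, len(variants)
    lo, hi = design.maf_range

    # block id per variant: consecutive variants on one chromosome whose
    # positions fall in the same ld_block_length_bp stretch share a block
    if design.ld_block_length_bp > 0:
        block = (
            variants["chrom"].astype(str)
            + ":"
            + (variants["pos"] // design.ld_block_length_bp).astype(str)
        ).to_numpy()
    else:
        block = variants["variant_id"].to_numpy()  # singleton blocks

    # one MAF per block so copying preserves each variant's marginal
    block_ids, block_index = np.unique(block, return_inverse=True)
    block_maf = rng.uniform(lo, hi, size=len(block_ids))
    maf = block_maf[block_index]
    variants = variants.assign(sim_maf=maf)  # drawn target, for verification

    hap = np.empty((2 * n, m), dtype=np.int8)
    copy = design.ld_block_correlation
    for j in range(m):
        fresh = rng.random(2 * n) < maf[j]
        if j > 0 and block[j] == block[j - 1] and copy > 0:
            keep = rng.random(2 * n) < copy
            hap[:, j] = np.where(keep, hap[:, j - 1], fresh)
        else:
            hap[:, j] = fresh
    dosages = (hap[:n] + hap[n:]).astype(float)
    matrix = GenotypeMatrix(dosages, [f"pig{i:03d}" for i in range(n)],
                            list(variants["variant_id"]))
    return matrix, variants


def place_genes(
    design: SimulationDesign,
    tissue: str,
    gene_length_bp: int = 20_000,
) -> pd.DataFrame:
    """Deterministic gene layout interleaved with the variant grid so that
    planted pairs can be chosen within the cis window.

    Gene ids are shared across tissues (each tissue expresses the first
    ``n_genes[tissue]`` genes of one common layout), mirroring a study
    where both tissues share most of the expressed-gene universe.
    """
    rng = np.random.default_rng(design.seed + 3)
    n_genes = design.n_genes[tissue]
    n_universe = max(design.n_genes.values())
    n_chrom = len(design.genome.chrom_names)
    per = int(np.ceil(n_universe / n_chrom))
    rows = []
    k = 0
    for name, length in zip(design.genome.chrom_names, design.genome.chrom_lengths):
        for i in range(per):
            if k >= n_universe:
                break
            start = 1 + (i * design.variant_spacing_bp * 3 + 5_000) % max(
                length - gene_length_bp, 1
            )
            rows.append(
                (f"G{k:05d}", name, start,
                 start + gene_length_bp - 1,
                 "+" if rng.random() < 0.5 else "-")
            )
            k += 1
    universe = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand"]
    )
    # the tissue expresses a deterministic prefix of the shared universe
    return make_gene_annotation(universe.head(n_genes))


def simulate_expression(
    genotypes: GenotypeMatrix,
    genes: pd.DataFrame,
    design: SimulationDesign,
    tissue: str,
) -> pd.DataFrame:
    """Negative-binomial counts (genes x samples) with planted effects."""
    if design.nb_dispersion <= 0:
        raise ValidationError("non-positive dispersion")
    rng = np.random.default_rng(design.seed + 1 + hash(tissue) % 10_000)
    gene_ids = list(genes["gene_id"])
    n_genes, n = len(gene_ids), genotypes.n_samples

    base_log2 = rng.uniform(*design.baseline_log2_mean_range, size=n_genes)
    lib_factor = rng.uniform(*design.library_size_range, size=n) / np.mean(
        design.library_size_range
    )
    log2_mu = np.tile(base_log2[:, None], (1, n))

    gidx = {g: i for i, g in enumerate(gene_ids)}
    vidx = {v: j for j, v in enumerate(genotypes.variant_ids)}
    for gene_id, variant_id, effect in list(design.cis_effects) + list(
        design.trans_effects
    ):
        if gene_id not in gidx:
            continue
        if variant_id not in vidx:
            raise ValidationError(f"planted variant {variant_id!r} not in panel")
        dose = np.nan_to_num(genotypes.dosages[:, vidx[variant_id]])
        log2_mu[gidx[gene_id]] += dose * effect

    mu = (2.0 ** log2_mu) * lib_factor[None, :]
    shape = 1.0 / design.nb_dispersion
    lam = rng.gamma(shape, mu / shape)
    counts = rng.poisson(lam)
    return pd.DataFrame(counts, index=gene_ids, columns=genotypes.sample_ids)


def simulate_ebv(genotypes: GenotypeMatrix, design: SimulationDesign) -> pd.DataFrame:
    """EBV = sum(causal dosage x effect) + Gaussian noise; tertile groups.

    Groups are assigned by sorting on EBV (ties broken by sample order):
    the lowest block of ``group_sizes[0]`` samples is "low", the middle is
    "medium", the top is "high".  Covariates are simulated independently.
    """
    n = genotypes.n_samples
    if sum(design.group_sizes) != n:
        raise ValidationError("group sizes incompatible with sample count")
    rng = np.random.default_rng(design.seed + 2)
    ebv = np.zeros(n)
    vidx = {v: j for j, v in enumerate(genotypes.variant_ids)}
    for variant_id, effect in design.ebv_effects:
        if variant_id not in vidx:
            raise ValidationError(f"causal variant {variant_id!r} not in panel")
        ebv += np.nan_to_num(genotypes.dosages[:, vidx[variant_id]]) * effect
    if design.ebv_noise_sd > 0:
        ebv += rng.normal(0, design.ebv_noise_sd, size=n)

    order = np.argsort(ebv, kind="stable")
    group = np.empty(n, dtype=object)
    lo, mid, hi = design.group_sizes
    group[order[:lo]] = "low"
    group[order[lo : lo + mid]] = "medium"
    group[order[lo + mid :]] = "high"

    samples = pd.DataFrame(
        {
            "sample_id": genotypes.sample_ids,
            "group": group,
            "ebv": ebv,
            "tissue_yield_mg": rng.uniform(120, 180, size=n),
            "geno_qc": rng.uniform(0.97, 1.0, size=n),
            "rin": rng.uniform(6.5, 9.5, size=n),
        }
    )
    return make_sample_table(samples)


def group_ebv_summary(samples: pd.DataFrame) -> pd.DataFrame:
    """Realised per-group EBV mean and sd (reported by the generator)."""
    return (
        samples.groupby("group")["ebv"]
        .agg(["mean", "std", "size"])
        .reset_index()
        .rename(columns={"size": "n"})
    )


def simulate_trait_db(
    genome: GenomeBuild,
    n_traits: int = 40,
    qtls_per_trait: int = 40,
    mean_length_bp: float = 2_000_000,
    boar_taint_traits=BOAR_TAINT_TRAITS,
    breeds: dict[str, int] | None = None,
    seed: int = 0,
    taint_intervals: list[tuple[str, int, int]] | None = None,
) -> pd.DataFrame:
    """Mock trait-QTL interval table with uniformly placed intervals.

    The taint-relevant trait names are always present; ``breeds`` maps
    breed name to the approximate share of rows it should receive (row
    counts per breed are then controllable for the breed filter).  When
    ``taint_intervals`` is given, every taint-relevant trait is placed on
    exactly those (chrom, start, end) intervals instead of randomly, so
    planted eQTL SNPs can be made to overlap them.
    """
    rng = np.random.default_rng(seed)
    names = list(boar_taint_traits) + [
        f"Trait {i:03d}" for i in range(max(n_traits - len(boar_taint_traits), 0))
    ]
    breeds = breeds or {"BreedA": 9, "BreedB": 1}  # BreedA clears a 1000-QTL floor
    breed_names = list(breeds)
    breed_p = np.array([breeds[b] for b in breed_names], dtype=float)
    breed_p /= breed_p.sum()

    rows = []
    for t, name in enumerate(names):
        category = QTL_CATEGORIES[t % len(QTL_CATEGORIES)]
        if taint_intervals is not None and name in boar_taint_traits:
            for chrom, start, end in taint_intervals:
                rows.append((name, category, breed_names[0], chrom,
                             int(start), int(end)))
            continue
        for _ in range(qtls_per_trait):
            ci = rng.integers(len(genome.chrom_names))
            chrom = genome.chrom_names[ci]
            clen = genome.chrom_lengths[ci]
            length = int(min(max(rng.exponential(mean_length_bp), 1), clen))
            start = int(rng.integers(1, clen - length + 2))
            rows.append(
                (
                    name,
                    category,
                    breed_names[rng.choice(len(breed_names), p=breed_p)],
                    chrom,
                    start,
                    start + length - 1,
                )
            )
    df = pd.DataFrame(
        rows, columns=["trait", "category", "breed", "chrom", "start", "end"]
    )
    return make_trait_qtl_table(df, genome)


def default_planted_design(seed: int = 0, **overrides) -> SimulationDesign:
    """A ready-made design with cis effects, EBV-linked variants and two
    tissues, used by the CLI `simulate` command and the test suite."""
    design = SimulationDesign(seed=seed, **overrides)
    genotypes, variants = simulate_genotypes(design)
    liver_genes = place_genes(design, "liver")
    # plant cis pairs: first few genes paired with the nearest variant
    v = variants.set_index("variant_id")
    cis = []
    for _, gene in liver_genes.head(8).iterrows():
        same = variants[variants["chrom"] == gene["chrom"]]
        d = (same["pos"] - gene["start"]).abs()
        cis.append((gene["gene_id"], same.loc[d.idxmin(), "variant_id"], 1.0))
    design.cis_effects = cis
    design.ebv_effects = [(cis[0][1], -0.3), (cis[1][1], -0.2)]
    return design
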