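import numpy as np
import pandas as pd
import pytest

from eqtlflow.io_formats import GenomeBuild, GenotypeMatrix, make_variant_table
from eqtlflow.synthetic_data import (
    SimulationDesign,
    place_genes,
    simulate_ebv,
    simulate_expression,
    simulate_genotypes,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_genome():
    return GenomeBuild(("1", "2"), (10_000_000, 8_000_000))


def random_genotypes(rng, n_samples, n_variants, maf_low=0.1, maf_high=0.5,
                     spacing=1_000, chrom="1"):
    """Plain HWE genotypes with a deterministic variant grid (no LD)."""
    maf = rng.uniform(maf_low, maf_high, size=n_variants)
    dosages = rng.binomial(2, maf, size=(n_samples, n_variants)).astype(float)
    ids = [f"v{j:05d}" for j in range(n_variants)]
    variants = make_variant_table(
        pd.DataFrame(
            {
                "variant_id": ids,
                "chrom": chrom,
                "pos": 1 + spacing * np.arange(n_variants),
            }
        )
    )
    return GenotypeMatrix(dosages, [f"s{i:03d}" for i in range(n_samples)], ids), variants


@pytest.fixture
def tiny_design():
    """48-sample, small-panel design with planted cis and EBV effects."""
    design = SimulationDesign(
        n_variants=200,
        n_genes={"liver": 60, "testis": 70},
        seed=7,
    )
    genotypes, variants = simulate_genotypes(design)
    genes = place_genes(design, "liver")
    v = variants.set_index("variant_id")
    cis = []
    for _, gene in genes.head(4).iterrows():
        same = variants[variants["chrom"] == gene["chrom"]]
        d = (same["pos"] - gene["start"]).abs()
        cis.append((gene["gene_id"], same.loc[d.idxmin(), "variant_id"], 1.2))
    design.cis_effects = cis
    design.ebv_effects = [(cis[0][1], -0.3)]
    return design


@pytest.fixture
def tiny_dataset(tiny_design):
    genotypes, variants = simulate_genotypes(tiny_design)
    genes = place_genes(tiny_design, "liver")
    counts = simulate_expression(genotypes, genes, tiny_design, "liver")
    samples = simulate_ebv(genotypes, tiny_design)
    return {
        "design": tiny_design,
        "genotypes": genotypes,
        "variants": variants,
        "genes": genes,
        "counts": counts,
        "samples": samples,
    }
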