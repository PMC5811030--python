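"""Chromosomal eQTL densities and the Spearman co-expression network."""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenomeBuild, ValidationError


def chromosome_density(
    eqtls: pd.DataFrame,
    genome: GenomeBuild,
    scale: float = 1e8,
) -> pd.DataFrame:
    """eQTL count per chromosome / chromosome length * scale, sorted
    descending by density.  Chromosomes with zero eQTLs are included."""
    unknown = set(eqtls["snp_chrom"].astype(str)) - set(genome.chrom_names)
    if unknown:
        raise ValidationError(f"eQTL chromosomes not in genome: {sorted(unknown)}")
    counts = eqtls.groupby(eqtls["snp_chrom"].astype(str)).size()
    rows = []
    for name, length in zip(genome.chrom_names, genome.chrom_lengths):
        n = int(counts.get(name, 0))
        rows.append((name, n, length, n / length * scale))
    out = pd.DataFrame(rows, columns=["chrom", "n_eqtls", "length_bp", "density"])
    return out.sort_values(
        "density", ascending=False, kind="mergesort"
    ).reset_index(drop=True)


def spearman_network(
    expression: pd.DataFrame,
    gene_ids: list[str],
    tissue: str,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Spearman edges among the given genes with |rho| >= threshold.

    One row per unordered pair; midranks for ties; constant genes are
    excluded with a warning.  Columns: gene_i, gene_j, tissue, rho, sign.
    """
    if expression.shape[1] < 4:
        raise ValidationError("need >= 4 samples for a correlation network")
    present = [g for g in gene_ids if g in expression.index]
    usable = []
    for g in present:
        if expression.loc[g].nunique() < 2:
            warnings.warn(f"gene {g!r} constant in {tissue}; excluded", stacklevel=2)
        else:
            usable.append(g)
    rows = []
    if usable:
        # midrank-transform once, then one Pearson matrix over all genes
        ranks = np.vstack(
            [stats.rankdata(expression.loc[g].to_numpy()) for g in usable]
        )
        corr = np.corrcoef(ranks)
        for a, b in combinations(range(len(usable)), 2):
            rho = corr[a, b]
            if np.isfinite(rho) and abs(rho) >= threshold:
                rows.append((usable[a], usable[b], tissue, float(rho),
                             "positive" if rho > 0 else "negative"))
    return pd.DataFrame(rows, columns=["gene_i", "gene_j", "tissue", "rho", "sign"])
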