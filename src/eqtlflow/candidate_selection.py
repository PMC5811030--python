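"""Candidate-marker selection from filtered cis eQTLs.

Two criteria make a (filtered cis eQTL, genotype class) pair a candidate:

  i)  the class's median summarised EBV is <= the configured ceiling
      (the low group's maximum EBV; inclusive comparison), and
  ii) the eQTL's SNP overlaps a taint-relevant trait that the enrichment
      test called significant (FDR < target).

One output row is emitted per (eQTL, qualifying genotype, overlapped
trait) triple, so an eQTL overlapping several relevant traits appears
once per trait with a shared key.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_formats import (
    BOAR_TAINT_TRAITS,
    GenotypeMatrix,
    ValidationError,
)
from .ebv_filter import GENOTYPE_LABELS
from .qtl_enrichment import count_overlaps

CANDIDATE_COLUMNS = [
    "variant_id", "gene_id", "candidate_genotype", "median_ebv", "mean_ebv",
    "n_carriers", "fdr_ebv", "tissue", "overlapping_trait",
]


def genotype_ebv_stats(dosage: np.ndarray, samples: pd.DataFrame) -> pd.DataFrame:
    """Median and mean EBV per non-empty genotype class for one variant."""
    dosage = np.asarray(dosage, dtype=float)
    ok = ~np.isnan(dosage)
    if not ok.any():
        raise ValidationError("all genotypes missing")
    ebv = samples["ebv"].to_numpy(dtype=float)
    rows = []
    for dose, label in GENOTYPE_LABELS.items():
        sel = ok & (dosage == dose)
        if not sel.any():
            continue
        rows.append(
            {
                "genotype": label,
                "dosage": dose,
                "n": int(sel.sum()),
                "median_ebv": float(np.median(ebv[sel])),
                "mean_ebv": float(ebv[sel].mean()),
            }
        )
    return pd.DataFrame(rows)


def select_candidates(
    filtered_cis: pd.DataFrame,
    enrichment: pd.DataFrame,
    traits: pd.DataFrame,
    genotypes: GenotypeMatrix,
    samples: pd.DataFrame,
    variants: pd.DataFrame,
    ebv_max: float = -0.0699208,
    boar_taint_traits=BOAR_TAINT_TRAITS,
    fdr_target: float = 0.05,
) -> pd.DataFrame:
    """Apply both candidacy criteria; returns the candidate table.

    ``filtered_cis`` are filtered cis eQTL records (variant_id, gene_id,
    tissue, fdr_ebv); eQTLs present in both tissues are collapsed to one
    row with tissue "both".  ``enrichment`` is the output of
    :func:`eqtlflow.qtl_enrichment.enrich_all` on the same SNP set.
    """
    if not boar_taint_traits:
        raise ValidationError("empty taint-relevant trait set")
    relevant = enrichment[
        enrichment["trait"].isin(boar_taint_traits)
        & (enrichment["fdr"] < fdr_target)
    ]["trait"].tolist()
    if not relevant:
        return pd.DataFrame(columns=CANDIDATE_COLUMNS)

    # collapse multi-tissue duplicates of the same gene-SNP pair
    pairs = (
        filtered_cis.groupby(["variant_id", "gene_id"], sort=False)
        .agg(
            tissue=("tissue", lambda s: "both" if s.nunique() > 1 else s.iloc[0]),
            fdr_ebv=("fdr_ebv", "min"),
        )
        .reset_index()
    )
    vidx = {v: j for j, v in enumerate(genotypes.variant_ids)}
    vpos = variants.set_index("variant_id")

    rows = []
    for rec in pairs.itertuples(index=False):
        dose = genotypes.dosages[:, vidx[rec.variant_id]]
        stats_ = genotype_ebv_stats(dose, samples)
        qualifying = stats_[stats_["median_ebv"] <= ebv_max]
        if qualifying.empty:
            continue
        snp = pd.DataFrame(
            {
                "variant_id": [rec.variant_id],
                "chrom": [vpos.loc[rec.variant_id, "chrom"]],
                "pos": [vpos.loc[rec.variant_id, "pos"]],
            }
        )
        for trait in relevant:
            trait_rows = traits[traits["trait"] == trait]
            k, _ = count_overlaps(snp, trait_rows)
            if k == 0:
                continue
            for g in qualifying.itertuples(index=False):
                rows.append(
                    {
                        "variant_id": rec.variant_id,
                        "gene_id": rec.gene_id,
                        "candidate_genotype": g.genotype,
                        "median_ebv": g.median_ebv,
                        "mean_ebv": g.mean_ebv,
                        "n_carriers": g.n,
                        "fdr_ebv": rec.fdr_ebv,
                        "tissue": rec.tissue,
                        "overlapping_trait": trait,
                    }
                )
    out = pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)
    # emitted rows satisfy the candidate invariants by construction
    assert (out["median_ebv"] <= ebv_max).all()
    assert out["overlapping_trait"].isin(boar_taint_traits).all()
    assert (out["n_carriers"] > 0).all()
    return out.reset_index(drop=True)


def summarise_candidates(candidates: pd.DataFrame) -> dict:
    """Bookkeeping totals over a candidate table.

    Returns entry count (table rows), unique (SNP, gene) eQTL count,
    unique gene count, total candidate genotypes (distinct
    (SNP, gene, genotype) triples) and the per-gene genotype counts.
    """
    if candidates.empty:
        return {
            "n_entries": 0,
            "n_eqtls": 0,
            "n_unique_genes": 0,
            "n_candidate_genotypes": 0,
            "genotypes_per_gene": {},
        }
    triples = candidates.drop_duplicates(
        ["variant_id", "gene_id", "candidate_genotype"]
    )
    per_gene = (
        triples.groupby("gene_id").size().sort_values(ascending=False).to_dict()
    )
    return {
        "n_entries": int(len(candidates)),
        "n_eqtls": int(
            candidates.drop_duplicates(["variant_id", "gene_id"]).shape[0]
        ),
        "n_unique_genes": int(candidates["gene_id"].nunique()),
        "n_candidate_genotypes": int(len(triples)),
        "genotypes_per_gene": per_gene,
    }


def summarise_genotype_distribution(per_gene_counts: dict[str, int]) -> dict:
    """Totals from a per-gene candidate-genotype distribution."""
    return {
        "n_unique_genes": len(per_gene_counts),
        "n_candidate_genotypes": int(sum(per_gene_counts.values())),
    }
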