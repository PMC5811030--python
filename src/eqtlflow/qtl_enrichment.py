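"""Trait-QTL enrichment of filtered cis-eQTL SNPs.

Pipeline: drop traits contributed by sparsely represented breeds, compute
each trait's summed interval length L (overlapping intervals merged per
chromosome by default), count distinct eQTL SNPs falling inside any of the
trait's intervals, and test k overlaps among n SNPs against the per-SNP
hit probability pi = L / G (G the genome background length) with a
one-sided upper-tail binomial test.  BH-FDR across traits; enriched means
FDR < target.  A category summary reports enriched-trait counts divided
by each category's database total.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats

from .eqtl_scan import bh_fdr
from .io_formats import ValidationError


def breed_filter(traits: pd.DataFrame, min_qtls: int = 1_000) -> pd.DataFrame:
    """Keep rows whose breed has >= min_qtls rows in the input table."""
    breed_counts = traits.groupby("breed").size()
    keep = traits["breed"].map(breed_counts) >= min_qtls
    return traits[keep].reset_index(drop=True)


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of 1-based inclusive intervals on one chromosome."""
    merged: list[list[int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def trait_length(trait_rows: pd.DataFrame, merge: bool = True) -> int:
    """Summed interval length in bp (end - start + 1 per interval).

    With ``merge`` (default), overlapping intervals are unioned per
    chromosome first; without it, plain summation (literal mode).
    """
    if (trait_rows["start"] > trait_rows["end"]).any():
        raise ValidationError("interval with start > end")
    if not merge:
        return int((trait_rows["end"] - trait_rows["start"] + 1).sum())
    total = 0
    for _, grp in trait_rows.groupby("chrom"):
        for s, e in merge_intervals(list(zip(grp["start"], grp["end"]))):
            total += e - s + 1
    return total


def count_overlaps(snps: pd.DataFrame, trait_rows: pd.DataFrame) -> tuple[int, list[str]]:
    """Distinct SNPs (by variant_id) inside >= 1 trait interval, inclusive ends.

    Returns (k, overlapping variant ids).  A SNP covered by several of the
    trait's intervals counts once.
    """
    hits: list[str] = []
    by_chrom = {c: g for c, g in trait_rows.groupby("chrom")}
    seen = set()
    for row in snps.itertuples(index=False):
        if row.variant_id in seen:
            continue
        seen.add(row.variant_id)
        grp = by_chrom.get(str(row.chrom))
        if grp is None:
            continue
        inside = ((grp["start"] <= row.pos) & (row.pos <= grp["end"])).any()
        if inside:
            hits.append(row.variant_id)
    return len(hits), hits


def binomial_enrichment(k: int, n_snps: int, l_trait: int, genome_bp: int) -> float:
    """One-sided upper-tail binomial p-value P(X >= k), X ~ Bin(n, L/G)."""
    if l_trait <= 0 or l_trait > genome_bp:
        raise ValidationError("trait length must lie in (0, G]")
    if not 0 <= k <= n_snps:
        raise ValidationError("overlap count outside [0, n_snps]")
    if k == 0:
        return 1.0
    pi = min(l_trait / genome_bp, 1.0)
    return float(stats.binom.sf(k - 1, n_snps, pi))


def enrich_all(
    eqtl_snps: pd.DataFrame,
    traits: pd.DataFrame,
    genome_bp: int,
    fdr_target: float = 0.05,
    merge: bool = True,
    snp_genes: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Per-trait enrichment over a deduplicated SNP set.

    ``eqtl_snps`` needs variant_id/chrom/pos columns (duplicates are
    collapsed); ``snp_genes`` optionally maps variant ids to the gene ids
    of their eQTLs so each result can carry the overlapping gene list.
    """
    snps = eqtl_snps.drop_duplicates("variant_id").reset_index(drop=True)
    n = len(snps)
    rows = []
    for trait, trait_rows in traits.groupby("trait", sort=True):
        l_trait = trait_length(trait_rows, merge=merge)
        k, hit_ids = count_overlaps(snps, trait_rows)
        p = binomial_enrichment(k, n, l_trait, genome_bp)
        genes: list[str] = []
        if snp_genes:
            genes = sorted({g for v in hit_ids for g in snp_genes.get(v, [])})
        rows.append(
            {
                "trait": trait,
                "category": trait_rows["category"].iloc[0],
                "n_snps": n,
                "k_overlap": k,
                "length_bp": l_trait,
                "pi": min(l_trait / genome_bp, 1.0),
                "p": p,
                "genes": ",".join(genes),
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        out["fdr"] = []
        out["enriched"] = []
        return out
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    out["enriched"] = out["fdr"] < fdr_target
    return out.sort_values("fdr", kind="mergesort").reset_index(drop=True)


def category_summary(
    enriched_traits: pd.DataFrame,
    category_totals: dict[str, int] | pd.Series,
    ndigits: int = 3,
) -> pd.DataFrame:
    """Enriched-trait counts per category with the adjusted frequency
    n_enriched / category_total (rounded for reporting; the exact value is
    kept in ``adjusted_exact``)."""
    totals = dict(category_totals)
    counts = (
        enriched_traits.groupby("category").size() if len(enriched_traits) else pd.Series(dtype=int)
    )
    missing = set(counts.index) - set(totals)
    if missing:
        raise ValidationError(f"categories missing from totals: {sorted(missing)}")
    rows = []
    for cat, total in totals.items():
        if total <= 0:
            raise ValidationError(f"non-positive total for category {cat!r}")
        n = int(counts.get(cat, 0))
        exact = n / total
        rows.append(
            {
                "category": cat,
                "n_enriched": n,
                "category_total": total,
                "adjusted_exact": exact,
                "adjusted": round(exact, ndigits),
            }
        )
    columns = ["category", "n_enriched", "category_total",
               "adjusted_exact", "adjusted"]
    return pd.DataFrame(rows, columns=columns).sort_values(
        "n_enriched", ascending=False, kind="mergesort"
    ).reset_index(drop=True)
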