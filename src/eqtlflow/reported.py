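"""Loaders for the published summary tables shipped with the package.

These small TSVs record the study's printed bookkeeping inputs (category
summary, candidate table, per-gene genotype distribution, per-tissue
filtered-eQTL counts) so that reporting arithmetic can be recomputed
without any external downloads.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    ref = resources.files("eqtlflow.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def category_summary_inputs() -> pd.DataFrame:
    """Per-category enriched-trait counts and database totals."""
    return _load("reported_category_summary.tsv")


def candidate_table() -> pd.DataFrame:
    """The published candidate-eQTL table (one row per entry)."""
    return _load("reported_candidates.tsv")


def genotype_distribution() -> dict[str, int]:
    """Per-gene candidate-genotype counts."""
    df = _load("reported_genotype_counts.tsv")
    return dict(zip(df["gene_id"], df["n_genotypes"].astype(int)))


def filtered_count_inputs() -> pd.DataFrame:
    """Published per-(tissue, class) filtered-eQTL counts."""
    return _load("reported_filtered_counts.tsv")
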