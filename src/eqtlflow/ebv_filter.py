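"""Per-eQTL association of genotype classes with breeding values and with
gene expression, via nested-model F tests with additive covariates.

For every retained eQTL, samples fall into up to three genotype classes
(AA / AB / BB by dosage 0 / 1 / 2).  Two nested ordinary-least-squares
models are compared:

    reduced:  response ~ covariates
    full:     response ~ covariates + genotype-class indicators

with F = ((RSS0 - RSS1)/(k - 1)) / (RSS1 / (n - rank_full)), k the number
of non-empty classes.  BH-FDR is applied per tissue within each test
family (EBV; expression), and records significant in both families at the
target are the "filtered eQTLs".

The default model is additive in the covariates; an optional interaction
mode adds covariate x genotype terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .eqtl_scan import bh_fdr
from .io_formats import GenotypeMatrix, ValidationError

GENOTYPE_LABELS = {0: "AA", 1: "AB", 2: "BB"}
DEFAULT_COVARIATES = ("tissue_yield_mg", "geno_qc", "rin")


@dataclass
class AssociationResult:
    f_stat: float
    p: float
    degenerate: bool = False  # zero residual variance in the full model


def _nested_f_test(
    response: np.ndarray,
    classes: np.ndarray,
    covariates: np.ndarray,
    interactions: bool = False,
) -> AssociationResult:
    """F test of genotype-class indicators on top of the covariates."""
    ok = ~np.isnan(response) & ~np.isnan(classes)
    y = response[ok]
    cls = classes[ok].astype(int)
    x0 = np.column_stack([np.ones(ok.sum()), covariates[ok]])
    levels = np.unique(cls)
    k = len(levels)
    if k < 2:
        warnings.warn("single non-empty genotype class; p = 1", stacklevel=3)
        return AssociationResult(0.0, 1.0)

    # k-1 indicator columns (first level is the baseline)
    ind = np.column_stack([(cls == lv).astype(float) for lv in levels[1:]])
    x1 = np.column_stack([x0, ind])
    if interactions:
        inter = np.column_stack(
            [covariates[ok] * ind[:, j : j + 1] for j in range(ind.shape[1])]
        )
        x1 = np.column_stack([x1, inter])

    def rss(x):
        coef, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ coef
        return float(resid @ resid), np.linalg.matrix_rank(x)

    rss0, _ = rss(x0)
    rss1, rank1 = rss(x1)
    df1 = rank1 - np.linalg.matrix_rank(x0)
    df2 = len(y) - rank1
    if df1 < 1 or df2 < 1:
        raise ValidationError("not enough samples for the nested F test")
    if rss1 <= 1e-12 * max(rss0, 1.0):
        if rss0 - rss1 <= 1e-12:
            return AssociationResult(0.0, 1.0)  # response constant
        return AssociationResult(np.inf, 0.0, degenerate=True)
    f = ((rss0 - rss1) / df1) / (rss1 / df2)
    f = max(f, 0.0)
    return AssociationResult(float(f), float(stats.f.sf(f, df1, df2)))


def _covariate_matrix(samples: pd.DataFrame, covariates) -> np.ndarray:
    missing = [c for c in covariates if c not in samples.columns]
    if missing:
        raise ValidationError(f"sample table missing covariates {missing}")
    return samples[list(covariates)].to_numpy(dtype=float)


def ebv_association(
    dosage: np.ndarray,
    samples: pd.DataFrame,
    covariates=DEFAULT_COVARIATES,
    interactions: bool = False,
) -> AssociationResult:
    """EBV ~ covariates (+ genotype) nested F test for one variant."""
    return _nested_f_test(
        samples["ebv"].to_numpy(dtype=float),
        np.asarray(dosage, dtype=float),
        _covariate_matrix(samples, covariates),
        interactions,
    )


def expression_association(
    dosage: np.ndarray,
    expression_row: np.ndarray,
    samples: pd.DataFrame,
    covariates=DEFAULT_COVARIATES,
    interactions: bool = False,
) -> AssociationResult:
    """Normalised expression ~ covariates (+ genotype) nested F test."""
    return _nested_f_test(
        np.asarray(expression_row, dtype=float),
        np.asarray(dosage, dtype=float),
        _covariate_matrix(samples, covariates),
        interactions,
    )


def annotate_associations(
    records: pd.DataFrame,
    genotypes: GenotypeMatrix,
    expression: pd.DataFrame,
    samples: pd.DataFrame,
    covariates=DEFAULT_COVARIATES,
    interactions: bool = False,
) -> pd.DataFrame:
    """Attach p_ebv and p_expression to each eQTL record of one tissue."""
    if genotypes.sample_ids != list(samples["sample_id"]):
        raise ValidationError("genotype and sample table order differ")
    if list(expression.columns) != list(samples["sample_id"]):
        raise ValidationError("expression and sample table order differ")
    out = records.copy()
    p_ebv = np.empty(len(out))
    p_expr = np.empty(len(out))
    ebv_cache: dict[str, float] = {}
    vidx = {v: j for j, v in enumerate(genotypes.variant_ids)}
    for i, row in enumerate(out.itertuples(index=False)):
        dose = genotypes.dosages[:, vidx[row.variant_id]]
        if row.variant_id not in ebv_cache:
            ebv_cache[row.variant_id] = ebv_association(
                dose, samples, covariates, interactions
            ).p
        p_ebv[i] = ebv_cache[row.variant_id]
        p_expr[i] = expression_association(
            dose, expression.loc[row.gene_id].to_numpy(), samples,
            covariates, interactions,
        ).p
    out["p_ebv"] = p_ebv
    out["p_expression"] = p_expr
    return out


def filter_eqtls(records: pd.DataFrame, fdr_target: float = 0.05) -> pd.DataFrame:
    """BH within each family per tissue; keep records with both FDRs < target.

    Input must carry p_ebv and p_expression columns.  Returns all records
    with fdr_ebv / fdr_expression attached plus a boolean ``filtered``;
    the filtered eQTLs are the rows where it is True.
    """
    out = records.copy()
    out["fdr_ebv"] = np.nan
    out["fdr_expression"] = np.nan
    for tissue, idx in out.groupby("tissue").groups.items():
        out.loc[idx, "fdr_ebv"] = bh_fdr(out.loc[idx, "p_ebv"].to_numpy())
        out.loc[idx, "fdr_expression"] = bh_fdr(
            out.loc[idx, "p_expression"].to_numpy()
        )
    out["filtered"] = (out["fdr_ebv"] < fdr_target) & (
        out["fdr_expression"] < fdr_target
    )
    return out


def filtered_counts(records: pd.DataFrame) -> pd.DataFrame:
    """Per-(tissue, class) filtered totals plus the bookkeeping identity
    total = cis + trans within each tissue."""
    filt = records[records["filtered"]]
    counts = (
        filt.groupby(["tissue", "eqtl_class"], observed=True)
        .size()
        .rename("n")
        .reset_index()
    )
    totals = filt.groupby("tissue").size().rename("n").reset_index()
    totals["eqtl_class"] = "total"
    return pd.concat([counts, totals[counts.columns]], ignore_index=True)
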