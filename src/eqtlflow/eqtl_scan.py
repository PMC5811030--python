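"""Single-tissue cis/trans eQTL scan by matrix linear models.

Both genotype and expression rows are residualised against the covariate
space, standardised to unit norm, and correlated by one blockwise matrix
product.  The per-pair correlation r maps to a t statistic with
df = n - rank(covariates) - 1 and a two-sided p-value; a pair is *cis*
when the SNP lies within [gene start - W, gene end + W] (W the cis
window), otherwise *trans*.  Cis pairs are retained at p < p_cis and
trans pairs at p < p_trans, with Benjamini-Hochberg FDR computed
separately within each (tissue, class).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenotypeMatrix, RunConfig, ValidationError

EQTL_COLUMNS = [
    "variant_id", "gene_id", "tissue", "eqtl_class",
    "snp_chrom", "distance", "r", "t", "p", "fdr_eqtl",
]


@dataclass
class ScanDesign:
    """Covariate matrix (samples x p) shared by genotypes and expression."""

    covariates: np.ndarray
    sample_ids: list[str]

    def __post_init__(self):
        self.covariates = np.asarray(self.covariates, dtype=float)
        n, p = self.covariates.shape
        if n != len(self.sample_ids):
            raise ValidationError("covariate rows do not match sample ids")
        if np.linalg.matrix_rank(self.covariates) < p:
            raise ValidationError("covariate matrix is rank deficient")
        if n <= p + 2:
            raise ValidationError("too few samples for the design")

    @property
    def rank(self) -> int:
        return self.covariates.shape[1]

    @property
    def df_residual(self) -> int:
        return len(self.sample_ids) - self.rank - 1

    @classmethod
    def from_groups(cls, samples: pd.DataFrame) -> "ScanDesign":
        """Intercept + two indicator columns for the three EBV groups."""
        groups = samples["group"].to_numpy()
        design = np.column_stack(
            [
                np.ones(len(groups)),
                (groups == "medium").astype(float),
                (groups == "high").astype(float),
            ]
        )
        return cls(design, list(samples["sample_id"]))


def residualize(matrix: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Replace each row (variable x samples) by its OLS residual."""
    x = np.asarray(covariates, dtype=float)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValidationError("covariate matrix is rank deficient")
    y = np.asarray(matrix, dtype=float)
    coef, *_ = np.linalg.lstsq(x, y.T, rcond=None)
    return y - (x @ coef).T


def _standardize_rows(resid: np.ndarray, labels: list[str]):
    """Unit-norm rows; zero-variance rows are dropped with a warning."""
    norms = np.linalg.norm(resid, axis=1)
    keep = norms > 1e-12
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} zero-variance rows from the scan",
            stacklevel=3,
        )
    kept_labels = [l for l, k in zip(labels, keep) if k]
    return resid[keep] / norms[keep, None], kept_labels


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def r_to_t(r: np.ndarray, df: int) -> np.ndarray:
    r = np.clip(r, -(1 - 1e-12), 1 - 1e-12)
    return r * np.sqrt(df / (1.0 - r * r))


def scan(
    genotypes: GenotypeMatrix,
    expression: pd.DataFrame,
    variants: pd.DataFrame,
    genes: pd.DataFrame,
    design: ScanDesign,
    tissue: str,
    config: RunConfig | None = None,
    sample_weights: np.ndarray | None = None,
    block_size: int = 2_000,
) -> pd.DataFrame:
    """Run the scan and return retained pairs as an eQTL record table.

    ``expression`` is a genes x samples matrix of normalised values whose
    columns match ``design.sample_ids`` (the same order as the genotype
    rows).  Missing dosages are mean-imputed per variant before
    residualisation.  When ``sample_weights`` is given (the optional
    weighted mode) all rows and the covariates are scaled by sqrt(w).
    """
    config = config or RunConfig()
    if genotypes.sample_ids != design.sample_ids:
        raise ValidationError("genotype sample order differs from design")
    if list(expression.columns) != design.sample_ids:
        raise ValidationError("expression sample order differs from design")

    g = genotypes.dosages.T.copy()  # variants x samples
    # mean-impute residual missingness so the matrix product is defined
    mask = np.isnan(g)
    if mask.any():
        col_means = np.nanmean(g, axis=1)
        g[mask] = np.take(col_means, np.nonzero(mask)[0])
    e = expression.to_numpy(dtype=float)
    cov = design.covariates
    if sample_weights is not None:
        sw = np.sqrt(np.asarray(sample_weights, dtype=float))
        g = g * sw
        e = e * sw
        cov = cov * sw[:, None]

    g_res, g_ids = _standardize_rows(residualize(g, cov), genotypes.variant_ids)
    e_res, e_ids = _standardize_rows(residualize(e, cov), list(expression.index))
    if not g_ids or not e_ids:
        raise ValidationError("no variable rows left after residualisation")

    vpos = variants.set_index("variant_id").loc[g_ids]
    snp_chrom = vpos["chrom"].to_numpy()
    snp_pos = vpos["pos"].to_numpy()
    gpos = genes.set_index("gene_id").loc[e_ids]
    gene_chrom = gpos["chrom"].to_numpy()
    gene_start = gpos["start"].to_numpy()
    gene_end = gpos["end"].to_numpy()

    df = design.df_residual
    w = config.cis_window_bp
    frames = []
    for lo in range(0, len(e_ids), block_size):
        hi = min(lo + block_size, len(e_ids))
        r = g_res @ e_res[lo:hi].T  # variants x gene-block
        same = snp_chrom[:, None] == gene_chrom[None, lo:hi]
        cis = same & (
            (snp_pos[:, None] >= gene_start[None, lo:hi] - w)
            & (snp_pos[:, None] <= gene_end[None, lo:hi] + w)
        )
        t = r_to_t(r, df)
        p = 2.0 * stats.t.sf(np.abs(t), df)
        keep = np.where(cis, p < config.p_cis, p < config.p_trans)
        vi, gi = np.nonzero(keep)
        if vi.size == 0:
            continue
        frames.append(
            pd.DataFrame(
                {
                    "variant_id": np.asarray(g_ids, dtype=object)[vi],
                    "gene_id": np.asarray(e_ids, dtype=object)[gi + lo],
                    "tissue": tissue,
                    "eqtl_class": np.where(cis[vi, gi], "cis", "trans"),
                    "snp_chrom": snp_chrom[vi],
                    "distance": snp_pos[vi] - gene_start[gi + lo],
                    "r": r[vi, gi],
                    "t": t[vi, gi],
                    "p": np.maximum(p[vi, gi], np.finfo(float).tiny),
                }
            )
        )
    if frames:
        records = pd.concat(frames, ignore_index=True)
    else:
        records = pd.DataFrame(columns=EQTL_COLUMNS[:-1])
    records["fdr_eqtl"] = np.nan
    for cls in ("cis", "trans"):
        sel = records["eqtl_class"] == cls
        if sel.any():
            records.loc[sel, "fdr_eqtl"] = bh_fdr(records.loc[sel, "p"].to_numpy())
    return records[EQTL_COLUMNS].sort_values(
        ["eqtl_class", "p"], kind="mergesort"
    ).reset_index(drop=True)
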