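"""Gene filtering and normalisation of RNA-seq count matrices.

The stages mirror the usual limma-style preparation: drop genes whose mean
count does not exceed a threshold, transform to log2 counts-per-million
with the 0.5 / +1 offsets, and derive per-observation precision weights
from a lowess mean-variance trend fitted to sqrt residual standard
deviations of a per-gene OLS fit.

Library sizes are computed on the filtered matrix (filter first, then
normalise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io_formats import ValidationError

WEIGHT_FLOOR = 1e-6
WEIGHT_CEIL = 1e6
LOWESS_SPAN = 0.5


@dataclass
class ExpressionSet:
    """Per-tissue expression container: counts, log2-CPM and weights."""

    tissue: str
    counts: pd.DataFrame          # genes x samples, integer
    logcpm: pd.DataFrame          # same shape, float
    weights: pd.DataFrame         # same shape, float > 0
    trend: "MeanVarianceTrend | None" = None

    def __post_init__(self):
        if not (self.counts.shape == self.logcpm.shape == self.weights.shape):
            raise ValidationError("counts/logcpm/weights shapes disagree")
        if not np.isfinite(self.logcpm.to_numpy()).all():
            raise ValidationError("non-finite normalised values")
        if (self.weights.to_numpy() <= 0).any():
            raise ValidationError("non-positive precision weight")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


def filter_low_expression(counts: pd.DataFrame, mean_threshold: float = 5.0) -> pd.DataFrame:
    """Keep genes whose mean count over all samples is strictly > threshold."""
    if (counts.to_numpy() < 0).any():
        raise ValidationError("negative counts")
    keep = counts.mean(axis=1) > mean_threshold
    return counts.loc[keep]


def log_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """log2((count + 0.5) / (library_size + 1) * 1e6), per-sample libraries."""
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    if (lib <= 0).any():
        bad = counts.columns[lib <= 0][0]
        raise ValidationError(f"sample {bad!r} has zero library size")
    values = np.log2((counts.to_numpy(dtype=float) + 0.5) / (lib + 1.0) * 1e6)
    return pd.DataFrame(values, index=counts.index, columns=counts.columns)


@dataclass
class MeanVarianceTrend:
    """Piecewise-linear trend of sqrt residual sd against mean log-count."""

    x: np.ndarray  # sorted knot abscissae (fitted log-cpm)
    y: np.ndarray  # trend values (sqrt sd scale)

    def __call__(self, at: np.ndarray) -> np.ndarray:
        return np.interp(at, self.x, self.y)


def _ols_fit(y: np.ndarray, design: np.ndarray):
    """Row-wise OLS of y (genes x samples) on design (samples x p)."""
    coef, *_ = np.linalg.lstsq(design, y.T, rcond=None)
    fitted = (design @ coef).T
    resid = y - fitted
    return fitted, resid


def mean_variance_weights(
    logcpm: pd.DataFrame,
    design: np.ndarray | None = None,
    span: float = LOWESS_SPAN,
) -> tuple[pd.DataFrame, MeanVarianceTrend]:
    """Precision weights from a lowess trend of sqrt-sd vs mean log-cpm.

    Per gene, fit OLS on the design, take sqrt of the residual standard
    deviation, smooth it against the gene's mean log-cpm, then evaluate the
    interpolated trend at every observation's fitted value; the weight is
    trend**-4 clipped to [1e-6, 1e6].
    """
    y = logcpm.to_numpy(dtype=float)
    n_genes, n_samples = y.shape
    if n_samples < 4:
        raise ValidationError("need >= 4 samples for a mean-variance trend")
    if design is None:
        design = np.ones((n_samples, 1))
    design = np.asarray(design, dtype=float)
    rank = np.linalg.matrix_rank(design)
    if n_samples < design.shape[1] + 1:
        raise ValidationError("fewer samples than design columns + 1")

    fitted, resid = _ols_fit(y, design)
    df_resid = n_samples - rank
    sd = np.sqrt((resid ** 2).sum(axis=1) / df_resid)
    sqrt_sd = np.sqrt(sd)
    mean_log = y.mean(axis=1)

    smooth = lowess(sqrt_sd, mean_log, frac=span, return_sorted=True)
    # collapse duplicate abscissae so np.interp sees strictly sorted knots
    knots = pd.DataFrame(smooth, columns=["x", "y"]).groupby("x", sort=True).mean()
    trend = MeanVarianceTrend(knots.index.to_numpy(), knots["y"].to_numpy())

    w = np.clip(trend(fitted) ** -4.0, WEIGHT_FLOOR, WEIGHT_CEIL)
    weights = pd.DataFrame(w, index=logcpm.index, columns=logcpm.columns)
    return weights, trend


def prepare_expression(
    counts: pd.DataFrame,
    tissue: str,
    design: np.ndarray | None = None,
    mean_threshold: float = 5.0,
    sample_weights: np.ndarray | None = None,
) -> ExpressionSet:
    """Filter, normalise and weight a raw count matrix.

    ``sample_weights`` (optional, length n_samples) are multiplied into the
    gene-wise precision weights; this replaces full array-weight
    estimation.
    """
    filtered = filter_low_expression(counts, mean_threshold)
    if filtered.empty:
        raise ValidationError("no genes pass the mean-count filter")
    norm = log_cpm(filtered)
    weights, trend = mean_variance_weights(norm, design)
    if sample_weights is not None:
        sw = np.asarray(sample_weights, dtype=float)
        if sw.shape != (norm.shape[1],) or (sw <= 0).any():
            raise ValidationError("sample weights must be positive, one per sample")
        weights = weights * sw[np.newaxis, :]
    return ExpressionSet(tissue, filtered, norm, weights, trend)
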