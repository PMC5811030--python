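"""Variant-level genotype QC: call rate, Hardy-Weinberg exact test, minor
allele frequency, and sliding-window LD pruning.

Filters apply in the fixed order call-rate -> HWE -> MAF -> LD prune, and
each removed variant is attributed to the first filter it fails.  Call
rate, MAF and HWE use strict inequalities (keep if metric > threshold).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix, RunConfig, ValidationError


@dataclass
class QcReport:
    n_input: int
    n_removed_callrate: int
    n_removed_hwe: int
    n_removed_maf: int
    n_removed_ld: int
    n_retained: int

    def __post_init__(self):
        removed = (
            self.n_removed_callrate + self.n_removed_hwe
            + self.n_removed_maf + self.n_removed_ld
        )
        if self.n_input - removed != self.n_retained:
            raise ValidationError("QC report arithmetic does not balance")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": ["input", "call_rate", "hwe", "maf", "ld_prune", "retained"],
                "n": [
                    self.n_input,
                    self.n_removed_callrate,
                    self.n_removed_hwe,
                    self.n_removed_maf,
                    self.n_removed_ld,
                    self.n_retained,
                ],
            }
        )


def call_rate(column: np.ndarray) -> float:
    """Fraction of non-missing calls in a variant column."""
    column = np.asarray(column, dtype=float)
    if column.size == 0:
        raise ValidationError("empty genotype column")
    return float(np.count_nonzero(~np.isnan(column)) / column.size)


def genotype_counts(column: np.ndarray) -> tuple[int, int, int]:
    """(n_AA, n_AB, n_BB) over non-missing calls; dosage counts B."""
    column = np.asarray(column, dtype=float)
    obs = column[~np.isnan(column)]
    return (
        int((obs == 0).sum()),
        int((obs == 1).sum()),
        int((obs == 2).sum()),
    )


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Two-sided Hardy-Weinberg exact test p-value.

    Sums, over all heterozygote counts consistent with the observed allele
    counts, the conditional probabilities that do not exceed that of the
    observed configuration (the standard exact-test construction used by
    common GWAS toolkits, without the mid-p adjustment).
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValidationError("negative genotype count")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValidationError("all-zero genotype counts")
    n_b = 2 * n_bb + n_ab  # copies of the rarer-coded allele
    n_a = 2 * n_aa + n_ab
    rare = min(n_a, n_b)

    # P(het = h | allele counts) computed by the stable recurrence over h
    # of matching parity; normalised at the end.
    h_obs = n_ab
    hs = list(range(rare % 2, rare + 1, 2))
    probs = {}
    h_mid = hs[len(hs) // 2]
    probs[h_mid] = 1.0
    # upward recurrence: p(h+2)/p(h) = hom_a*hom_b ... derived from the
    # hypergeometric-form conditional distribution
    h = h_mid
    while h + 2 <= rare:
        # counts at het = h: rare homozygotes and common homozygotes
        n_rr = (rare - h) // 2
        n_cc = n - h - n_rr
        probs[h + 2] = probs[h] * (4.0 * n_rr * n_cc) / ((h + 2.0) * (h + 1.0))
        h += 2
    h = h_mid
    while h - 2 >= hs[0]:
        n_rr = (rare - h) // 2
        n_cc = n - h - n_rr
        probs[h - 2] = probs[h] * (h * (h - 1.0)) / (4.0 * (n_rr + 1.0) * (n_cc + 1.0))
        h -= 2
    total = sum(probs.values())
    p_obs = probs[h_obs] / total
    # 1 + 1e-12 guard against ties lost to floating-point rounding
    p = sum(v for v in probs.values() if v / total <= p_obs * (1 + 1e-12)) / total
    return float(min(p, 1.0))


def minor_allele_frequency(column: np.ndarray) -> float:
    """min(f_B, 1 - f_B) over non-missing calls."""
    column = np.asarray(column, dtype=float)
    obs = column[~np.isnan(column)]
    if obs.size == 0:
        raise ValidationError("all calls missing")
    f_b = float(obs.sum() / (2 * obs.size))
    return min(f_b, 1.0 - f_b)


def ld_r2(col_i: np.ndarray, col_j: np.ndarray) -> float:
    """Squared Pearson correlation of dosages over pairwise-complete samples.

    Zero variance in either column yields 0 (no prunable signal).
    """
    col_i = np.asarray(col_i, dtype=float)
    col_j = np.asarray(col_j, dtype=float)
    ok = ~np.isnan(col_i) & ~np.isnan(col_j)
    if ok.sum() < 2:
        raise ValidationError("fewer than 2 pairwise-complete samples")
    x, y = col_i[ok], col_j[ok]
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = float(np.corrcoef(x, y)[0, 1])
    return min(r * r, 1.0)


def ld_prune(
    matrix: GenotypeMatrix,
    variants: pd.DataFrame,
    window_bp: int = 5_000,
    step_bp: int = 5_000,
    r2_max: float = 0.8,
) -> list[str]:
    """Greedy left-to-right sliding-window pruning; returns retained ids.

    Within each bp window, every pair with r^2 > ``r2_max`` loses the
    variant with the lower MAF (tie: the later position is removed).
    Windows advance by ``step_bp`` per chromosome.
    """
    v = variants.set_index("variant_id").loc[matrix.variant_ids].reset_index()
    removed: set[str] = set()
    maf = {
        vid: minor_allele_frequency(matrix.dosages[:, j])
        for j, vid in enumerate(matrix.variant_ids)
    }
    col = {vid: matrix.dosages[:, j] for j, vid in enumerate(matrix.variant_ids)}

    for chrom, grp in v.groupby("chrom", sort=False):
        grp = grp.sort_values("pos", kind="mergesort")
        ids = list(grp["variant_id"])
        pos = dict(zip(grp["variant_id"], grp["pos"]))
        if not ids:
            continue
        lo = int(grp["pos"].min())
        hi = int(grp["pos"].max())
        start = lo
        while start <= hi:
            window = [
                vid for vid in ids
                if start <= pos[vid] < start + window_bp and vid not in removed
            ]
            for a_idx in range(len(window)):
                a = window[a_idx]
                if a in removed:
                    continue
                for b_idx in range(a_idx + 1, len(window)):
                    b = window[b_idx]
                    if a in removed:
                        break
                    if b in removed:
                        continue
                    if ld_r2(col[a], col[b]) > r2_max:
                        if maf[a] < maf[b]:
                            removed.add(a)
                        elif maf[b] < maf[a]:
                            removed.add(b)
                        else:  # tie -> remove the later position
                            removed.add(b if pos[b] >= pos[a] else a)
            start += step_bp
    return [vid for vid in matrix.variant_ids if vid not in removed]


def run_qc(
    matrix: GenotypeMatrix,
    variants: pd.DataFrame,
    config: RunConfig | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame, QcReport]:
    """Full filter chain; returns (filtered matrix, filtered variants, report)."""
    import warnings

    config = config or RunConfig()
    n_input = matrix.n_variants

    keep_cr = [
        vid for j, vid in enumerate(matrix.variant_ids)
        if call_rate(matrix.dosages[:, j]) > config.call_rate_min
    ]
    n_cr = n_input - len(keep_cr)

    m = matrix.subset_variants(keep_cr)
    keep_hwe = [
        vid for j, vid in enumerate(m.variant_ids)
        if hwe_exact_test(*genotype_counts(m.dosages[:, j])) > config.hwe_p_min
    ]
    n_hwe = m.n_variants - len(keep_hwe)

    m = m.subset_variants(keep_hwe)
    keep_maf = [
        vid for j, vid in enumerate(m.variant_ids)
        if minor_allele_frequency(m.dosages[:, j]) > config.maf_min
    ]
    n_maf = m.n_variants - len(keep_maf)

    m = m.subset_variants(keep_maf)
    keep_ld = ld_prune(
        m, variants, config.ld_window_bp, config.ld_step_bp, config.ld_r2_max
    )
    n_ld = m.n_variants - len(keep_ld)
    m = m.subset_variants(keep_ld)

    if m.n_variants == 0:
        warnings.warn("QC removed every variant", stacklevel=2)

    report = QcReport(n_input, n_cr, n_hwe, n_maf, n_ld, m.n_variants)
    out_variants = variants[variants["variant_id"].isin(m.variant_ids)].reset_index(drop=True)
    return m, out_variants, report
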