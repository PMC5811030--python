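import math

import numpy as np
import pandas as pd
import pytest

from eqtlflow.genotype_qc import (
    QcReport,
    call_rate,
    genotype_counts,
    hwe_exact_test,
    ld_prune,
    ld_r2,
    minor_allele_frequency,
    run_qc,
)
from eqtlflow.io_formats import GenotypeMatrix, RunConfig, ValidationError, make_variant_table
from conftest import random_genotypes


# -------------------------------------------------------------- call rate


def test_call_rate_no_missing():
    assert call_rate(np.zeros(48)) == 1.0


@pytest.mark.parametrize(
    "n_missing,expected,kept",
    [(3, 45 / 48, False), (2, 46 / 48, True)],
)
def test_call_rate_boundary(n_missing, expected, kept):
    col = np.zeros(48)
    col[:n_missing] = np.nan
    rate = call_rate(col)
    assert rate == pytest.approx(expected)
    assert (rate > 0.95) is kept


# ------------------------------------------------------------------- HWE


def hwe_enumeration_oracle(n_aa, n_ab, n_bb):
    """Exhaustive enumeration over heterozygote counts of matching parity
    with the exact multinomial-conditional (hypergeometric-form) weights."""
    n = n_aa + n_ab + n_bb
    rare = min(2 * n_aa + n_ab, 2 * n_bb + n_ab)
    probs = {}
    for h in range(rare % 2, rare + 1, 2):
        n_rr = (rare - h) // 2
        n_cc = n - h - n_rr
        probs[h] = (
            math.factorial(n)
            / (math.factorial(n_rr) * math.factorial(n_cc) * math.factorial(h))
            * 2.0 ** h
        )
    total = sum(probs.values())
    p_obs = probs[n_ab] / total
    return sum(v for v in probs.values() if v / total <= p_obs * (1 + 1e-12)) / total


def test_hwe_monomorphic_is_one():
    assert hwe_exact_test(48, 0, 0) == 1.0
    assert hwe_exact_test(0, 0, 31) == 1.0


def test_hwe_matches_enumeration_oracle_352():
    assert hwe_exact_test(3, 5, 2) == pytest.approx(
        hwe_enumeration_oracle(3, 5, 2), rel=1e-12
    )


@pytest.mark.parametrize(
    "counts",
    [(10, 20, 10), (0, 10, 0), (25, 1, 22), (7, 0, 7), (40, 7, 1), (1, 1, 1)],
)
def test_hwe_matches_enumeration_oracle_grid(counts):
    assert hwe_exact_test(*counts) == pytest.approx(
        hwe_enumeration_oracle(*counts), rel=1e-10
    )


def test_hwe_probabilities_sum_to_one():
    # re-derive the conditional distribution the test sums over and check
    # total mass 1 (enumeration oracle self-check)
    n_aa, n_ab, n_bb = 12, 9, 6
    n = n_aa + n_ab + n_bb
    rare = min(2 * n_aa + n_ab, 2 * n_bb + n_ab)
    total = 0.0
    weights = []
    for h in range(rare % 2, rare + 1, 2):
        n_rr = (rare - h) // 2
        n_cc = n - h - n_rr
        weights.append(
            math.factorial(n)
            / (math.factorial(n_rr) * math.factorial(n_cc) * math.factorial(h))
            * 2.0 ** h
        )
    normalised = [w / sum(weights) for w in weights]
    assert sum(normalised) == pytest.approx(1.0, abs=1e-12)


def test_hwe_threshold_keeps_and_removes():
    # excess heterozygosity strong enough to cross the 1e-4 ceiling
    p_extreme = hwe_exact_test(24, 0, 24)
    assert p_extreme < 1e-4  # removed under "keep if p > 1e-4"
    p_mild = hwe_exact_test(14, 22, 12)
    assert p_mild > 1e-4  # kept


def test_hwe_all_zero_errors():
    with pytest.raises(ValidationError):
        hwe_exact_test(0, 0, 0)


# ------------------------------------------------------------------- MAF


@pytest.mark.parametrize(
    "dosages,expected",
    [([0, 0, 0, 0], 0.0), ([2, 2, 2, 2], 0.0), ([0, 1, 1, 2], 0.5)],
)
def test_maf_cases(dosages, expected):
    assert minor_allele_frequency(np.array(dosages, float)) == pytest.approx(expected)


def test_maf_all_missing_errors():
    with pytest.raises(ValidationError):
        minor_allele_frequency(np.array([np.nan, np.nan]))


# -------------------------------------------------------------------- LD


def test_ld_r2_identical_columns():
    col = np.array([0, 1, 2, 1, 0], float)
    assert ld_r2(col, col) == pytest.approx(1.0)


def test_ld_r2_orthogonal():
    assert ld_r2(np.array([0, 0, 1, 1], float), np.array([0, 1, 0, 1], float)) == 0.0


def test_ld_r2_matches_pearson_oracle(rng):
    x = rng.integers(0, 3, 20).astype(float)
    y = np.clip(x + rng.integers(-1, 2, 20), 0, 2).astype(float)
    expected = np.corrcoef(x, y)[0, 1] ** 2
    assert ld_r2(x, y) == pytest.approx(expected, abs=1e-12)


def test_ld_r2_zero_variance_defined_as_zero():
    assert ld_r2(np.ones(6), np.array([0, 1, 2, 0, 1, 2], float)) == 0.0


def brute_force_prune(matrix, variants, window_bp, step_bp, r2_max):
    """Independent re-statement of the removal rule, pair by pair."""
    v = variants.set_index("variant_id").loc[matrix.variant_ids].reset_index()
    maf = {
        vid: minor_allele_frequency(matrix.dosages[:, j])
        for j, vid in enumerate(matrix.variant_ids)
    }
    col = {vid: matrix.dosages[:, j] for j, vid in enumerate(matrix.variant_ids)}
    removed = set()
    for chrom, grp in v.groupby("chrom", sort=False):
        grp = grp.sort_values("pos")
        pos = dict(zip(grp["variant_id"], grp["pos"]))
        start = int(grp["pos"].min())
        while start <= int(grp["pos"].max()):
            ids = [
                x for x in grp["variant_id"]
                if start <= pos[x] < start + window_bp and x not in removed
            ]
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    a, b = ids[i], ids[j]
                    if a in removed or b in removed:
                        continue
                    if ld_r2(col[a], col[b]) > r2_max:
                        if maf[a] < maf[b]:
                            removed.add(a)
                        elif maf[b] < maf[a]:
                            removed.add(b)
                        else:
                            removed.add(b if pos[b] >= pos[a] else a)
            start += step_bp
    return [x for x in matrix.variant_ids if x not in removed]


def test_ld_prune_all_independent_retained(rng):
    matrix, variants = random_genotypes(rng, 100, 12, spacing=50)
    # independence makes r2 small with very high probability at n=100
    kept = ld_prune(matrix, variants, 5_000, 5_000, 0.8)
    assert kept == matrix.variant_ids


def test_ld_prune_duplicate_pair_keeps_earlier(rng):
    base = rng.binomial(2, 0.4, size=30).astype(float)
    dosages = np.column_stack([base, base])
    variants = make_variant_table(
        pd.DataFrame(
            {"variant_id": ["a", "b"], "chrom": "1", "pos": [100, 200]}
        )
    )
    matrix = GenotypeMatrix(dosages, [f"s{i}" for i in range(30)], ["a", "b"])
    assert ld_prune(matrix, variants) == ["a"]  # equal MAF tie -> later removed


def test_ld_prune_matches_brute_force_oracle(rng):
    # 30 correlated variants: LD blocks via haplotype copying
    n, m = 60, 30
    hap = np.empty((2 * n, m))
    for j in range(m):
        fresh = rng.random(2 * n) < 0.3
        if j % 5 != 0:
            keep = rng.random(2 * n) < 0.97
            hap[:, j] = np.where(keep, hap[:, j - 1], fresh)
        else:
            hap[:, j] = fresh
    dosages = hap[:n] + hap[n:]
    ids = [f"v{j:02d}" for j in range(m)]
    variants = make_variant_table(
        pd.DataFrame({"variant_id": ids, "chrom": "1", "pos": 1 + 400 * np.arange(m)})
    )
    matrix = GenotypeMatrix(dosages, [f"s{i}" for i in range(n)], ids)
    kept = ld_prune(matrix, variants, 5_000, 5_000, 0.8)
    assert kept == brute_force_prune(matrix, variants, 5_000, 5_000, 0.8)
    assert len(kept) < m  # something was actually pruned


def test_ld_prune_idempotent(rng):
    matrix, variants = random_genotypes(rng, 50, 40, spacing=300)
    # add strong LD by duplicating some columns
    matrix.dosages[:, 1] = matrix.dosages[:, 0]
    matrix.dosages[:, 21] = matrix.dosages[:, 20]
    kept = ld_prune(matrix, variants)
    pruned = matrix.subset_variants(kept)
    assert ld_prune(pruned, variants) == kept


# ----------------------------------------------------------------- run_qc


def test_run_qc_nothing_fails(rng):
    matrix, variants = random_genotypes(rng, 80, 15, maf_low=0.25, spacing=50_000)
    filtered, _, report = run_qc(matrix, variants)
    assert (
        report.n_removed_callrate,
        report.n_removed_hwe,
        report.n_removed_maf,
        report.n_removed_ld,
    ) == (0, 0, 0, 0)
    assert report.n_retained == matrix.n_variants
    np.testing.assert_array_equal(filtered.dosages, matrix.dosages)


def test_run_qc_one_designed_failure_per_filter(rng):
    n = 48
    good = lambda: rng.binomial(2, 0.35, n).astype(float)
    cols, ids, pos = [], [], []

    fail_cr = good()
    fail_cr[:3] = np.nan  # call rate 45/48 < 0.95
    fail_hwe = np.array([0.0, 2.0] * (n // 2))  # no hets at 50/50 alleles
    fail_maf = np.zeros(n)
    fail_maf[0] = 1.0  # MAF 1/96 < 0.05
    keeper = good()
    dup = keeper.copy()  # r2 = 1 with keeper, same window
    for name, col, p in [
        ("cr", fail_cr, 100),
        ("hwe", fail_hwe, 200),
        ("maf", fail_maf, 300),
        ("keep", keeper, 400),
        ("dup", dup, 500),
    ]:
        ids.append(name)
        cols.append(col)
        pos.append(p)
    matrix = GenotypeMatrix(
        np.column_stack(cols), [f"s{i}" for i in range(n)], ids
    )
    variants = make_variant_table(
        pd.DataFrame({"variant_id": ids, "chrom": "1", "pos": pos})
    )
    filtered, _, report = run_qc(matrix, variants)
    assert (
        report.n_removed_callrate,
        report.n_removed_hwe,
        report.n_removed_maf,
        report.n_removed_ld,
    ) == (1, 1, 1, 1)
    assert filtered.variant_ids == ["keep"]


def test_run_qc_equals_sequential_filters(rng):
    matrix, variants = random_genotypes(rng, 60, 300, maf_low=0.01, spacing=700)
    # inject missingness and LD
    miss = rng.random(matrix.dosages.shape) < 0.03
    matrix.dosages[miss] = np.nan
    for j in range(0, 300, 7):
        if j + 1 < 300:
            matrix.dosages[:, j + 1] = matrix.dosages[:, j]
    config = RunConfig()

    stage = [
        v for j, v in enumerate(matrix.variant_ids)
        if call_rate(matrix.dosages[:, j]) > config.call_rate_min
    ]
    m1 = matrix.subset_variants(stage)
    stage = [
        v for j, v in enumerate(m1.variant_ids)
        if hwe_exact_test(*genotype_counts(m1.dosages[:, j])) > config.hwe_p_min
    ]
    m2 = m1.subset_variants(stage)
    stage = [
        v for j, v in enumerate(m2.variant_ids)
        if minor_allele_frequency(m2.dosages[:, j]) > config.maf_min
    ]
    m3 = m2.subset_variants(stage)
    expected = ld_prune(m3, variants, config.ld_window_bp, config.ld_step_bp,
                        config.ld_r2_max)

    filtered, _, report = run_qc(matrix, variants, config)
    assert filtered.variant_ids == expected
    assert report.n_input == 300
    assert report.n_retained == len(expected)


def test_qc_report_balance_enforced():
    with pytest.raises(ValidationError):
        QcReport(10, 1, 1, 1, 1, 5)
    report = QcReport(10, 1, 2, 3, 0, 4)
    assert report.n_input == report.n_retained + 6
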