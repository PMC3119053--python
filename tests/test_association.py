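"""Allelic association, the dual significance rule, epistasis scan and LD."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from piebaldnet.association import (
    allelic_odds_ratio,
    epistasis_scan,
    ld_r2,
    reconstruct_allele_counts,
    significant_snps,
    snp_association,
)
from piebaldnet.genotypes import CASE, CONTROL, MISSING

from conftest import make_table


def brute_chi2(observed):
    """Independent oracle: cell-by-cell sum of (O-E)^2/E over positive-E cells."""
    observed = np.asarray(observed, dtype=float)
    n = observed.sum()
    rows = observed.sum(axis=1, keepdims=True)
    cols = observed.sum(axis=0, keepdims=True)
    expected = rows * cols / n
    mask = expected > 0
    return float((((observed - expected) ** 2)[mask] / expected[mask]).sum())


# ---------------------------------------------------------------------------
# Odds ratios


@pytest.mark.parametrize(
    "table,expected",
    [
        ((26, 22, 126, 18), 5.92),  # allele table behind freqs 0.54 / 0.88
        ((38, 10, 59, 85), 5.47),  # 0.79 / 0.41
    ],
)
def test_odds_ratio_worked_examples(table, expected):
    assert allelic_odds_ratio(*table) == pytest.approx(expected, abs=0.005)


def test_odds_ratio_null_and_zero_cells():
    assert allelic_odds_ratio(10, 10, 20, 20) == 1.0
    assert np.isnan(allelic_odds_ratio(10, 0, 5, 5))
    assert allelic_odds_ratio(0, 10, 0, 20) == 1.0  # both groups monomorphic


@given(st.tuples(*[st.integers(1, 50)] * 4))
def test_odds_ratio_oriented_and_label_invariant(cells):
    a, b, c, d = cells
    orr = allelic_odds_ratio(a, b, c, d)
    swapped = allelic_odds_ratio(b, a, d, c)  # relabel B <-> b
    assert orr >= 1.0
    assert orr == pytest.approx(swapped)


def test_reconstruction_from_printed_summaries():
    # unambiguous case: frequencies pin the counts down exactly
    assert reconstruct_allele_counts(0.79, 0.41, 48, 144) == (38, 10, 59, 85)
    # ambiguous control count resolved by the published OR
    assert reconstruct_allele_counts(0.54, 0.88, 48, 144, printed_or=5.92) == (
        26, 22, 126, 18,
    )
    with pytest.raises(ValueError):
        reconstruct_allele_counts(0.54, 0.88, 48, 144)  # ambiguous, no OR given


# ---------------------------------------------------------------------------
# Single-SNP association


def test_association_statistics_match_brute_force():
    # cases: 2,2,1,1 -> B count 6/8 alleles; controls 0,0,1,1 -> 2/8
    calls = [[2], [2], [1], [1], [0], [0], [1], [1]]
    table = make_table(calls, labels=[CASE] * 4 + [CONTROL] * 4)
    (rec,) = snp_association(table)
    assert rec.freq_case == pytest.approx(6 / 8)
    assert rec.freq_control == pytest.approx(2 / 8)
    assert rec.geno_diff == pytest.approx(1.5 - 0.5)
    expect = brute_chi2([[6, 2], [2, 6]])
    assert rec.chi2 == pytest.approx(expect)
    assert rec.p_value == pytest.approx(stats.chi2.sf(expect, 1))
    assert rec.df == 1


def test_chi2_on_reconstructed_count_table():
    chi2 = brute_chi2([[26, 22], [126, 18]])
    assert chi2 == pytest.approx(24.25, abs=0.1)
    n = 192
    direct = n * (26 * 18 - 22 * 126) ** 2 / (48 * 144 * 152 * 40)
    assert chi2 == pytest.approx(direct)


def test_identical_frequencies_give_null_statistics():
    calls = [[1], [1], [1], [1]]
    table = make_table(calls, labels=[CASE, CASE, CONTROL, CONTROL])
    (rec,) = snp_association(table)
    assert rec.chi2 == 0.0
    assert rec.p_value == 1.0
    assert rec.odds_ratio == 1.0


def test_association_invariant_to_animal_order():
    rng = np.random.default_rng(9)
    calls = rng.integers(0, 3, size=(10, 4))
    labels = [CASE] * 3 + [CONTROL] * 7
    t1 = make_table(calls, labels=labels)
    perm = rng.permutation(10)
    t2 = make_table(calls[perm], labels=[labels[i] for i in perm])
    r1 = {r.snp_id: r for r in snp_association(t1)}
    r2 = {r.snp_id: r for r in snp_association(t2)}
    for s in r1:
        assert r1[s].chi2 == pytest.approx(r2[s].chi2, nan_ok=True)
        assert r1[s].geno_diff == pytest.approx(r2[s].geno_diff, nan_ok=True)


def test_all_small_2x2_tables_match_oracle():
    """Every allele table with total count <= 12 agrees with direct enumeration."""
    from piebaldnet.association import _pearson_2x2

    for a, b, c, d in itertools.product(range(7), repeat=4):
        if not 0 < a + b + c + d <= 12:
            continue
        chi2, p = _pearson_2x2(a, b, c, d)
        denom = (a + b) * (c + d) * (a + c) * (b + d)
        if denom == 0:
            assert chi2 == 0.0 and p == 1.0
        else:
            assert chi2 == pytest.approx(brute_chi2([[a, b], [c, d]]))


# ---------------------------------------------------------------------------
# Dual significance rule


def test_sd_rule_agrees_with_direct_computation():
    diffs = [0.0] * 9 + [3.0]
    calls = [[1]] * 4
    # build records directly to isolate the rule
    from piebaldnet.association import AssociationRecord

    records = [
        AssociationRecord(f"s{i}", 0.5, 0.5, d, 1.0, 1, 0.0005, 1.0)
        for i, d in enumerate(diffs)
    ]
    significant_snps(records)
    arr = np.array(diffs)
    mean, sd = arr.mean(), arr.std(ddof=0)
    assert mean == pytest.approx(0.3)
    assert sd == pytest.approx(0.9)
    for rec, d in zip(records, diffs):
        assert rec.passes_sd_rule == (abs(d - mean) > 3.0 * sd)


def test_sd_rule_degenerate_spread_flags_nothing():
    from piebaldnet.association import AssociationRecord

    records = [
        AssociationRecord(f"s{i}", 0.5, 0.5, 0.7, 20.0, 1, 1e-6, 2.0) for i in range(5)
    ]
    sig = significant_snps(records)
    assert sig == set()
    assert not any(r.passes_sd_rule for r in records)


def test_significance_is_a_conjunction():
    from piebaldnet.association import AssociationRecord

    # strong p-value but a genotype difference well inside 3 SD
    diffs = [-1.0, 1.0] * 10 + [0.5]
    records = [
        AssociationRecord(f"s{i}", 0.5, 0.5, d, 12.0, 1, 0.0005, 2.0)
        for i, d in enumerate(diffs)
    ]
    sig = significant_snps(records)
    assert "s20" not in sig  # 0.5 is within 3 SD of the mean
    assert not records[-1].significant


# ---------------------------------------------------------------------------
# Epistasis scan


def test_pair_count_combinatorics():
    rng = np.random.default_rng(5)
    calls = rng.integers(0, 3, size=(20, 30))
    table = make_table(calls, labels=[CASE] * 6 + [CONTROL] * 14)
    records = epistasis_scan(table, table.snp_ids[:10])
    assert len(records) == 45  # C(10, 2)
    assert all(r.df == 8 for r in records)
    # unordered pairs stored once
    seen = {frozenset((r.snp_a, r.snp_b)) for r in records}
    assert len(seen) == 45


def test_identical_joint_distribution_is_null():
    # cases and controls have the same joint genotype distribution
    block = [[0, 0], [1, 1], [2, 2], [0, 1]]
    calls = block + block
    table = make_table(calls, labels=[CASE] * 4 + [CONTROL] * 4)
    (rec,) = epistasis_scan(table, ["s0", "s1"])
    assert rec.chi2 == pytest.approx(0.0)
    assert rec.p_value == pytest.approx(1.0)


def test_nine_by_two_table_matches_brute_force():
    case_counts = [4, 2, 0, 2, 4, 0, 0, 0, 0]
    ctrl_counts = [0, 0, 4, 0, 0, 4, 2, 2, 0]
    calls, labels = [], []
    for cell, (nc, nn) in enumerate(zip(case_counts, ctrl_counts)):
        ga, gb = divmod(cell, 3)
        for _ in range(nc):
            calls.append([ga, gb])
            labels.append(CASE)
        for _ in range(nn):
            calls.append([ga, gb])
            labels.append(CONTROL)
    table = make_table(calls, labels=labels)
    (rec,) = epistasis_scan(table, ["s0", "s1"])
    expect = brute_chi2(np.column_stack([case_counts, ctrl_counts]))
    assert rec.chi2 == pytest.approx(expect)
    assert rec.p_value == pytest.approx(stats.chi2.sf(expect, 8))


def test_missing_calls_excluded_pairwise():
    calls = [[0, MISSING], [1, 1], [2, 2], [0, 0], [1, 1], [2, 0]]
    table = make_table(calls, labels=[CASE] * 3 + [CONTROL] * 3)
    (rec,) = epistasis_scan(table, ["s0", "s1"])
    # animal 0 must be dropped; recompute from the remaining five
    obs = np.zeros((9, 2))
    for i, (ga, gb) in enumerate([(1, 1), (2, 2)]):
        obs[ga * 3 + gb, 0] += 1
    for ga, gb in [(0, 0), (1, 1), (2, 0)]:
        obs[ga * 3 + gb, 1] += 1
    assert rec.chi2 == pytest.approx(brute_chi2(obs))


def test_proximity_flag_under_100kb():
    calls = np.random.default_rng(0).integers(0, 3, size=(8, 3))
    table = make_table(
        calls,
        labels=[CASE] * 4 + [CONTROL] * 4,
        chroms=["chr1", "chr1", "chr2"],
        positions=[1_000, 99_000, 50_000],
    )
    recs = {frozenset((r.snp_a, r.snp_b)): r for r in epistasis_scan(table, table.snp_ids)}
    assert recs[frozenset(("s0", "s1"))].proximity_flag  # 98 kb apart, same chrom
    assert not recs[frozenset(("s0", "s2"))].proximity_flag  # different chrom


def test_degenerate_pair_gets_missing_statistics():
    calls = [[0, 0]] * 6
    table = make_table(calls, labels=[CASE] * 3 + [CONTROL] * 3)
    (rec,) = epistasis_scan(table, ["s0", "s1"])
    assert np.isnan(rec.chi2)
    assert not rec.significant


# ---------------------------------------------------------------------------
# LD


def test_ld_r2_examples():
    table = make_table([[0, 0, 1], [0, 0, 1], [2, 2, 0], [2, 2, 2], [1, 1, 1]])
    assert ld_r2(table, "s0", "s1") == pytest.approx(1.0)
    ga = np.array([0, 1, 2, 0, 1])
    gb = np.array([1, 1, 0, 2, 1])
    table2 = make_table(np.column_stack([ga, gb]))
    expect = np.corrcoef(ga, gb)[0, 1] ** 2
    assert ld_r2(table2, "s0", "s1") == pytest.approx(expect)


def test_ld_r2_sign_free_and_degenerate():
    table = make_table([[0, 2], [0, 2], [2, 0], [2, 0]])
    assert ld_r2(table, "s0", "s1") == pytest.approx(1.0)  # perfect negative
    table2 = make_table([[1, 0], [1, 1], [1, 2]])
    assert np.isnan(ld_r2(table2, "s0", "s1"))  # zero variance at s0
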