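"""Rank-sum and Spearman statistics against independent brute-force oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from podoquant import (
    compare_cohort,
    correlate_features,
    rank_sum_test,
    signed_rank_test,
    spearman_correlation,
)
from podoquant.simulate import CohortParams, simulate_case_features


# ---------------------------------------------------------------- oracles


def exact_ranksum_p(x, y):
    """Two-sided rank-sum p by full enumeration of group assignments."""
    pooled = np.concatenate([x, y])
    n, nx = len(pooled), len(x)
    ranks = np.argsort(np.argsort(pooled)) + 1.0  # no ties assumed
    observed = ranks[:nx].sum()
    mean = nx * (n + 1) / 2.0
    stats = [
        sum(ranks[list(idx)]) for idx in itertools.combinations(range(n), nx)
    ]
    dev = abs(observed - mean)
    extreme = sum(1 for s in stats if abs(s - mean) >= dev - 1e-12)
    return extreme / len(stats)


def brute_force_spearman(x, y):
    """Average-rank Pearson correlation, written independently of scipy."""

    def average_ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(len(v))
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = average_ranks(x), average_ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / math.sqrt((rx**2).sum() * (ry**2).sum()))


# ---------------------------------------------------------------- rank-sum


def test_identical_samples_give_p_one():
    res = rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.p_value == 1.0


def test_disjoint_small_samples_exact_p():
    """[1,2,3] vs [4,5,6]: U = 0 in 1 of C(6,3) = 20 assignments, doubled."""
    res = rank_sum_test([1, 2, 3], [4, 5, 6])
    assert res.method == "exact"
    assert res.p_value == pytest.approx(0.1, abs=1e-12)
    assert res.p_value == pytest.approx(exact_ranksum_p([1, 2, 3], [4, 5, 6]), abs=1e-12)


@pytest.mark.parametrize("seed", range(6))
def test_exact_branch_matches_enumeration_oracle(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=rng.integers(2, 6))
    y = rng.normal(size=rng.integers(2, 6))
    res = rank_sum_test(x, y)
    assert res.method == "exact"
    assert res.p_value == pytest.approx(exact_ranksum_p(x, y), abs=1e-12)


def test_large_or_tied_samples_use_normal_approximation():
    rng = np.random.default_rng(0)
    res = rank_sum_test(rng.normal(size=11), rng.normal(size=13))
    assert res.method == "normal_approx"
    tied = rank_sum_test([1, 1, 2], [2, 3, 4])
    assert tied.method == "normal_approx"


def test_exact_and_normal_branches_agree_at_boundary():
    """Combined n = 20 without ties: the two p-values differ by < 0.02."""
    from scipy.stats import mannwhitneyu

    rng = np.random.default_rng(42)
    worst = 0.0
    for _ in range(200):
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        p_exact = rank_sum_test(x, y).p_value
        p_norm = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        worst = max(worst, abs(p_exact - min(p_norm, 1.0)))
    assert worst < 0.02


def test_type_one_error_rate_near_nominal():
    """Null rejection rate at alpha 0.05, n = 11 vs 13, 2000 replicates."""
    rng = np.random.default_rng(2024)
    rejections = sum(
        rank_sum_test(rng.normal(size=11), rng.normal(size=13)).p_value < 0.05
        for _ in range(2000)
    )
    assert 0.03 <= rejections / 2000 <= 0.07


@settings(max_examples=25, deadline=None)
@given(
    data=st.lists(
        st.floats(-50, 50).filter(lambda v: abs(v) > 1e-6), min_size=4, max_size=12, unique=True
    ),
    split=st.integers(2, 10),
)
def test_p_invariant_under_monotone_transform(data, split):
    split = min(split, len(data) - 2)
    x, y = data[:split], data[split:]
    p_raw = rank_sum_test(x, y).p_value
    # scaling by a power of two is exact in floating point, hence strictly
    # monotone and injective on any inputs
    fx = [v * 4.0 for v in x]
    fy = [v * 4.0 for v in y]
    assert rank_sum_test(fx, fy).p_value == pytest.approx(p_raw, abs=1e-12)


def test_fold_change_is_ratio_of_means():
    res = rank_sum_test([10.0, 30.0], [5.0, 5.0], group_a="normal", group_b="MCD")
    assert res.fold_change == pytest.approx(4.0)
    assert (res.group_a, res.group_b, res.n_a, res.n_b) == ("normal", "MCD", 2, 2)


def test_empty_group_rejected():
    with pytest.raises(ValueError):
        rank_sum_test([], [1.0])


def test_signed_rank_requires_pairing():
    with pytest.raises(ValueError, match="equal length"):
        signed_rank_test([1.0, 2.0], [1.0, 2.0, 3.0])
    res = signed_rank_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.p_value == 1.0


# ---------------------------------------------------------------- spearman


def test_monotone_relationship_gives_rho_one():
    x = [1.0, 2.0, 5.0, 9.0]
    res = spearman_correlation(x, [math.exp(v) for v in x])
    assert res.rho == pytest.approx(1.0, abs=0)
    reversed_res = spearman_correlation(x, [-math.exp(v) for v in x])
    assert reversed_res.rho == pytest.approx(-1.0, abs=0)


def test_tied_example_matches_brute_force():
    x, y = [1.0, 2.0, 3.0, 4.0], [2.0, 1.0, 4.0, 3.0]
    res = spearman_correlation(x, y)
    assert res.rho == pytest.approx(brute_force_spearman(x, y), abs=1e-12)


def test_random_tied_vectors_match_brute_force_to_twelve_digits():
    rng = np.random.default_rng(77)
    for _ in range(100):
        n = int(rng.integers(5, 40))
        x = rng.integers(0, 8, size=n).astype(float)  # heavy ties
        y = rng.integers(0, 8, size=n).astype(float)
        if np.unique(x).size == 1 or np.unique(y).size == 1:
            continue
        res = spearman_correlation(x, y)
        assert res.rho == pytest.approx(brute_force_spearman(x, y), abs=1e-12)


def test_self_correlation_is_one(rng):
    x = rng.normal(size=20)
    assert spearman_correlation(x, x).rho == pytest.approx(1.0, abs=0)


def test_zero_rank_variance_gives_missing():
    res = spearman_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    assert math.isnan(res.rho) and math.isnan(res.p_value)


def test_too_short_input_rejected():
    with pytest.raises(ValueError, match="n >= 3"):
        spearman_correlation([1.0, 2.0], [3.0, 4.0])


# ---------------------------------------------------------------- cohort level


def test_compare_cohort_yields_one_result_per_disease_group():
    df = simulate_case_features(CohortParams(), 5)
    results = compare_cohort(df, "nfe2l1_nuclear")
    assert len(results) == 5
    assert {r.group_b for r in results} == {"MCD", "DN", "FSGS", "MesIgA", "MCGN"}
    assert all(r.group_a == "normal" for r in results)
    assert all(0 <= r.p_adjusted <= 1 for r in results)
    # BH never lowers a raw p-value
    assert all(r.p_adjusted >= r.p_value - 1e-12 for r in results)


def test_compare_cohort_unknown_feature_and_missing_reference():
    df = simulate_case_features(CohortParams(), 5)
    with pytest.raises(KeyError):
        compare_cohort(df, "no_such_feature")
    with pytest.raises(ValueError, match="reference"):
        compare_cohort(df[df.group != "normal"], "nfe2l1_nuclear")


def test_correlate_features_drops_missing_pairwise():
    df = simulate_case_features(CohortParams(), 5).copy()
    df.loc[df.index[:3], "nqo1_intensity"] = math.nan
    res = correlate_features(df, "nfe2l1_nuclear", "nqo1_intensity")
    assert res.n == len(df) - 3
    assert -1 <= res.rho <= 1
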