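"""Cohort-level nonparametric statistics.

Disease groups are compared against normal kidney with the two-sample
Wilcoxon–Mann–Whitney rank-sum test: exact enumeration null when the combined
sample is small (n <= 20) and tie-free, otherwise the normal approximation
with continuity correction and tie-corrected variance.  A paired signed-rank
variant is provided for completeness, but the cohort's groups are independent
with unequal sizes, so the rank-sum test is the default.

Monotone associations are summarised by Spearman's rank correlation (average
ranks for ties, two-sided p from the t-approximation with n - 2 df).

Multiple-comparison handling: raw p-values mirror the original analysis;
Benjamini–Hochberg adjusted p-values are reported alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

#: Largest combined sample size for which the exact rank-sum null is used.
EXACT_MAX_N = 20


@dataclass
class GroupComparisonResult:
    """One two-group comparison on one case-level feature.

    ``fold_change`` is mean(group_a) / mean(group_b); with the reference group
    as ``group_a`` this reads as the reference-over-disease reduction factor.
    """

    feature: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    statistic: float  # Mann–Whitney U of group_a
    p_value: float
    fold_change: float
    method: str  # "exact" or "normal_approx"
    p_adjusted: float = math.nan


@dataclass
class CorrelationResult:
    """Spearman rank correlation between two features."""

    feature_x: str
    feature_y: str
    n: int
    rho: float
    p_value: float


def rank_sum_test(
    x: Sequence[float],
    y: Sequence[float],
    feature: str = "",
    group_a: str = "a",
    group_b: str = "b",
) -> GroupComparisonResult:
    """Two-sided two-sample Wilcoxon–Mann–Whitney rank-sum test.

    The exact null (full enumeration over all C(n_x + n_y, n_x) group
    assignments) is used when the combined sample has at most 20 observations
    and no ties; otherwise the normal approximation with continuity correction
    and tie-corrected variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    if x.size + y.size <= EXACT_MAX_N and no_ties:
        method = "exact"
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        method = "normal_approx"
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    mean_y = float(np.mean(y))
    fold = float(np.mean(x)) / mean_y if mean_y != 0 else math.nan
    return GroupComparisonResult(
        feature=feature,
        group_a=group_a,
        group_b=group_b,
        n_a=int(x.size),
        n_b=int(y.size),
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        fold_change=fold,
        method=method,
    )


def signed_rank_test(
    x: Sequence[float],
    y: Sequence[float],
    feature: str = "",
    group_a: str = "a",
    group_b: str = "b",
) -> GroupComparisonResult:
    """Paired Wilcoxon signed-rank test (requires equal-length samples).

    Provided for paired designs; unequal group sizes make it undefined, which
    is why the rank-sum test is the cohort default.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("signed-rank test requires paired samples of equal length")
    if x.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.all(x == y):
        stat, p = math.nan, 1.0
        method = "exact"
    else:
        res = sps.wilcoxon(x, y, alternative="two-sided")
        stat, p = float(res.statistic), float(res.pvalue)
        method = "signed_rank"
    mean_y = float(np.mean(y))
    fold = float(np.mean(x)) / mean_y if mean_y != 0 else math.nan
    return GroupComparisonResult(
        feature=feature,
        group_a=group_a,
        group_b=group_b,
        n_a=int(x.size),
        n_b=int(y.size),
        statistic=stat,
        p_value=min(p, 1.0),
        fold_change=fold,
        method=method,
    )


def spearman_correlation(
    x: Sequence[float], y: Sequence[float], feature_x: str = "x", feature_y: str = "y"
) -> CorrelationResult:
    """Spearman rank correlation with average ranks for ties.

    rho is the Pearson correlation of the average ranks; the two-sided p-value
    comes from the t-distribution with n - 2 degrees of freedom.  Zero rank
    variance in either vector leaves rho and p undefined (NaN).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError(f"need n >= 3 observations, got {x.size}")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return CorrelationResult(feature_x, feature_y, int(x.size), math.nan, math.nan)
    rho, p = sps.spearmanr(x, y)
    return CorrelationResult(
        feature_x=feature_x,
        feature_y=feature_y,
        n=int(x.size),
        rho=float(rho),
        p_value=float(min(p, 1.0)),
    )


def _as_case_frame(cases) -> pd.DataFrame:
    if isinstance(cases, pd.DataFrame):
        return cases
    from .features import case_table

    return case_table(list(cases))


def compare_cohort(
    cases,
    feature: str,
    reference_group: str = "normal",
    test: str = "ranksum",
) -> list[GroupComparisonResult]:
    """Compare every non-reference group against the reference on one feature.

    ``cases`` is a case-level table (DataFrame or CaseFeatures sequence).
    Missing case values are dropped per comparison; fold change is
    reference-group mean over disease-group mean.  Benjamini–Hochberg adjusted
    p-values are filled in across the returned family of comparisons.
    """
    df = _as_case_frame(cases)
    if feature not in df.columns:
        raise KeyError(f"unknown feature {feature!r}")
    if reference_group not in set(df["group"]):
        raise ValueError(f"reference group {reference_group!r} not present")
    test_fn = rank_sum_test if test == "ranksum" else signed_rank_test

    ref_vals = df.loc[df["group"] == reference_group, feature].dropna().to_numpy()
    results: list[GroupComparisonResult] = []
    for grp in [g for g in pd.unique(df["group"]) if g != reference_group]:
        vals = df.loc[df["group"] == grp, feature].dropna().to_numpy()
        results.append(
            test_fn(ref_vals, vals, feature=feature, group_a=reference_group, group_b=grp)
        )
    if results:
        adj = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        results = [replace(r, p_adjusted=float(a)) for r, a in zip(results, adj)]
    return results


def correlate_features(
    cases, feature_x: str, feature_y: str
) -> CorrelationResult:
    """Spearman correlation between two features across cases (or glomeruli).

    Rows with a missing value in either feature are dropped pairwise.
    """
    df = _as_case_frame(cases)
    for f in (feature_x, feature_y):
        if f not in df.columns:
            raise KeyError(f"unknown feature {f!r}")
    sub = df[[feature_x, feature_y]].dropna()
    return spearman_correlation(
        sub[feature_x].to_numpy(), sub[feature_y].to_numpy(), feature_x, feature_y
    )


def comparison_table(results: Sequence[GroupComparisonResult]) -> pd.DataFrame:
    cols = [
        "feature", "group_a", "group_b", "n_a", "n_b",
        "statistic", "p_value", "p_adjusted", "fold_change", "method",
    ]
    return pd.DataFrame.from_records(
        [{c: getattr(r, c) for c in cols} for r in results], columns=cols
    )


def correlation_table(results: Sequence[CorrelationResult]) -> pd.DataFrame:
    cols = ["feature_x", "feature_y", "n", "rho", "p_value"]
    return pd.DataFrame.from_records(
        [{c: getattr(r, c) for c in cols} for r in results], columns=cols
    )
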