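"""Optional figure rendering: per-group strip/box plots and rank-correlation
scatter plots of the case-level tables."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .io import GROUPS
from .stats import correlate_features


def plot_group_comparison(cases: pd.DataFrame, feature: str, path: str | Path) -> None:
    """Box plot with jittered case points, one box per disease group."""
    groups = [g for g in GROUPS if g in set(cases["group"])]
    data = [cases.loc[cases["group"] == g, feature].dropna().to_numpy() for g in groups]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.boxplot(data, tick_labels=groups, showfliers=False)
    rng = np.random.default_rng(0)  # jitter is cosmetic only
    for i, vals in enumerate(data, start=1):
        ax.plot(i + rng.uniform(-0.12, 0.12, len(vals)), vals, "o", ms=3, alpha=0.6)
    ax.set_ylabel(feature)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_correlation(
    cases: pd.DataFrame, feature_x: str, feature_y: str, path: str | Path
) -> None:
    """Scatter plot annotated with the Spearman rank correlation."""
    res = correlate_features(cases, feature_x, feature_y)
    sub = cases[[feature_x, feature_y]].dropna()
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(sub[feature_x], sub[feature_y], "o", ms=4, alpha=0.7)
    ax.set_xlabel(feature_x)
    ax.set_ylabel(feature_y)
    ax.set_title(f"Spearman rho = {res.rho:.2f} (p = {res.p_value:.2g}, n = {res.n})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
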