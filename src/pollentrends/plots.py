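"""Optional figure helpers for the standard outputs.

Layouts mirror the three canonical summaries of the analysis: per-site
homogenizing proportions, per-site slope distributions ordered by
elevation, and the overall spline trend with the occupancy boxplot.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_site_proportions", "plot_site_slopes", "plot_trend_and_occupancy"]


def plot_site_proportions(site_summary: pd.DataFrame, path: str) -> None:
    """Stacked bar per site: homogenizing vs differentiating pair fractions."""
    df = site_summary.dropna(subset=["proportion_homogenizing"])
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.bar(df["site_id"], df["proportion_homogenizing"], color="#2c6fbb",
           label="homogenizing (slope < 0)")
    ax.bar(df["site_id"], 1.0 - df["proportion_homogenizing"],
           bottom=df["proportion_homogenizing"], color="#e8b93c",
           label="differentiating (slope > 0)")
    ax.set_ylabel("proportion of pair trends")
    ax.legend(fontsize=8)
    ax.tick_params(axis="x", rotation=90)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_site_slopes(
    trends: pd.DataFrame, site_meta: pd.DataFrame, path: str
) -> None:
    """Boxplots of pair slopes per site, ordered by site elevation."""
    order = site_meta.sort_values("elevation_m")["site_id"].tolist() \
        if "elevation_m" in site_meta else sorted(site_meta["site_id"])
    data, labels = [], []
    for site in order:
        s = trends.loc[
            (trends["site_a"] == site) | (trends["site_b"] == site), "slope"
        ]
        if len(s):
            data.append(s.to_numpy())
            labels.append(site)
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.boxplot(data, tick_labels=labels, whis=(0, 100))
    ax.axhline(0.0, color="grey", linestyle="--", linewidth=0.8)
    ax.set_ylabel("similarity slope (per cal yr BP)")
    ax.tick_params(axis="x", rotation=90)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_trend_and_occupancy(
    comparisons: pd.DataFrame, spline, path: str
) -> None:
    """Spline trend over all comparisons plus occupancy-grouped boxplot."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    ax1.scatter(comparisons["age_mid"], comparisons["similarity"],
                s=8, facecolors="none", edgecolors="#2c6fbb", linewidths=0.5)
    if spline is not None:
        ax1.fill_between(spline.grid, spline.ci_low, spline.ci_high,
                         color="grey", alpha=0.3, label="95% CI")
        ax1.plot(spline.grid, spline.fit, color="#1b3f8f", label="spline trend")
        ax1.legend(fontsize=8)
    ax1.set_xlabel("age (cal yr BP)")
    ax1.set_ylabel("Bray-Curtis similarity")
    ax1.invert_xaxis()
    groups = [
        comparisons.loc[comparisons["occupancy"] == s, "similarity"].to_numpy()
        for s in ("neither", "one", "both")
    ]
    ax2.boxplot([g for g in groups if len(g)],
                tick_labels=[s for s, g in zip(("neither", "one", "both"), groups) if len(g)])
    ax2.set_ylabel("Bray-Curtis similarity")
    ax2.set_xlabel("islands settled during interval")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
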