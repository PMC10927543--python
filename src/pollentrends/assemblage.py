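"""Rarefaction, 500-year binning and percentage assemblages.

Pollen sums differ by an order of magnitude between sites and sampling
campaigns, so count-based samples are first rarefied -- subsampled without
replacement (multivariate hypergeometric) -- to a common target depth.
Records published only as percentages cannot be rarefied and pass through
unchanged.  Samples are then placed in the ten 500-year intervals, averaged
per (site, interval) cell, and the cell means converted to percentages of
the mean pollen sum.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .intervals import OLDEST_BOUND, YOUNGEST_BOUND, TimeInterval, default_intervals

logger = logging.getLogger(__name__)

__all__ = [
    "rarefy_sample",
    "rarefy_records",
    "bin_and_average",
    "to_percentages",
    "DegenerateSampleError",
]

COUNTS = "counts"
PERCENTAGES = "percentages"


class DegenerateSampleError(ValueError):
    """An all-zero abundance map cannot be expressed as percentages."""


def to_percentages(values: pd.Series | dict) -> pd.Series:
    """Rescale an abundance map to sum to exactly 100.

    Raises :class:`DegenerateSampleError` on all-zero input.
    """
    s = pd.Series(values, dtype=float)
    total = s.sum()
    if not total > 0:
        raise DegenerateSampleError("all-zero abundance map")
    return 100.0 * s / total


def rarefy_sample(
    values: pd.Series | dict,
    target: int,
    rng: np.random.Generator,
) -> pd.Series:
    """Subsample integer counts to ``target`` grains without replacement.

    Draws are uniform over individual grains (multivariate hypergeometric),
    so the returned counts sum to ``target`` exactly and no taxon exceeds
    its input count.  A sample whose total is below ``target`` is returned
    unchanged (flagged upstream); a total equal to ``target`` is returned
    as-is.
    """
    s = pd.Series(values, dtype=np.int64)
    if (s < 0).any():
        raise ValueError("counts must be nonnegative")
    if target < 1:
        raise ValueError("rarefaction target must be >= 1")
    total = int(s.sum())
    if total <= target:
        return s
    drawn = rng.multivariate_hypergeometric(s.to_numpy(), target)
    return pd.Series(drawn, index=s.index)


def rarefy_records(
    samples: pd.DataFrame,
    target: int | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, int]:
    """Rarefy every count-based sample in a long table to a common depth.

    ``samples`` columns: ``site_id, age_bp, taxon, value, value_kind``.
    ``target`` defaults to the minimum pollen sum over count-based samples
    (the largest depth every such sample can reach).  Percentage-only
    samples pass through untouched; count samples whose total falls below
    an overridden target are passed through unrarefied with a log warning.

    Returns ``(rarefied table, target used)``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    is_count = samples["value_kind"] == COUNTS
    counts = samples.loc[is_count].reset_index(drop=True)
    if counts.empty:
        return samples.copy(), 0
    vals = counts["value"].to_numpy()
    ivals = vals.astype(np.int64)
    if (ivals != vals).any() or (ivals < 0).any():
        raise ValueError("count-based samples must hold nonnegative integers")
    groups = counts.groupby(["site_id", "age_bp"], sort=True).indices
    totals = {k: int(ivals[pos].sum()) for k, pos in groups.items()}
    if target is None:
        target = min(totals.values())
    n_below = sum(t < target for t in totals.values())
    if n_below:
        logger.warning(
            "%d samples have pollen sums below the rarefaction target %d; "
            "passed through unrarefied", n_below, target,
        )
    out_vals = vals.astype(float).copy()
    for key in sorted(groups):
        pos = groups[key]
        if totals[key] > target:
            out_vals[pos] = rng.multivariate_hypergeometric(ivals[pos], target)
    counts = counts.assign(value=out_vals)
    result = pd.concat(
        [samples.loc[~is_count], counts.loc[counts["value"] > 0]], ignore_index=True
    )
    return result, target


def bin_and_average(
    samples: pd.DataFrame,
    intervals: list[TimeInterval] | None = None,
) -> pd.DataFrame:
    """Bin samples into 500-year intervals and average within each cell.

    A sample of age ``a`` belongs to the interval whose young bound it
    sits on (young-inclusive, old-exclusive; a sample at the grid's
    oldest bound is kept in the earliest interval).  Within each (site, interval) cell holding at
    least one sample, the per-taxon arithmetic mean over the cell's samples
    is taken (taxa absent from a sample count as zero) and converted to
    percentages of the mean total.  Samples outside the grid are excluded
    and logged.  Cells with no samples produce no rows.

    Returns a long table ``site_id, interval_index, interval_old,
    interval_young, taxon, mean_pct, n_samples``.
    """
    intervals = intervals or default_intervals()
    cols = [
        "site_id", "interval_index", "interval_old", "interval_young",
        "taxon", "mean_pct", "n_samples",
    ]
    if samples.empty:
        return pd.DataFrame(columns=cols)
    ages = samples["age_bp"].astype(float)
    oldest = max(iv.old for iv in intervals)
    youngest = min(iv.young for iv in intervals)
    in_range = (ages > youngest) & (ages <= oldest)
    n_out = samples.loc[~in_range, ["site_id", "age_bp"]].drop_duplicates().shape[0]
    if n_out:
        logger.info(
            "bin_and_average: excluded %d samples outside (%g, %g] cal yr BP",
            n_out, oldest, youngest,
        )
    df = samples.loc[in_range].copy()
    if df.empty:
        return pd.DataFrame(columns=cols)
    # bin on time-before-the-oldest-bound so a sample at an interval's
    # young bound lands in the older interval (and the oldest bound itself
    # stays in the earliest interval)
    ivs = sorted(intervals, key=lambda iv: iv.old, reverse=True)
    edges_t = np.array([oldest - iv.old for iv in ivs] + [oldest - ivs[-1].young])
    t = oldest - df["age_bp"].astype(float).to_numpy()
    pos = np.maximum(np.searchsorted(edges_t, t, side="left") - 1, 0)
    df["interval_index"] = np.array([ivs[int(i)].index for i in pos])
    n_samples = (
        df.drop_duplicates(["site_id", "age_bp"])
        .groupby(["site_id", "interval_index"])
        .size()
        .rename("n_samples")
    )
    sums = (
        df.groupby(["site_id", "interval_index", "taxon"], sort=True)["value"]
        .sum()
        .reset_index()
    )
    mean = sums.merge(n_samples.reset_index(), on=["site_id", "interval_index"])
    mean["mean_value"] = mean["value"] / mean["n_samples"]
    cell_tot = mean.groupby(["site_id", "interval_index"])["mean_value"].transform("sum")
    if (cell_tot <= 0).any():
        bad = mean.loc[cell_tot <= 0, ["site_id", "interval_index"]].drop_duplicates()
        logger.warning("dropping %d all-zero assemblage cells", len(bad))
        mean = mean.loc[cell_tot > 0]
        cell_tot = cell_tot.loc[cell_tot > 0]
    mean["mean_pct"] = 100.0 * mean["mean_value"] / cell_tot
    mean = mean.loc[mean["mean_pct"] > 0]
    by_index = {iv.index: iv for iv in intervals}
    mean["interval_old"] = mean["interval_index"].map(lambda i: by_index[i].old)
    mean["interval_young"] = mean["interval_index"].map(lambda i: by_index[i].young)
    return (
        mean[cols]
        .sort_values(["site_id", "interval_index", "taxon"])
        .reset_index(drop=True)
    )
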