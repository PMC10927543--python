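"""Pairwise Bray-Curtis similarity of interval assemblages with occupancy status.

Bray-Curtis dissimilarity on abundances, BC = 1 - 2*sum_i min(a_i, b_i) /
sum_i (a_i + b_i), is inverted so values represent taxonomic similarity
(1 = identical composition, 0 = no shared taxa).  It weights by abundance
and excludes joint absences, so two sites missing the same taxa are not
deemed more similar.  Each unordered site pair is compared within each
500-year interval where both sites have an assemblage, and the comparison
is labelled by whether neither, one or both islands had been settled by
people during that interval.
"""

from __future__ import annotations

import itertools
import logging
import math

import numpy as np
import pandas as pd

from .intervals import TimeInterval, default_intervals

logger = logging.getLogger(__name__)

__all__ = [
    "bray_curtis_similarity",
    "assign_occupancy",
    "pairwise_table",
    "DegenerateAssemblageError",
]

OCCUPANCY_LEVELS = ("neither", "one", "both")

#: Settlement-age value meaning an island was never settled.
NEVER = math.inf  # stored as NaN in CSVs; compared as "never settled"


class DegenerateAssemblageError(ValueError):
    """An empty or all-zero assemblage has no defined Bray-Curtis similarity."""


def bray_curtis_similarity(a: pd.Series | dict, b: pd.Series | dict) -> float:
    """Inverted Bray-Curtis index between two percentage assemblages.

    ``similarity = 2 * sum_i min(a_i, b_i) / sum_i (a_i + b_i)`` over the
    union of taxa, with absent taxa counted as zero.  Symmetric; 1 for
    identical maps, 0 for disjoint support; joint absences have no effect.
    """
    sa = pd.Series(a, dtype=float)
    sb = pd.Series(b, dtype=float)
    if not sa.sum() > 0 or not sb.sum() > 0:
        raise DegenerateAssemblageError("empty or all-zero assemblage")
    union = sa.index.union(sb.index)
    va = sa.reindex(union, fill_value=0.0).to_numpy()
    vb = sb.reindex(union, fill_value=0.0).to_numpy()
    return float(2.0 * np.minimum(va, vb).sum() / (va + vb).sum())


def _settled(settlement_age: float, bound: float) -> bool:
    """An island counts as settled once its settlement date predates the
    given interval bound.  NaN / inf settlement ages mean never settled."""
    if settlement_age is None or (isinstance(settlement_age, float) and math.isnan(settlement_age)):
        return False
    if settlement_age == NEVER:
        return False
    return settlement_age > bound


def assign_occupancy(
    island_a: str,
    island_b: str,
    interval: TimeInterval,
    settlements: dict[str, float],
    edge: str = "young",
) -> str:
    """Classify an island pair in an interval as ``neither``/``one``/``both`` settled.

    With the default ``edge="young"`` an island is settled in an interval
    iff its settlement date is older than the interval's young bound, so
    the interval containing the settlement event already counts as
    settled (impacts begin at settlement).  ``edge="old"`` defers settled
    status to the first interval fully after settlement.
    """
    if edge not in ("young", "old"):
        raise ValueError(f"unknown occupancy edge rule {edge!r}")
    missing = [i for i in (island_a, island_b) if i not in settlements]
    if missing:
        raise KeyError(f"islands missing from settlement table: {missing}")
    bound = interval.young if edge == "young" else interval.old
    n = sum(_settled(settlements[i], bound) for i in (island_a, island_b))
    return OCCUPANCY_LEVELS[n]


def pairwise_table(
    assemblages: pd.DataFrame,
    site_islands: dict[str, str] | pd.Series,
    settlements: dict[str, float],
    intervals: list[TimeInterval] | None = None,
    edge: str = "young",
) -> pd.DataFrame:
    """All within-interval pairwise similarities between site assemblages.

    ``assemblages`` is the long table produced by
    :func:`pollentrends.assemblage.bin_and_average`.  One row is produced
    per unordered site pair (``site_a < site_b`` lexicographically) per
    interval in which both sites have an assemblage; with *s* sites a fully
    covered interval yields s(s-1)/2 rows.  Degenerate assemblages are
    skipped with a log entry.

    Returns columns ``site_a, site_b, interval_index, interval_old,
    interval_young, age_mid, similarity, occupancy``.
    """
    intervals = intervals or default_intervals()
    by_index = {iv.index: iv for iv in intervals}
    site_islands = dict(site_islands)
    rows = []
    for idx, grp in assemblages.groupby("interval_index", sort=True):
        iv = by_index[int(idx)]
        wide = grp.pivot_table(
            index="site_id", columns="taxon", values="mean_pct", fill_value=0.0
        )
        sites = sorted(wide.index)
        mat = wide.loc[sites].to_numpy()
        totals = mat.sum(axis=1)
        for ia, ib in itertools.combinations(range(len(sites)), 2):
            if not (totals[ia] > 0 and totals[ib] > 0):
                logger.warning(
                    "skipping degenerate assemblage pair (%s, %s) in interval %d",
                    sites[ia], sites[ib], iv.index,
                )
                continue
            sim = float(
                2.0 * np.minimum(mat[ia], mat[ib]).sum() / (totals[ia] + totals[ib])
            )
            occ = assign_occupancy(
                site_islands[sites[ia]], site_islands[sites[ib]], iv, settlements, edge
            )
            rows.append(
                {
                    "site_a": sites[ia],
                    "site_b": sites[ib],
                    "interval_index": iv.index,
                    "interval_old": iv.old,
                    "interval_young": iv.young,
                    "age_mid": iv.midpoint,
                    "similarity": sim,
                    "occupancy": occ,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "site_a", "site_b", "interval_index", "interval_old",
            "interval_young", "age_mid", "similarity", "occupancy",
        ],
    )
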