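"""Sensitivity-analysis variants of the homogenization pipeline.

Three robustness checks, each a local modification feeding the unchanged
downstream similarity/trend pipeline:

* ``min_count`` -- drop count-based samples whose pollen sum falls below a
  threshold (default 300 grains); percentage-only records are retained
  since they carry no sum to test.
* ``exclude_taxa`` -- remove named abundant taxa (default Cyperaceae and
  Poaceae, the dominant post-settlement open-vegetation types) from the
  percentage assemblages and renormalize.
* ``same_rank`` -- restrict assemblages to taxa identified at one
  taxonomic rank (family, genus or species) and renormalize, so
  comparisons are only ever between like-ranked taxa.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["SensitivitySpec", "filter_min_count", "exclude_taxa", "restrict_to_rank"]

VARIANTS = ("same_rank", "min_count", "exclude_taxa")
DEFAULT_MIN_COUNT = 300
DEFAULT_EXCLUDED = frozenset({"Cyperaceae", "Poaceae"})


@dataclass(frozen=True)
class SensitivitySpec:
    """Which pipeline variant to run and its parameter."""

    variant: str
    rank: str = "genus"
    min_count: int = DEFAULT_MIN_COUNT
    excluded_taxa: frozenset[str] = field(default_factory=lambda: DEFAULT_EXCLUDED)

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown sensitivity variant {self.variant!r}")
        if self.variant == "min_count" and self.min_count < 0:
            raise ValueError("min_count threshold must be >= 0")
        if self.variant == "exclude_taxa" and not self.excluded_taxa:
            raise ValueError("exclusion set must be nonempty")
        if self.variant == "same_rank" and self.rank not in ("family", "genus", "species"):
            raise ValueError(f"unknown rank {self.rank!r}")


def filter_min_count(samples: pd.DataFrame, threshold: int) -> pd.DataFrame:
    """Drop count samples with pollen sum strictly below ``threshold``.

    Percentage-only samples are retained (no count to test) with a log
    warning.
    """
    is_count = samples["value_kind"] == "counts"
    n_pct = samples.loc[~is_count].drop_duplicates(["site_id", "age_bp"]).shape[0]
    if n_pct:
        logger.warning(
            "filter_min_count: %d percentage-only samples retained without a count test",
            n_pct,
        )
    totals = samples.loc[is_count].groupby(["site_id", "age_bp"])["value"].sum()
    low = set(totals.index[totals < threshold])
    keys = list(zip(samples["site_id"], samples["age_bp"]))
    drop = pd.Series([k in low for k in keys], index=samples.index) & is_count
    if drop.any():
        n = samples.loc[drop].drop_duplicates(["site_id", "age_bp"]).shape[0]
        logger.info("filter_min_count: removed %d samples with sums < %d", n, threshold)
    return samples.loc[~drop].reset_index(drop=True)


def _renormalize(assemblages: pd.DataFrame, keep: pd.Series, what: str) -> pd.DataFrame:
    out = assemblages.loc[keep].copy()
    dropped_cells = (
        assemblages.loc[~keep, ["site_id", "interval_index"]]
        .drop_duplicates()
        .merge(
            out[["site_id", "interval_index"]].drop_duplicates(),
            how="left", indicator=True,
        )
    )
    emptied = dropped_cells.loc[dropped_cells["_merge"] == "left_only"]
    if len(emptied):
        logger.info("%s: dropped %d assemblages left empty", what, len(emptied))
    tot = out.groupby(["site_id", "interval_index"])["mean_pct"].transform("sum")
    out["mean_pct"] = 100.0 * out["mean_pct"] / tot
    return out.reset_index(drop=True)


def exclude_taxa(assemblages: pd.DataFrame, taxa: set[str]) -> pd.DataFrame:
    """Remove named taxa from percentage assemblages and renormalize to 100.

    Assemblages left empty by the removal are dropped with a log entry.
    """
    keep = ~assemblages["taxon"].isin(set(taxa))
    return _renormalize(assemblages, keep, "exclude_taxa")


def restrict_to_rank(
    assemblages: pd.DataFrame, rank: str, taxon_ranks: dict[str, str]
) -> pd.DataFrame:
    """Keep only taxa identified at ``rank`` and renormalize to 100.

    ``taxon_ranks`` maps standardized names to their rank (from the name
    table under the active standardization mode).  Assemblages with no
    taxon at the rank are dropped with a log entry.
    """
    keep = assemblages["taxon"].map(taxon_ranks) == rank
    return _renormalize(assemblages, keep, f"restrict_to_rank({rank})")
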