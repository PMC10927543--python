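"""Harmonization of raw pollen/spore names against a local name table.

Pollen types are recorded under heterogeneous names: outdated synonyms,
tentative identifications ("Ipomoea cf. batatas"), and multi-match types
that cannot be separated morphologically ("Macaranga/Mallotus").  Two
standardizations are supported:

* ``STD1`` keeps the lowest level of identification (a "cf." species is
  promoted to that species);
* ``STD2`` lifts uncertain identifications one level up (a "cf." species
  becomes its genus).

Both modes drop indeterminate types and types only identifiable above the
family level, replace synonyms with accepted names, and aggregate
multi-match types to the lowest rank shared by their members (genus if the
members are congeneric, otherwise family; members from different families
are dropped with a warning).

The name table is a required local input with one row per raw name -- no
network nomenclature services are queried.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TaxonStatus",
    "StandardizationMode",
    "TaxonEntry",
    "NameTable",
    "UnresolvedNameError",
    "resolve_name",
    "standardize",
    "count_taxa",
    "REMOVED",
]

#: Sentinel returned by :func:`resolve_name` for names dropped from the analysis.
REMOVED = None

RANKS = ("family", "genus", "species")


class TaxonStatus(str, Enum):
    ACCEPTED = "accepted"
    SYNONYM = "synonym"
    INDETERMINATE = "indeterminate"
    UNCERTAIN_ABOVE_FAMILY = "uncertain_above_family"
    MULTI_MATCH = "multi_match"
    CF_SPECIES = "cf_species"


class StandardizationMode(str, Enum):
    """STD1 keeps the lowest identification level; STD2 lifts uncertain ones up."""

    STD1 = "std1"
    STD2 = "std2"


class UnresolvedNameError(KeyError):
    """A raw name was not found in the name table.

    Unknown names are never silently kept; the offending names are listed.
    """

    def __init__(self, names: list[str]):
        self.names = sorted(set(names))
        super().__init__(f"unresolved raw names (not in name table): {self.names}")


def normalize_raw_name(name: str) -> str:
    """Trim, collapse internal whitespace, and upper-case the first letter.

    Pollen-type names are short controlled strings; anything fuzzier than
    this would mask errors in the name table.
    """
    s = re.sub(r"\s+", " ", str(name).strip())
    if s:
        s = s[0].upper() + s[1:]
    return s


@dataclass(frozen=True)
class TaxonEntry:
    """One name-table row: how a raw pollen name maps to an accepted taxon."""

    raw_name: str
    status: TaxonStatus
    accepted_name: str = ""
    rank: str = ""  # family | genus | species ('' for removed categories)
    genus: str = ""
    family: str = ""
    multi_match_members: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.status in (TaxonStatus.ACCEPTED, TaxonStatus.SYNONYM, TaxonStatus.CF_SPECIES):
            if self.rank not in RANKS:
                raise ValueError(f"{self.raw_name!r}: rank {self.rank!r} invalid for status {self.status}")
            if self.rank == "species" and not self.genus:
                raise ValueError(f"{self.raw_name!r}: species-rank entry needs a genus")
            if self.rank in ("species", "genus") and not self.family:
                raise ValueError(f"{self.raw_name!r}: {self.rank}-rank entry needs a family")
        if self.status is TaxonStatus.MULTI_MATCH and len(self.multi_match_members) < 2:
            raise ValueError(f"{self.raw_name!r}: multi_match needs >= 2 members")
        if self.status is TaxonStatus.CF_SPECIES and self.rank != "species":
            raise ValueError(f"{self.raw_name!r}: cf_species entries carry the species name")


class NameTable:
    """Raw-name -> :class:`TaxonEntry` lookup keyed on normalized raw names."""

    def __init__(self, entries: list[TaxonEntry] | dict[str, TaxonEntry]):
        if isinstance(entries, dict):
            entries = list(entries.values())
        self._entries: dict[str, TaxonEntry] = {}
        for e in entries:
            key = normalize_raw_name(e.raw_name)
            if key in self._entries:
                raise ValueError(f"duplicate raw name in table: {key!r}")
            self._entries[key] = e

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, raw_name: str) -> bool:
        return normalize_raw_name(raw_name) in self._entries

    def get(self, raw_name: str) -> TaxonEntry | None:
        return self._entries.get(normalize_raw_name(raw_name))

    def __getitem__(self, raw_name: str) -> TaxonEntry:
        e = self.get(raw_name)
        if e is None:
            raise UnresolvedNameError([raw_name])
        return e

    @property
    def entries(self) -> dict[str, TaxonEntry]:
        return dict(self._entries)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "raw_name": e.raw_name,
                "status": e.status.value,
                "accepted_name": e.accepted_name,
                "rank": e.rank,
                "genus": e.genus,
                "family": e.family,
                "multi_match_members": "|".join(e.multi_match_members),
            }
            for e in self._entries.values()
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "raw_name", "status", "accepted_name", "rank",
                "genus", "family", "multi_match_members",
            ],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "NameTable":
        entries = []
        for _, r in df.iterrows():
            members = tuple(m for m in str(r.get("multi_match_members", "") or "").split("|") if m)
            entries.append(
                TaxonEntry(
                    raw_name=str(r["raw_name"]),
                    status=TaxonStatus(str(r["status"])),
                    accepted_name=str(r.get("accepted_name", "") or ""),
                    rank=str(r.get("rank", "") or ""),
                    genus=str(r.get("genus", "") or ""),
                    family=str(r.get("family", "") or ""),
                    multi_match_members=members,
                )
            )
        return cls(entries)


def _resolve_multi_match(entry: TaxonEntry) -> tuple[str, str] | None:
    """Aggregate a multi-match type to the lowest rank its members share."""
    if entry.genus:
        return entry.genus, "genus"
    if entry.family:
        return entry.family, "family"
    logger.warning(
        "multi-match type %r has members in different families; removed", entry.raw_name
    )
    return REMOVED


def resolve_name(
    raw_name: str, table: NameTable, mode: StandardizationMode
) -> tuple[str, str] | None:
    """Map a raw name to ``(standardized_name, rank)``, or ``REMOVED`` (None).

    Raises :class:`UnresolvedNameError` if ``raw_name`` is absent from the
    table.
    """
    entry = table[raw_name]
    status = entry.status
    if status in (TaxonStatus.INDETERMINATE, TaxonStatus.UNCERTAIN_ABOVE_FAMILY):
        return REMOVED
    if status is TaxonStatus.ACCEPTED or status is TaxonStatus.SYNONYM:
        return entry.accepted_name, entry.rank
    if status is TaxonStatus.MULTI_MATCH:
        return _resolve_multi_match(entry)
    if status is TaxonStatus.CF_SPECIES:
        if mode is StandardizationMode.STD1:
            return entry.accepted_name, "species"
        return entry.genus, "genus"
    raise AssertionError(f"unhandled status {status}")  # pragma: no cover


def standardize(
    samples: pd.DataFrame,
    table: NameTable,
    mode: StandardizationMode | str = StandardizationMode.STD1,
) -> pd.DataFrame:
    """Standardize taxon names in a long-format sample table.

    ``samples`` has columns ``site_id, age_bp, taxon, value`` (and optionally
    ``value_kind``).  Values of raw names mapping to the same standardized
    name are summed per sample; removed names are dropped, so each sample's
    total shrinks by exactly the removed values.
    """
    mode = StandardizationMode(mode)
    if samples.empty:
        return samples.copy()
    raw_names = samples["taxon"].unique()
    missing = [n for n in raw_names if n not in table]
    if missing:
        raise UnresolvedNameError(missing)
    mapping = {n: resolve_name(n, table, mode) for n in raw_names}
    out = samples.copy()
    resolved = out["taxon"].map(mapping)
    keep = resolved.notna()
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("standardize: dropped %d rows of removed categories", n_removed)
    out = out.loc[keep].copy()
    out["taxon"] = resolved.loc[keep].map(lambda t: t[0])
    group_cols = [c for c in ("site_id", "age_bp", "value_kind") if c in out.columns]
    out = (
        out.groupby(group_cols + ["taxon"], as_index=False, sort=False)["value"].sum()
    )
    return out[group_cols[:2] + ["taxon", "value"] + group_cols[2:]]


def rank_table(table: NameTable, mode: StandardizationMode | str) -> dict[str, str]:
    """Standardized-name -> rank map implied by a name table under one mode."""
    mode = StandardizationMode(mode)
    out: dict[str, str] = {}
    for raw in table.entries:
        res = resolve_name(raw, table, mode)
        if res is not REMOVED:
            name, rank = res
            out[name] = rank
    return out


def count_taxa(
    samples: pd.DataFrame, table: NameTable, mode: StandardizationMode | str
) -> dict[str, int]:
    """Count distinct standardized taxa by rank across a set of records.

    Returns ``{"family": f, "genus": g, "species": s, "total": f+g+s}``; each
    distinct standardized name is counted once over all records.
    """
    mode = StandardizationMode(mode)
    counts = {r: 0 for r in RANKS}
    if not samples.empty:
        std = standardize(samples, table, mode)
        ranks = rank_table(table, mode)
        for name in std["taxon"].unique():
            counts[ranks[name]] += 1
    counts["total"] = sum(counts[r] for r in RANKS)
    return counts


def removable_raw_names(table: NameTable) -> set[str]:
    """Raw names dropped by both modes (indeterminate / above-family types).

    Rarefaction excludes these "unknown types" before subsampling.
    """
    return {
        e.raw_name
        for e in table.entries.values()
        if e.status in (TaxonStatus.INDETERMINATE, TaxonStatus.UNCERTAIN_ABOVE_FAMILY)
    }
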