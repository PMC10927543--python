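"""CSV and YAML I/O for pollen records, name tables and run configuration.

All tables are plain CSV.  Ages are real numbers in cal yr BP (present =
1950 CE; negative allowed).  The long sample format is
``site_id,age_bp,taxon,value,value_kind`` with ``value_kind`` one of
``counts`` / ``percentages``; duplicate (site, age, taxon) rows are summed
with a warning, and mixed value kinds within one sample are an error.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .taxonomy import NameTable

logger = logging.getLogger(__name__)

__all__ = [
    "read_samples",
    "write_samples",
    "read_name_table",
    "write_name_table",
    "read_settlements",
    "write_settlements",
    "read_site_meta",
    "write_site_meta",
    "MalformedInputError",
]

SAMPLE_COLUMNS = ["site_id", "age_bp", "taxon", "value", "value_kind"]
VALUE_KINDS = {"counts", "percentages"}


class MalformedInputError(ValueError):
    """An input CSV row violates the expected schema."""


def read_samples(path: str | Path) -> pd.DataFrame:
    """Read a long-format sample CSV into the canonical sample table.

    Rows are grouped by site; row order is irrelevant.  Duplicate
    (site, age, taxon) rows are summed with a warning.  A malformed row
    raises :class:`MalformedInputError` with its line number; a sample
    mixing value kinds is an error.
    """
    df = pd.read_csv(
        path,
        dtype={"site_id": str, "taxon": str, "value_kind": str},
        float_precision="round_trip",
    )
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise MalformedInputError(f"{path}: missing columns {missing}")
    if df.empty:
        return df[SAMPLE_COLUMNS]
    for col in ("age_bp", "value"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise MalformedInputError(f"{path}: malformed {col!r} at line {line}")
        df[col] = vals.astype(float)
    bad_kind = ~df["value_kind"].isin(VALUE_KINDS)
    if bad_kind.any():
        line = int(bad_kind.idxmax()) + 2
        raise MalformedInputError(f"{path}: invalid value_kind at line {line}")
    if (df["value"] < 0).any():
        line = int((df["value"] < 0).idxmax()) + 2
        raise MalformedInputError(f"{path}: negative value at line {line}")
    kinds = df.groupby(["site_id", "age_bp"])["value_kind"].nunique()
    mixed = kinds[kinds > 1]
    if len(mixed):
        raise MalformedInputError(
            f"{path}: samples mixing counts and percentages: {list(mixed.index)[:5]}"
        )
    dup = df.duplicated(["site_id", "age_bp", "taxon"], keep=False)
    if dup.any():
        logger.warning(
            "%s: summed %d duplicate (site, age, taxon) rows", path, int(dup.sum())
        )
        df = (
            df.groupby(["site_id", "age_bp", "taxon", "value_kind"], as_index=False, sort=False)["value"]
            .sum()
        )
    return df[SAMPLE_COLUMNS].reset_index(drop=True)


def write_samples(df: pd.DataFrame, path: str | Path) -> None:
    df[SAMPLE_COLUMNS].to_csv(path, index=False)


def read_name_table(path: str | Path) -> NameTable:
    df = pd.read_csv(path, dtype=str).fillna("")
    return NameTable.from_frame(df)


def write_name_table(table: NameTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index=False)


def read_settlements(path: str | Path) -> dict[str, float]:
    """Island -> settlement age (cal yr BP); blank or 'never' means never settled."""
    df = pd.read_csv(path, dtype={"island_id": str}, float_precision="round_trip")
    out: dict[str, float] = {}
    for _, r in df.iterrows():
        v = r["settlement_age_bp"]
        if (isinstance(v, float) and math.isnan(v)) or str(v).strip().lower() in ("", "never", "nan"):
            out[str(r["island_id"])] = float("nan")
        else:
            age = float(v)
            if age <= 0:
                raise MalformedInputError(
                    f"{path}: settlement ages must be positive (island {r['island_id']})"
                )
            out[str(r["island_id"])] = age
    return out


def write_settlements(settlements: dict[str, float] | pd.DataFrame, path: str | Path) -> None:
    if isinstance(settlements, dict):
        settlements = pd.DataFrame(
            {"island_id": list(settlements), "settlement_age_bp": list(settlements.values())}
        )
    df = settlements.copy()
    df["settlement_age_bp"] = [
        "never" if (v is None or (isinstance(v, float) and not np.isfinite(v))) else v
        for v in df["settlement_age_bp"]
    ]
    df.to_csv(path, index=False)


def read_site_meta(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"site_id": str, "island_id": str}, float_precision="round_trip")
    for col in ("site_id", "island_id"):
        if col not in df.columns:
            raise MalformedInputError(f"{path}: missing column {col!r}")
    if df["site_id"].duplicated().any():
        raise MalformedInputError(f"{path}: duplicate site_id rows")
    return df


def write_site_meta(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)
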