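"""End-to-end orchestration: records -> assemblages -> similarities -> trends.

The analysis chain follows the order: drop unknown types, (optionally)
exclude low-count samples, rarefy counts to a common depth, standardize
taxon names, bin into 500-year intervals and average, compute pairwise
Bray-Curtis similarities with occupancy status, fit per-pair OLS trends,
and summarize per site / per occupancy group with an overall
smoothing-spline trend curve.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assemblage import bin_and_average, rarefy_records
from .intervals import TimeInterval, default_intervals
from .io import (
    read_name_table,
    read_samples,
    read_settlements,
    read_site_meta,
    write_name_table,
    write_samples,
    write_settlements,
    write_site_meta,
)
from .sensitivity import SensitivitySpec, exclude_taxa, filter_min_count, restrict_to_rank
from .similarity import pairwise_table
from .synthetic import SyntheticConfig, generate_archipelago
from .taxonomy import (
    NameTable,
    StandardizationMode,
    count_taxa,
    rank_table,
    removable_raw_names,
    standardize,
)
from .trends import (
    abundance_by_settlement,
    fit_trend_spline,
    occupancy_summary,
    pair_trend_table,
    site_summary,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "analyze", "run_pipeline"]


@dataclass
class RunConfig:
    """One pipeline run: either file inputs or a synthetic archipelago."""

    samples_path: str | None = None
    name_table_path: str | None = None
    settlements_path: str | None = None
    site_meta_path: str | None = None
    synthetic: SyntheticConfig | None = None
    mode: str = "std1"
    rarefaction_target: int | None = None   # None -> minimum pollen sum
    rarefy_method: str = "subsample"        # "subsample" | "none"
    average_domain: str = "abundance"       # "abundance" | "percentage"
    occupancy_edge: str = "young"           # settled iff age > this interval bound
    sensitivity: SensitivitySpec | None = None
    seed: int = 0
    output_dir: str = "pollentrends_output"

    def __post_init__(self) -> None:
        has_files = self.samples_path is not None
        if has_files == (self.synthetic is not None):
            raise ValueError("provide exactly one of file inputs or a synthetic config")
        if has_files and not all(
            (self.name_table_path, self.settlements_path, self.site_meta_path)
        ):
            raise ValueError("file runs need samples, name table, settlements and site metadata")
        if self.rarefy_method not in ("subsample", "none"):
            raise ValueError(f"unknown rarefy_method {self.rarefy_method!r}")
        if self.average_domain not in ("abundance", "percentage"):
            raise ValueError(f"unknown average_domain {self.average_domain!r}")


def analyze(
    samples: pd.DataFrame,
    name_table: NameTable,
    site_meta: pd.DataFrame,
    settlements: dict[str, float],
    *,
    mode: StandardizationMode | str = "std1",
    rarefaction_target: int | None = None,
    rarefy_method: str = "subsample",
    average_domain: str = "abundance",
    occupancy_edge: str = "young",
    sensitivity: SensitivitySpec | None = None,
    seed: int = 0,
    intervals: list[TimeInterval] | None = None,
    fit_spline: bool = True,
) -> dict:
    """Run the full analysis in memory and return every stage's table.

    Returns a dict with keys ``assemblages, comparisons, trends,
    site_summary, occupancy_summary, spline, abundance, taxon_counts,
    rarefaction_target``.
    """
    mode = StandardizationMode(mode)
    intervals = intervals or default_intervals()
    site_islands = site_meta.set_index("site_id")["island_id"]

    # unknown types are excluded before rarefaction
    unknown = removable_raw_names(name_table)
    known = samples.loc[~samples["taxon"].isin(unknown)].reset_index(drop=True)

    if sensitivity is not None and sensitivity.variant == "min_count":
        known = filter_min_count(known, sensitivity.min_count)

    if rarefy_method == "subsample":
        rarefied, target_used = rarefy_records(known, rarefaction_target, seed)
    else:
        rarefied, target_used = known, 0

    std = standardize(rarefied, name_table, mode)
    taxon_counts = count_taxa(rarefied, name_table, mode)

    if average_domain == "percentage":
        std = std.copy()
        tot = std.groupby(["site_id", "age_bp"])["value"].transform("sum")
        std["value"] = 100.0 * std["value"] / tot

    assemblages = bin_and_average(std, intervals)

    if sensitivity is not None and sensitivity.variant == "exclude_taxa":
        assemblages = exclude_taxa(assemblages, set(sensitivity.excluded_taxa))
    elif sensitivity is not None and sensitivity.variant == "same_rank":
        assemblages = restrict_to_rank(
            assemblages, sensitivity.rank, rank_table(name_table, mode)
        )

    comparisons = pairwise_table(
        assemblages, site_islands, settlements, intervals, edge=occupancy_edge
    )
    trends = pair_trend_table(comparisons)
    sites = site_summary(trends, sorted(site_meta["site_id"]))
    occupancy = occupancy_summary(comparisons)

    spline = None
    if fit_spline and len(comparisons) >= 10 and comparisons["age_mid"].nunique() >= 3:
        spline = fit_trend_spline(
            comparisons["age_mid"].to_numpy(), comparisons["similarity"].to_numpy()
        )
    elif fit_spline:
        logger.warning("too few comparisons for a spline trend; skipped")

    abundance = abundance_by_settlement(std, site_islands, settlements)

    return {
        "assemblages": assemblages,
        "comparisons": comparisons,
        "trends": trends,
        "site_summary": sites,
        "occupancy_summary": occupancy,
        "spline": spline,
        "abundance": abundance,
        "taxon_counts": taxon_counts,
        "rarefaction_target": target_used,
    }


def _spline_frame(spline) -> pd.DataFrame:
    if spline is None:
        return pd.DataFrame(columns=["age_bp", "fit", "ci_low", "ci_high"])
    return pd.DataFrame(
        {"age_bp": spline.grid, "fit": spline.fit,
         "ci_low": spline.ci_low, "ci_high": spline.ci_high}
    )


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured analysis and write all outputs plus a manifest.

    Outputs (CSV) and ``manifest.json`` go to ``config.output_dir``; the
    manifest records inputs, seed, versions and row counts at every stage.
    Returns the manifest dict.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(out / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("pollentrends")
    root.addHandler(log_handler)
    try:
        if config.synthetic is not None:
            site_meta, settlements_df, name_table, samples, _truth = generate_archipelago(
                config.synthetic
            )
            settlements = dict(
                zip(settlements_df["island_id"], settlements_df["settlement_age_bp"])
            )
            write_samples(samples, out / "samples.csv")
            write_name_table(name_table, out / "name_table.csv")
            write_settlements(settlements_df, out / "settlements.csv")
            write_site_meta(site_meta, out / "site_meta.csv")
            inputs = {"synthetic": True, "synthetic_seed": config.synthetic.seed}
        else:
            samples = read_samples(config.samples_path)
            name_table = read_name_table(config.name_table_path)
            settlements = read_settlements(config.settlements_path)
            site_meta = read_site_meta(config.site_meta_path)
            inputs = {
                "synthetic": False,
                "samples": str(config.samples_path),
                "name_table": str(config.name_table_path),
                "settlements": str(config.settlements_path),
                "site_meta": str(config.site_meta_path),
            }

        result = analyze(
            samples,
            name_table,
            site_meta,
            settlements,
            mode=config.mode,
            rarefaction_target=config.rarefaction_target,
            rarefy_method=config.rarefy_method,
            average_domain=config.average_domain,
            occupancy_edge=config.occupancy_edge,
            sensitivity=config.sensitivity,
            seed=config.seed,
        )

        result["assemblages"].to_csv(out / "assemblages.csv", index=False)
        result["comparisons"].to_csv(out / "comparisons.csv", index=False)
        result["trends"].to_csv(out / "trends.csv", index=False)
        result["site_summary"].to_csv(out / "site_summary.csv", index=False)
        result["occupancy_summary"].to_csv(out / "occupancy_summary.csv", index=False)
        _spline_frame(result["spline"]).to_csv(out / "spline.csv", index=False)
        result["abundance"].to_csv(out / "abundance.csv", index=False)

        occ = result["occupancy_summary"]
        manifest = {
            "package_version": __version__,
            "versions": {
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "inputs": inputs,
            "seed": config.seed,
            "mode": str(StandardizationMode(config.mode).value),
            "sensitivity": (
                None if config.sensitivity is None else config.sensitivity.variant
            ),
            "rarefaction_target": result["rarefaction_target"],
            "taxon_counts": result["taxon_counts"],
            "n_samples": int(samples.drop_duplicates(["site_id", "age_bp"]).shape[0]),
            "n_assemblages": int(
                result["assemblages"][["site_id", "interval_index"]]
                .drop_duplicates().shape[0]
            ),
            "n_comparisons": int(len(result["comparisons"])),
            "n_comparisons_by_occupancy": {
                r["occupancy"]: int(r["n"]) for _, r in occ.iterrows()
            },
            "n_pair_trends": int(len(result["trends"])),
        }
        assert sum(manifest["n_comparisons_by_occupancy"].values()) == manifest["n_comparisons"]
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest
    finally:
        root.removeHandler(log_handler)
        log_handler.close()
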