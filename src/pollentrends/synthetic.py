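"""Synthetic archipelago generator for end-to-end pipeline testing.

Emulates the statistical structure of a multi-island fossil-pollen
compilation: 15 sites on 13 islands, two human-settlement waves (~3,000 and
~700 cal yr BP), heterogeneous pollen-count depths including
percentage-only records, messy taxon names (synonyms, "cf." forms,
multi-match types, indeterminate categories), and a post-settlement
compositional shift toward shared open-vegetation (disturbance) taxa.

Generative model per site sample:

1. every site has a fixed baseline composition mixing a shared regional
   Dirichlet mean with a site-specific Dirichlet mean, with mixing weight
   ``exp(-lambda * d)`` in the island's distance ``d`` to the archipelago
   centroid (compositional similarity decays with distance);
2. for ages younger than the island's settlement date, a fraction
   ``delta`` of probability mass is moved onto the shared disturbance taxa
   (Poaceae and Cyperaceae), ramped linearly over the first 500 years
   after settlement and constant thereafter;
3. a small fixed fraction of each sample is emitted as indeterminate /
   unknown spore types so the unknown-removal step is exercised;
4. counts are multinomial at the sample's count depth; percentage-only
   sites report percentages with no counts.

Taxon names in the default pool are real Pacific plant families, genera
and species, but the synonym strings and all abundances are synthetic
fixtures, not field data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .taxonomy import NameTable, TaxonEntry, TaxonStatus

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "ConfigurationError",
    "generate_archipelago",
    "generate_name_table",
    "DISTURBANCE_TAXA",
]

DISTURBANCE_TAXA = ("Poaceae", "Cyperaceae")

EARLY_WAVE = 3_000.0
LATE_WAVE = 700.0

#: (name, rank, genus, family); disturbance families first so any pool size
#: >= 3 contains them, and the ranks interleaved so small pools still hold
#: families, genera and species.  Synthetic fixture pool (plausible Pacific
#: taxa).
DEFAULT_POOL: tuple[tuple[str, str, str, str], ...] = (
    ("Poaceae", "family", "", "Poaceae"),
    ("Cyperaceae", "family", "", "Cyperaceae"),
    ("Euphorbiaceae", "family", "", "Euphorbiaceae"),
    ("Macaranga", "genus", "Macaranga", "Euphorbiaceae"),
    ("Mallotus", "genus", "Mallotus", "Euphorbiaceae"),
    ("Ipomoea batatas", "species", "Ipomoea", "Convolvulaceae"),
    ("Arecaceae", "family", "", "Arecaceae"),
    ("Metrosideros", "genus", "Metrosideros", "Myrtaceae"),
    ("Cocos nucifera", "species", "Cocos", "Arecaceae"),
    ("Moraceae", "family", "", "Moraceae"),
    ("Ficus", "genus", "Ficus", "Moraceae"),
    ("Casuarina equisetifolia", "species", "Casuarina", "Casuarinaceae"),
    ("Myrtaceae", "family", "", "Myrtaceae"),
    ("Syzygium", "genus", "Syzygium", "Myrtaceae"),
    ("Pometia pinnata", "species", "Pometia", "Sapindaceae"),
    ("Casuarinaceae", "family", "", "Casuarinaceae"),
    ("Pandanus", "genus", "Pandanus", "Pandanaceae"),
    ("Terminalia catappa", "species", "Terminalia", "Combretaceae"),
    ("Urticaceae", "family", "", "Urticaceae"),
    ("Freycinetia", "genus", "Freycinetia", "Pandanaceae"),
    ("Calophyllum inophyllum", "species", "Calophyllum", "Calophyllaceae"),
    ("Sapindaceae", "family", "", "Sapindaceae"),
    ("Cocos", "genus", "Cocos", "Arecaceae"),
    ("Cerbera odollam", "species", "Cerbera", "Apocynaceae"),
    ("Rubiaceae", "family", "", "Rubiaceae"),
    ("Casuarina", "genus", "Casuarina", "Casuarinaceae"),
    ("Planchonella garberi", "species", "Planchonella", "Sapotaceae"),
    ("Fabaceae", "family", "", "Fabaceae"),
    ("Ipomoea", "genus", "Ipomoea", "Convolvulaceae"),
    ("Malvaceae", "family", "", "Malvaceae"),
    ("Cyathea", "genus", "Cyathea", "Cyatheaceae"),
    ("Pandanaceae", "family", "", "Pandanaceae"),
    ("Elaeocarpus", "genus", "Elaeocarpus", "Elaeocarpaceae"),
    ("Araliaceae", "family", "", "Araliaceae"),
    ("Terminalia", "genus", "Terminalia", "Combretaceae"),
    ("Pometia", "genus", "Pometia", "Sapindaceae"),
    ("Trema", "genus", "Trema", "Cannabaceae"),
    ("Weinmannia", "genus", "Weinmannia", "Cunoniaceae"),
    ("Hibiscus", "genus", "Hibiscus", "Malvaceae"),
    ("Geniostoma", "genus", "Geniostoma", "Loganiaceae"),
)

#: raw synonym strings (a few real ones; the rest invented fixtures)
SYNONYMS = {
    "Poaceae": "Gramineae",
    "Arecaceae": "Palmae",
    "Fabaceae": "Leguminosae",
    "Ficus": "Urostigma",
    "Metrosideros": "Nania",
    "Trema": "Sponia",
    "Hibiscus": "Pariti",
    "Elaeocarpus": "Monocera",
}

#: congeneric-family pairs eligible for multi-match raw names
MULTI_PAIRS = {
    "Macaranga": ("Mallotus", "Euphorbiaceae"),
    "Mallotus": ("Macaranga", "Euphorbiaceae"),
    "Metrosideros": ("Syzygium", "Myrtaceae"),
    "Syzygium": ("Metrosideros", "Myrtaceae"),
    "Pandanus": ("Freycinetia", "Pandanaceae"),
    "Freycinetia": ("Pandanus", "Pandanaceae"),
}

UNKNOWN_TYPES: tuple[tuple[str, TaxonStatus], ...] = (
    ("Indeterminate", TaxonStatus.INDETERMINATE),
    ("Unknown spore", TaxonStatus.INDETERMINATE),
    ("Trilete spore", TaxonStatus.UNCERTAIN_ABOVE_FAMILY),
)


class ConfigurationError(ValueError):
    """Inconsistent synthetic-archipelago configuration."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters of the synthetic archipelago.

    Defaults mirror the emulated study: 15 sites on 13 islands, two
    settlement waves at ~3,000 (western islands) and ~700 (eastern
    islands) cal yr BP, pollen sums of a few hundred grains, a fifth of
    records percentage-only, and a post-settlement shift ``delta`` of
    composition onto the shared disturbance taxa.
    """

    n_sites: int = 15
    n_islands: int = 13
    pool_size: int = 40
    settlement_ages: dict[str, float] | None = None  # None -> two-wave default
    delta: float = 0.4
    distance_decay: float = 0.15  # per degree of inter-island distance
    count_depth_range: tuple[int, int] = (150, 800)
    pct_only_fraction: float = 0.2
    samples_per_site: int = 40
    time_span: tuple[float, float] = (5_000.0, -50.0)
    messy_name_fraction: float = 0.15
    unknown_fraction: float = 0.03
    # sparse site floras (few dominant taxa each) keep pre-settlement
    # between-island similarity low, as in real island pollen records
    dirichlet_base: float = 0.2
    dirichlet_disturbance: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.delta <= 1):
            raise ConfigurationError("delta must lie in [0, 1]")
        if self.pool_size < 3 or self.pool_size > len(DEFAULT_POOL):
            raise ConfigurationError(
                f"pool_size must lie in [3, {len(DEFAULT_POOL)}]"
            )
        if self.n_islands > self.n_sites:
            raise ConfigurationError("n_islands must not exceed n_sites")
        if self.n_islands < 1:
            raise ConfigurationError("need at least one island")
        if not (0 <= self.pct_only_fraction <= 1):
            raise ConfigurationError("pct_only_fraction must lie in [0, 1]")
        if not (0 <= self.messy_name_fraction <= 1):
            raise ConfigurationError("messy_name_fraction must lie in [0, 1]")
        if not (0 <= self.unknown_fraction < 1):
            raise ConfigurationError("unknown_fraction must lie in [0, 1)")
        if self.distance_decay < 0:
            raise ConfigurationError("distance_decay must be nonnegative")
        lo, hi = self.count_depth_range
        if not (1 <= lo <= hi):
            raise ConfigurationError("count_depth_range must satisfy 1 <= min <= max")
        old, young = self.time_span
        if not old > young:
            raise ConfigurationError("time_span must be (oldest, youngest) with oldest > youngest")


@dataclass
class SyntheticTruth:
    """Ground truth of one synthetic archipelago for parameter-recovery tests."""

    baseline: pd.DataFrame          # site x taxon baseline compositions (sum to 1)
    settlement_ages: dict[str, float]
    delta: float
    disturbance_taxa: tuple[str, ...]
    unknown_fraction: float
    raw_names: dict[str, str]       # accepted name -> emitted raw form

    def expected_composition(self, site_id: str, island_id: str, age: float) -> pd.Series:
        """Expected pool composition of a sample (before the unknown overlay)."""
        p = self.baseline.loc[site_id].astype(float)
        settle = self.settlement_ages.get(island_id, np.nan)
        r = 0.0
        if np.isfinite(settle) and age < settle:
            r = min((settle - age) / 500.0, 1.0)
        q = pd.Series(0.0, index=p.index)
        q.loc[list(self.disturbance_taxa)] = 1.0 / len(self.disturbance_taxa)
        return (1.0 - self.delta * r) * p + self.delta * r * q


def _pool(config: SyntheticConfig) -> list[tuple[str, str, str, str]]:
    return list(DEFAULT_POOL[: config.pool_size])


def _default_settlements(islands: pd.DataFrame) -> dict[str, float]:
    """Two-wave default: western half settled ~3,000, eastern half ~700 BP."""
    order = islands.sort_values("lon")["island_id"].tolist()
    n_early = (len(order) + 1) // 2
    return {
        isl: (EARLY_WAVE if i < n_early else LATE_WAVE) for i, isl in enumerate(order)
    }


def _build_names(config: SyntheticConfig) -> tuple[NameTable, dict[str, str]]:
    """Name table plus accepted-name -> raw-form map, deterministic in seed."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))
    pool = _pool(config)
    n_messy = int(round(config.messy_name_fraction * len(pool)))
    raw_of = {name: name for name, *_ in pool}
    entries: dict[str, TaxonEntry] = {}

    species = [t for t in pool if t[1] == "species"]
    multi = [t for t in pool if t[0] in MULTI_PAIRS]
    order = list(rng.permutation(len(pool)))
    chosen: list[tuple[str, tuple[str, str, str, str]]] = []
    kinds = ["synonym", "cf_species", "multi_match"]
    ki = 0
    used: set[str] = set()
    while len(chosen) < n_messy and len(used) < len(pool):
        kind = kinds[ki % len(kinds)]
        ki += 1
        eligible = {
            "synonym": pool,
            "cf_species": species,
            "multi_match": multi,
        }[kind]
        pick = next(
            (pool[i] for i in order if pool[i][0] not in used and pool[i] in eligible),
            None,
        )
        if pick is None:
            pick = next((pool[i] for i in order if pool[i][0] not in used), None)
            kind = "synonym"
        if pick is None:
            break
        used.add(pick[0])
        chosen.append((kind, pick))

    for kind, (name, rank, genus, family) in chosen:
        if kind == "cf_species" and rank == "species":
            gen, epithet = name.split(" ", 1)
            raw = f"{gen} cf. {epithet}"
            entries[raw] = TaxonEntry(
                raw_name=raw, status=TaxonStatus.CF_SPECIES, accepted_name=name,
                rank="species", genus=genus or gen, family=family,
            )
            raw_of[name] = raw
        elif kind == "multi_match" and name in MULTI_PAIRS:
            partner, shared_family = MULTI_PAIRS[name]
            raw = f"{name}/{partner}"
            if raw not in entries and f"{partner}/{name}" not in entries:
                entries[raw] = TaxonEntry(
                    raw_name=raw, status=TaxonStatus.MULTI_MATCH, accepted_name="",
                    rank="", genus="", family=shared_family,
                    multi_match_members=(name, partner),
                )
                raw_of[name] = raw
        else:
            raw = SYNONYMS.get(name, f"Eo{name[0].lower()}{name[1:]}")
            entries[raw] = TaxonEntry(
                raw_name=raw, status=TaxonStatus.SYNONYM, accepted_name=name,
                rank=rank, genus=genus, family=family,
            )
            raw_of[name] = raw

    for name, rank, genus, family in pool:
        if name not in entries and raw_of[name] == name:
            entries[name] = TaxonEntry(
                raw_name=name, status=TaxonStatus.ACCEPTED, accepted_name=name,
                rank=rank, genus=genus, family=family,
            )
    # accepted rows for messy taxa are still listed so standardized output
    # can be re-standardized (idempotence)
    for name, rank, genus, family in pool:
        if name not in entries:
            entries[name] = TaxonEntry(
                raw_name=name, status=TaxonStatus.ACCEPTED, accepted_name=name,
                rank=rank, genus=genus, family=family,
            )
    for raw, status in UNKNOWN_TYPES:
        entries[raw] = TaxonEntry(raw_name=raw, status=status)
    return NameTable(list(entries.values())), raw_of


def generate_name_table(config: SyntheticConfig) -> NameTable:
    """The name table a matching :func:`generate_archipelago` call emits."""
    config.validate()
    return _build_names(config)[0]


def generate_archipelago(
    config: SyntheticConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, NameTable, pd.DataFrame, SyntheticTruth]:
    """Generate one synthetic archipelago.

    Returns ``(site_meta, settlements, name_table, samples, truth)``:

    * ``site_meta``: site_id, island_id, elevation_m, lon, lat
    * ``settlements``: island_id, settlement_age_bp (NaN = never settled)
    * ``samples``: long table site_id, age_bp, taxon (raw name), value,
      value_kind
    * ``truth``: :class:`SyntheticTruth` for parameter-recovery tests

    Identical configs (including seed) produce identical outputs.
    """
    config = config or SyntheticConfig()
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 29]))
    name_table, raw_of = _build_names(config)
    pool = _pool(config)
    taxa = [name for name, *_ in pool]
    n_taxa = len(taxa)

    # islands west -> east with jittered positions
    island_ids = [f"I{i + 1:02d}" for i in range(config.n_islands)]
    lon = np.sort(rng.uniform(150.0, 230.0, size=config.n_islands))
    lat = rng.uniform(-25.0, -5.0, size=config.n_islands)
    islands = pd.DataFrame({"island_id": island_ids, "lon": lon, "lat": lat})

    # first (n_sites - n_islands) islands carry a second site
    site_islands = list(range(config.n_islands))
    site_islands += list(range(config.n_sites - config.n_islands))
    site_islands.sort()
    site_meta = pd.DataFrame(
        {
            "site_id": [f"S{i + 1:02d}" for i in range(config.n_sites)],
            "island_id": [island_ids[j] for j in site_islands],
            "elevation_m": np.round(rng.uniform(0.0, 760.0, size=config.n_sites), 1),
            "lon": lon[site_islands],
            "lat": lat[site_islands],
        }
    )

    if config.settlement_ages is None:
        settlement = _default_settlements(islands)
    else:
        settlement = {k: (np.nan if v in (None, "never") else float(v))
                      for k, v in config.settlement_ages.items()}
        missing = set(island_ids) - set(settlement)
        if missing:
            raise ConfigurationError(
                f"settlement_ages must cover all islands (or mark them 'never'); missing {sorted(missing)}"
            )
    settlements = pd.DataFrame(
        {
            "island_id": island_ids,
            "settlement_age_bp": [settlement[i] for i in island_ids],
        }
    )

    # baseline compositions: regional/site Dirichlet mix with distance decay
    alpha = np.full(n_taxa, config.dirichlet_base)
    for d in DISTURBANCE_TAXA:
        alpha[taxa.index(d)] = config.dirichlet_disturbance
    regional = rng.dirichlet(alpha)
    centroid = np.array([lon.mean(), lat.mean()])
    baseline = np.empty((config.n_sites, n_taxa))
    for i, isl in enumerate(site_islands):
        d = float(np.hypot(lon[isl] - centroid[0], lat[isl] - centroid[1]))
        w = float(np.exp(-config.distance_decay * d))
        own = rng.dirichlet(alpha)
        baseline[i] = w * regional + (1.0 - w) * own
    baseline_df = pd.DataFrame(baseline, index=site_meta["site_id"], columns=taxa)

    dist_mask = np.isin(taxa, DISTURBANCE_TAXA).astype(float)
    q = dist_mask / dist_mask.sum()
    unknown_names = [u for u, _ in UNKNOWN_TYPES]
    n_unknown = len(unknown_names)

    n_pct_only = int(round(config.pct_only_fraction * config.n_sites))
    pct_sites = set(
        rng.choice(site_meta["site_id"].to_numpy(), size=n_pct_only, replace=False)
    )

    old, young = config.time_span
    rows: list[dict] = []
    truth_raw: dict[str, str] = dict(raw_of)
    for i, site in enumerate(site_meta["site_id"]):
        isl = site_meta["island_id"].iloc[i]
        settle = settlement[isl]
        ages = np.sort(rng.uniform(young, old, size=config.samples_per_site))[::-1]
        for age in ages:
            r = 0.0
            if np.isfinite(settle) and age < settle:
                r = min((settle - age) / 500.0, 1.0)
            comp = (1.0 - config.delta * r) * baseline[i] + config.delta * r * q
            full = np.concatenate(
                [
                    (1.0 - config.unknown_fraction) * comp,
                    np.full(n_unknown, config.unknown_fraction / n_unknown),
                ]
            )
            depth = int(rng.integers(config.count_depth_range[0],
                                     config.count_depth_range[1] + 1))
            counts = rng.multinomial(depth, full / full.sum())
            names = [truth_raw[t] for t in taxa] + unknown_names
            as_pct = site in pct_sites
            for nm, c in zip(names, counts):
                if c == 0:
                    continue
                rows.append(
                    {
                        "site_id": site,
                        "age_bp": round(float(age), 1),
                        "taxon": nm,
                        "value": (100.0 * c / depth) if as_pct else float(c),
                        "value_kind": "percentages" if as_pct else "counts",
                    }
                )
    samples = pd.DataFrame(rows, columns=["site_id", "age_bp", "taxon", "value", "value_kind"])
    # raw-name collisions (e.g. both Macaranga and Mallotus mapped to the
    # same multi-match string) are merged like duplicate rows on read
    dup = samples.duplicated(["site_id", "age_bp", "taxon"], keep=False)
    if dup.any():
        samples = (
            samples.groupby(["site_id", "age_bp", "taxon", "value_kind"], as_index=False, sort=False)["value"]
            .sum()[["site_id", "age_bp", "taxon", "value", "value_kind"]]
        )
    samples = samples.sort_values(["site_id", "age_bp", "taxon"], ascending=[True, False, True]).reset_index(drop=True)

    truth = SyntheticTruth(
        baseline=baseline_df,
        settlement_ages=dict(settlement),
        delta=config.delta,
        disturbance_taxa=DISTURBANCE_TAXA,
        unknown_fraction=config.unknown_fraction,
        raw_names=truth_raw,
    )
    return site_meta, settlements, name_table, samples, truth


def variant(config: SyntheticConfig, **changes) -> SyntheticConfig:
    """A copy of ``config`` with the given fields replaced."""
    return replace(config, **changes)
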