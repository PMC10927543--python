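# pollentrends

Quantifying **floristic homogenization** — the increasing similarity of
plant community composition between distinct places — from multi-site
fossil pollen records, with the South Pacific islands as the motivating
setting: 15 pollen records on 13 islands spanning the past 5,000 years,
settled by people in two waves (~3,000 and ~700 cal yr BP).

The package is for palaeoecologists and community ecologists who have
long-format pollen (or spore) count tables per site and want a tested,
reproducible pipeline from raw counts to similarity-trend statistics. It
also ships a synthetic archipelago generator, so the entire analysis is
runnable and testable with no field data at all.

## The analysis

1. **Taxonomic standardization.** Raw pollen-type names are harmonized
   against a local name table: synonyms are replaced by accepted names,
   indeterminate types and types identifiable only above family level are
   removed, multi-match types (e.g. *Macaranga*/*Mallotus*) are aggregated
   to the lowest shared rank (here Euphorbiaceae), and tentative
   identifications ("*Ipomoea* cf. *batatas*") are kept at species level
   (standardization 1) or lifted to genus (standardization 2).
2. **Rarefaction.** Count samples are subsampled without replacement
   (multivariate hypergeometric) to a common depth — by default the
   minimum pollen sum — removing count-effort differences. Percentage-only
   records pass through.
3. **Binning.** Samples are placed in ten 500-year intervals tiling
   (4,900, −100] cal yr BP and averaged per (site, interval) cell; cell
   means are expressed as percentages.
4. **Similarity.** For each unordered site pair within each interval, the
   Bray–Curtis index is inverted to a similarity,

   *S*(a, b) = 2 Σᵢ min(aᵢ, bᵢ) / Σᵢ (aᵢ + bᵢ),

   which weights by abundance and ignores joint absences. Each comparison
   is labelled by whether **neither**, **one** or **both** islands had
   been settled by people during that interval.
5. **Trends.** Per pair, an OLS slope of similarity on age (≥ 4 interval
   points required). Because age increases into the past, *slope < 0*
   means similarity rising toward the present — homogenization. Per-site
   and per-occupancy-group box statistics summarize the slopes and
   similarities, and a cubic smoothing spline (penalty chosen by
   generalized cross-validation, pointwise 95% CIs) gives the overall
   trend curve.
6. **Sensitivity variants.** Re-run after dropping samples with pollen
   sums < 300, after excluding dominant disturbance taxa (Cyperaceae,
   Poaceae), or restricting to a single taxonomic rank.

## Worked example

Run the whole pipeline on a synthetic 15-site archipelago (seed-controlled,
settlement waves at 3,000/700 cal yr BP, a 0.4 post-settlement shift onto
shared open-vegetation taxa):

```sh
$ pollentrends run-all --synthetic --seed 1 --out demo
1008 comparisons, 105 pair trends -> demo
```

`demo/` now holds the emitted inputs (`samples.csv`, `name_table.csv`,
`settlements.csv`, `site_meta.csv`), every stage's output
(`assemblages.csv`, `comparisons.csv`, `trends.csv`, `site_summary.csv`,
`occupancy_summary.csv`, `spline.csv`, `abundance.csv`) and a
`manifest.json` recording seeds, versions and stage counts, e.g.:

```
n_samples: 600        n_assemblages: 147   rarefaction_target: 144
n_comparisons: 1008   n_pair_trends: 105
```

The occupancy summary shows the settlement contrast the generator injected:

```
occupancy,n,median,...
neither,390,0.2505,...
one,258,0.2066,...
both,360,0.4880,...
```

Pairs of islands that were *both* settled in an interval are markedly more
similar (median 0.49) than pairs where one or neither was settled
(≈ 0.21–0.25): human settlement homogenizes the island floras. The same
run in Python:

```python
import pollentrends as pt

site_meta, settlements, names, samples, truth = pt.generate_archipelago(
    pt.SyntheticConfig(seed=1)
)
settle = dict(zip(settlements["island_id"], settlements["settlement_age_bp"]))
res = pt.analyze(samples, names, site_meta, settle, seed=1)
res["occupancy_summary"]   # settlement contrast
res["site_summary"]        # per-site homogenizing proportions
res["spline"].fit          # overall trend curve
```

Stage-wise subcommands (`simulate`, `standardize`, `assemble`, `compare`,
`trends`, `report`) expose the same steps on CSV files; `report --figures`
writes the standard summary figures.

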