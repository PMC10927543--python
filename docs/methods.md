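# Methods

## Scope and data model

The pipeline quantifies trends in compositional similarity between fossil
pollen records. Its canonical in-memory containers are pandas tables:

* **samples** — long format `site_id, age_bp, taxon, value, value_kind`,
  one row per taxon per dated sample; `value_kind` is `counts` (integer
  pollen sums) or `percentages` (digitized diagrams with no counts).
  Ages are cal yr BP (present = 1950 CE), negative for post-1950.
* **name table** — `raw_name, status, accepted_name, rank, genus, family,
  multi_match_members`, one row per raw pollen-type name. This is a
  required local input: nomenclature is deliberately resolved offline so
  runs are reproducible and auditable.
* **site metadata** (`site_id, island_id, elevation_m, lon, lat`) and a
  **settlement table** (`island_id, settlement_age_bp`, `never` allowed).

## Standardization

Raw names are matched exactly after trimming, collapsing internal
whitespace and upper-casing the first letter; anything fuzzier would mask
errors in the name table, and pollen-type names are short controlled
strings. Unmatched names are a hard error listing the offenders — never a
silent pass-through.

Resolution rules, applied per raw name: indeterminate types and types
identifiable only above family are removed; synonyms take their accepted
name; multi-match types aggregate to the lowest rank shared by their
members (genus if congeneric, else family; members from different
families are removed with a warning, since aggregation above family is
not meaningful here); "cf." species resolve to the species under
standardization 1 and to their genus under standardization 2. Counts of
raw names mapping to one standardized name are summed per sample, so each
sample's total shrinks by exactly the removed values. Standardization is
idempotent, and the STD2 taxon list never retains a species that STD1
maps elsewhere.

## Rarefaction

Pollen sums in compilations like this span an order of magnitude, which
inflates the apparent richness (and hence dissimilarity) of deeply
counted samples. Count samples are therefore subsampled **without
replacement** to a common target — a multivariate hypergeometric draw —
before standardization, with unknown types excluded from the pollen sum
first. Random subsampling (rather than expected-richness rarefaction) is
used because the downstream similarity index needs abundances, not
richness. The target defaults to the minimum pollen sum among count
samples; it can be overridden, in which case samples below the target
pass through unrarefied with a logged flag, mirroring the retention of
percentage-only records. Rarefaction is unbiased for composition: the
expected post-rarefaction percentages equal the input percentages
(checked by Monte Carlo against the hypergeometric mean).

## Binning and averaging

The grid is ten 500-year intervals tiling (4,900, −100] cal yr BP,
anchored at the printed interval labels "4,900–4,400" and "400 to the
present". Membership is young-inclusive: a sample sitting exactly on an
interval's young bound belongs to the older interval (4,400 BP is in
4,900–4,400), a sample at exactly 4,900 BP is kept in the earliest
interval, and ages at or below −100 BP are outside the grid. The
convention is measure-zero for real dated samples but is pinned down so
runs are exactly reproducible.

Within each (site, interval) cell the per-taxon **arithmetic mean of the
rarefied counts** (or reported percentages, for percentage-only sites) is
taken — taxa absent from a sample count as zero — and converted to
percentages of the mean total. Averaging in the abundance domain before
the percentage transform is the default; a `percentage` averaging domain
is available as a switch. Empty cells produce no assemblage; no
interpolation is done.

## Similarity and occupancy

Within each interval, every unordered pair of sites with assemblages is
compared with the inverted Bray–Curtis index
`2 Σ min(a_i, b_i) / Σ (a_i + b_i)` on the percentage assemblages.
The index is symmetric, 1 iff the compositions are identical, 0 iff they
share no taxa, ignores joint absences, and is invariant to a common
rescaling — all property-tested, plus a cross-check against an
independent implementation (scipy's `braycurtis` distance).

An island counts as settled within an interval iff its settlement date is
older than the interval's **young** bound, so the interval containing the
settlement event is already "settled" (impacts begin at settlement). The
alternative old-bound rule is available as the `occupancy_edge` switch.
Pairs are labelled `neither` / `one` / `both`; two sites on one island
share settlement status, and same-island site pairs are retained.

## Trends and summaries

Each pair's (interval midpoint age, similarity) series gets an ordinary
least-squares slope, provided it has at least four points. The regressor
is the interval midpoint in cal yr BP (4,650 for the earliest interval),
so **negative slopes mean homogenization** (similarity rising toward the
present); reversing the time axis exactly flips every slope sign. A slope
of exactly zero is classified "flat" and counts toward neither direction
(measure-zero in practice). Per-site summaries report the fraction of
negative slopes and median/quartile statistics (linearly interpolated
quartiles, the common boxplot default); occupancy-group summaries add
Tukey whiskers (furthest points within 1.5 × IQR).

The overall trend is a **cubic smoothing spline** of similarity on age
over all comparisons. Duplicate ages (all comparisons in an interval
share its midpoint) are collapsed to weighted means, which is exactly
equivalent under the penalized least-squares criterion. The roughness
penalty λ is selected by minimizing the generalized cross-validation
score n·RSS/(n − tr(S))² on a log-λ grid with ternary refinement; the
smoother trace tr(S) is computed exactly (unit-vector smoothing) for up
to 120 unique ages and by a fixed-seed Hutchinson estimator above that.
The grid is capped at (age range)³ × 10⁴ because the banded solver loses
accuracy at extreme penalties — by then the fit is already
indistinguishable from the OLS line, its large-λ limit. Pointwise 95%
confidence bands are propagated through the linear smoother matrix with
the residual variance estimated on n − tr(S) degrees of freedom; they
are pointwise, not simultaneous.

## Sensitivity variants

Three robustness checks re-enter the unchanged downstream pipeline:
`min_count` drops count samples with original pollen sums strictly below
a threshold (default 300) **before** rarefaction, so the rarefaction
target is recomputed on the retained samples (threshold 0 reproduces the
baseline bit-for-bit); `exclude_taxa` removes named taxa (default
Cyperaceae and Poaceae) from the percentage assemblages **after**
interval averaging and renormalizes, keeping rarefaction identical to the
baseline; `same_rank` restricts assemblages to taxa of one rank and
renormalizes. "Same rank" is read as a restriction of the assemblages —
rank-wise partial similarities are a plausible alternative reading, but
restriction keeps the comparison set interpretable and is parameterized
so all three ranks can be run.

## The synthetic archipelago

The generator emulates the statistical structure the analysis assumes,
with defaults set once to the emulated study design: 15 sites on 13
islands (two islands carry two sites), western islands settled at
~3,000 cal yr BP and eastern at ~700, 40 samples per site drawn uniformly
over (5,000, −50) cal yr BP (records are irregularly sampled), pollen
sums uniform on 150–800 grains so the 300-grain sensitivity threshold
bites, a fifth of sites percentage-only, and ~3% of each sample emitted
as indeterminate/unknown types so the unknown-removal step is exercised.

Per site, a fixed baseline composition mixes a shared regional Dirichlet
mean with a site-specific Dirichlet mean, with weight exp(−λ·d) in the
island's distance d to the archipelago centroid — the simplest
distance-decay structure with one knob (λ = 0.15 per degree by default).
The Dirichlet concentration (0.2 per ordinary taxon, 0.02 for the
disturbance taxa) makes site floras sparse, keeping pre-settlement
between-island similarity low, as in real island pollen records. After an
island's settlement date, a fraction δ (default 0.4) of probability mass
moves onto the two shared disturbance taxa — named Poaceae and Cyperaceae
so the sensitivity analyses are exercisable verbatim — ramped linearly
over the first 500 years (avoiding a discontinuity exactly at a bin
edge). Counts are multinomial at the sample's depth. A configurable
fraction of taxa is emitted under messy raw names (synonyms, "cf."
forms, multi-match strings) listed in the emitted name table; the pool
names are plausible Pacific taxa but the synonym strings and all
abundances are synthetic fixtures.

What the generator does **not** emulate: sediment taphonomy and pollen
productivity biases, radiocarbon age uncertainty, autocorrelated sampling
depths, hydroseral succession, and any spatially explicit dispersal — so
green tests demonstrate that the pipeline recovers the generative signal,
not that real records satisfy these assumptions. The pre-settlement
similarity structure (distance decay, sparsity) is a modelling choice,
not an inference from data.

## Numerical and degenerate-input choices

All-zero abundance maps raise rather than emit NaN percentages; empty
assemblage cells are dropped and logged; pairs with fewer than four
interval points are dropped with a log entry, not an exception; unknown
raw names abort the run listing the names. Duplicate (site, age, taxon)
rows are summed on read with a warning; a sample mixing counts and
percentages is a hard error. CSV readers parse floats in round-trip mode
so a written archipelago re-reads bit-identically, making file-based and
in-memory runs byte-identical. Every source of randomness (generation
and rarefaction) descends from a single configured seed.

## Problem sizes

The test suite and the acceptance script run the default 15-site
archipelago (600 samples, ~1,000 pairwise comparisons); the
parameter-recovery check uses 100 seeds (20 for the per-site criterion)
and the null-control check 200 seeds, the replication counts at which the
directional claims are evaluated. Spline recovery is checked at n = 800
points with N(0, 0.02²) noise.

## Known limitations

No mixed-effects or autocorrelation-aware trend models (pairwise series
are short and strongly cross-correlated, so individual slope standard
errors would be optimistic and are not reported); no age-model
uncertainty propagation; no alternative similarity indices beyond the
implemented Bray–Curtis; spline bands are pointwise. Whether real
analyses averaged counts or percentages within intervals, and how
interval-edge settlement should be treated, are genuinely underdetermined
choices — both are exposed as configuration switches with the defaults
argued above.
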