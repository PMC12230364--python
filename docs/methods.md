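# Methods

This note documents the models and procedures implemented in `floristics`,
the choices made where the design was genuinely open, and what the synthetic
data do and do not demonstrate.

## Data model

The canonical input is a long-format occurrence table (one row per
reserve × species) with nested taxonomy (species → genus → family), a
closed areal-type vocabulary, and boolean endemic/cultivated flags.
Validation enforces that a species maps to exactly one genus and a genus to
exactly one family; duplicate (reserve, species) rows collapse with a count
in the validation report. Cultivated species — introductions that would
distort floristic similarity — are removed as whole species before any
analysis. Names are matched case-sensitively after whitespace
normalization; synonym resolution is assumed done upstream.

Reserve metadata carries WGS84 coordinates, three elevations per reserve
(base = lowest point, mean, peak, in meters, with base ≤ mean ≤ peak
enforced) and eight environmental variables: annual precipitation (mm),
annual mean temperature, coldest-quarter mean and warmest-quarter mean
(°C), each for the current period and the Last Glacial Maximum. Climate
values are inputs; no interpolation or paleoclimate simulation happens here.

## Similarity and distance

Presence/absence matrices are built at three levels. The areal-type matrix
is incidence over the type codes themselves (≤ 15 columns): a reserve's row
is the set of areal types represented in its flora. Computing it over
type-tagged genera instead was considered and rejected as the default — it
duplicates the genus level's information — but genus-level incidence under
any coefficient remains available through the API.

Coefficients: Sørensen `2a/(2a+b+c)` at species level, Szymkiewicz–Simpson
`a/min(|A|,|B|)` at genus level (insensitive to richness imbalance, which
matters when a species-poor high-elevation reserve is compared with a rich
lowland one), Jaccard `a/(a+b+c)` for areal-type spectra. Empty taxon sets
are errors, not zeros: an empty reserve is a data defect. Distances are
`d = 1 − S`; this preserves rank order, which is all downstream clustering
consumes. Note `1 − szymkiewicz` violates the triangle inequality, so no
stage assumes metricity.

## Regionalization

Per-level clustering is agglomerative with average linkage (UPGMA), chosen
for robustness to the non-metric genus distance. The implementation is
in-package for one reason: a deterministic tie rule. Among equal-distance
candidate merges (common in consensus distances, whose entries take only
four values) the pair with the lexicographically smallest (min member
index, max member index) merges first, making output independent of
platform and library internals. On tie-free inputs the implementation is
test-verified identical to `scipy.cluster.hierarchy.linkage(method=
"average")` at every cut.

The number of clusters is selected by maximal mean silhouette width over
k ∈ [2, 10] (ties to the smaller k). If all pairwise distances are equal
the silhouette is undefined and the smallest k is returned with a warning.

Consensus is the co-assignment matrix of the three hard labelings — entry
(i, j) is the fraction of levels in which i and j share a cluster — with
equal weight per level, then `1 − consensus` is clustered and cut at its own
silhouette-best k. Final regions are renumbered 1..k by the westernmost
member's longitude, giving stable, interpretable ids along an east–west
mountain axis.

## Endemic-genus components and dispersal gradients

Component labels (origin/diversification centers of endemic genera) and
origin coordinates are inputs from a curated table, never estimated.
Species-level override rows take precedence over the genus row, so a genus
whose species arose in different centers can contribute to two components;
the dataset-wide summary then counts the genus once per component and uses
the total of such pairs as denominator, keeping proportions summing to
100%. Endemic genera missing from the table are labeled `Uncertain`.

"Spreads X-ward with decreasing proportion" is a qualitative claim; it is
operationalized as distance decay: Spearman ρ between each reserve's
great-circle (haversine, Earth radius 6371.0088 km) distance from the
component's origin center and its count of that component's genera, with a
two-sided permutation p-value from seeded count shuffles (n_perm ≥ 199;
default 999). Permutation correlations are computed in one matrix product
on standardized ranks (permuting counts permutes their ranks). Constant
counts return ρ = NaN, p = 1, direction `flat`. The map export is
points-with-counts GeoJSON (RFC 7946) plus origin features; no least-cost
routes are inferred — route drawing is interpretive cartography, out of
scope.

Both per-reserve proportions (count / reserve endemic total) and raw counts
are exposed; the gradient test uses counts.

## Environmental drivers

**Importance.** "Mean decrease in accuracy" is realized as out-of-bag
permutation importance on a bagged ensemble of CART trees (default 500
trees, `sqrt` feature sampling, 100 permutation repeats, fixed seed): raw
importance of variable v = baseline OOB majority-vote accuracy minus OOB
accuracy with v's column permuted, averaged over repeats. The bagging loop
is explicit (per-tree bootstrap indices drawn from the seeded generator) so
OOB membership is exact and reproducible. Negative raw importances are
clipped to 0 before normalizing to percentages; relative importances sum to
100 ± 0.01. Correlated informative features split credit (the known masking
property) — interpret relative shares, not isolated magnitudes. The default
response is region membership; a richness-regression response is
deliberately not implemented as a default because region labels are the
pipeline's own product and keep the analysis self-contained.

**Group tests.** Per variable: Brown–Forsythe Levene (median-centered) at
α = 0.05 gates between one-way ANOVA (homogeneous variances) and
Kruskal–Wallis (tie-corrected). The gate level is conventional; raw p-values
are Benjamini–Hochberg adjusted across variables since many variables are
screened simultaneously. Constant variables are flagged and excluded from
adjustment. The test statistics are scipy's; the test suite holds
independent hand-computed and closed-form oracles against them.

**Elevation analysis.** All pairwise |Δelevation| within and between
regions for base/mean/peak. Thresholds — 900 m (base), 800 m (mean), 1000 m
(peak) within a region — are empirical report flags, not fitted parameters;
violations are listed as exceptions rather than errors because
topographically extreme regions can exceed the mean-elevation bound. A
"corridor statement" is emitted when every within-region maximum is below
1000 m while between-region differences reach 1000 m: terrain relief below
roughly 1000 m is the scale over which reserve floras mix freely.

## Synthetic data

The generator emulates: (i) latent regions occupying west→east longitude
bands of a 102–116°E × 29–37°N frame; (ii) per-region species pools = a
disjoint core plus one globally shared pool, sampled per reserve by
independent inclusion with probability `within_region_overlap`. Under this
model E[within-region Sørensen] equals the inclusion probability and
E[between-region Sørensen] ≈ shared_fraction × inclusion probability, so
the shared fraction is set to `between/within` — the two overlap knobs are
calibrated by construction, not tuned. (iii) Sequential species→genus→
family nesting per pool block; (iv) areal types with five common codes plus
two region-private codes per region (without rare, region-linked types,
every reserve would carry the full 15-code vocabulary and the areal-type
level would be uninformative); (v) endemic genera assigned to components
cyclically, with presence thinned by exp(−d/decay_length) from the
component's corner-of-frame origin; (vi) environmental variables = region
mean + Gaussian noise with per-variable effect sizes (precipitation
strongest by default); (vii) elevations = region base offset (1500 m
between regions) + ≤600 m uniform within-region spread, mean/peak stacked
above base; (viii) a block of cultivated species (default 372) sprinkled
over reserves.

Reference conditions (the generator defaults, used by the test suite and
acceptance script): 5 regions × 8 reserves, 2000-species pool, overlaps
0.7/0.2, 15 areal types, 6 components, 89 endemic genera, decay length
500 km, 372 cultivated species. All randomness flows from one integer seed
through named substreams (`SeedSequence([seed, stream_index])`), so adding
a stage never perturbs earlier draws and equal seeds give byte-identical
CSVs.

What passing tests show — and what they do not: recovery of planted regions
under these conditions demonstrates the pipeline's correctness, not that
real floras separate this cleanly; real occurrence data add spatial
autocorrelation, uneven sampling effort, richness gradients and taxonomic
noise that the generator deliberately omits. The distance-decay power
estimate likewise assumes the planted exponential form.

## Numerical choices and edge cases

- Similarity matrices are symmetrized (`(v + vᵀ)/2`) and clipped to [0, 1]
  against floating-point noise; diagonals are set exactly to 1 (0 for
  distances).
- Silhouette ties and merge ties both break toward the smaller/earlier
  candidate, for determinism.
- Permutation p-values use the add-one estimator `(1 + #extreme)/(1 + n_perm)`,
  never exactly zero.
- `hcluster` accepts k = n (all singletons); silhouette-based selection
  stays within [2, n − 1] where the score is defined.
- OOB voting ties break toward the smallest class index; samples never OOB
  (probability (1−1/n)^n_trees) are excluded from the accuracy.
- Kruskal–Wallis on fully tied data short-circuits to H = 0, p = 1; ANOVA
  with zero total variance warns and returns NaN.

## Problem sizes

Simulation studies use: 100 seeded datasets for recovery, 500 null
simulations (999 permutations each) for calibration, 100 seeds for power,
and 20 seeds (200 trees × 10 repeats) for importance ranks — sizes at which
the Monte-Carlo error of each reported rate is well below the margin being
asserted, while a full run stays interactive (~1 minute).

## Known limitations

- Consensus is built from hard per-level labelings with equal weights; no
  soft/fuzzy co-assignment or bootstrapped consensus.
- No spatial constraint in clustering: regions are floristic, and their
  geographic contiguity is an empirical outcome, not a constraint.
- Origin centers are single points; components with diffuse origins are
  represented only as well as their centroid.
- Permutation importance inherits the masking behavior of correlated
  predictors (current vs LGM climate pairs are correlated by construction).
- The corridor thresholds summarize pairwise differences; they are
  descriptive screens, not a mechanistic dispersal model.
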