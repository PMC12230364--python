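# floristics

Floristic regionalization of nature reserves from presence/absence plant
records: multi-level similarity, consensus clustering into regions,
endemic-genus dispersal gradients, environmental-driver importance, and the
within/between-region elevation analysis that diagnoses a mountain-corridor
effect.

## Who this is for

Biogeographers and biodiversity informaticians who have long-format survey
records (reserve × species, with genus/family taxonomy and phytogeographic
areal-type codes) and want to delineate floristic regions and ask what
drives them — the workflow used to analyse large east–west mountain systems
that act as dispersal corridors between floras.

## The method

**Multi-level similarity.** Reserves are compared at three levels, each with
the coefficient suited to it (a = shared taxa, b/c = taxa unique to either
reserve):

- species — Sørensen: `S = 2a / (2a + b + c)`
- genus — Szymkiewicz–Simpson overlap: `S = a / min(|A|, |B|)`
- areal type — Jaccard: `S = a / (a + b + c)`

For any pair of non-empty sets `jaccard ≤ sorensen ≤ szymkiewicz` (a
property-tested invariant). Similarities convert to distances `d = 1 − S`.

**Consensus regionalization.** Each level's distance matrix is clustered by
average linkage (UPGMA, with a deterministic merge tie rule) and cut at the
silhouette-best k; the three hard labelings are fused into a co-assignment
consensus matrix (entry = fraction of levels in which two reserves
co-cluster, so values lie in {0, ⅓, ⅔, 1}); `1 − consensus` is clustered
once more to give the final regions, renumbered west to east.

**Endemic-genus dispersal.** Each Chinese-endemic genus carries a
literature-derived geographic component (origin/diversification center) with
species-level overrides. Per-reserve component counts are tested for
distance decay: Spearman ρ between great-circle distance from the origin
center and genus count, with a seeded permutation p-value.

**Environmental drivers.** Permutation (mean-decrease-in-accuracy)
importance of climate and elevation variables for classifying region
membership, computed on out-of-bag samples of a bagged tree ensemble;
per-variable between-region tests gated by Brown–Forsythe Levene (ANOVA if
variances are homogeneous, Kruskal–Wallis otherwise), BH-adjusted. Pairwise
elevation differences within and between regions are screened against
corridor thresholds (base < 900 m, mean < 800 m, peak < 1000 m within a
region).

A seeded synthetic-data generator (`floristics.synth`) produces full
datasets with planted regions, taxonomy, areal types, component decay,
environmental effects, and a cultivated-species block, so every stage is
testable without any download.

## Worked example

```python
from floristics import (GeneratorConfig, generate, filter_cultivated,
                        regionalize, assign_components, component_counts,
                        gradient_test, importance, elevation_report)
from floristics.validation import distances_for

ds = generate(GeneratorConfig(seed=42))          # 5 regions x 8 reserves
occ, removed = filter_cultivated(ds.occurrences)
print("records:", len(occ), "| cultivated species removed:", removed)

ra = regionalize(distances_for(occ), lon=ds.meta.df["lon"])
print("regions:", ra.k, "| per-level k:", ra.per_level_k)

ann = assign_components(occ, ds.components)
cm = component_counts(ann, reserves=occ.reserves)
comp = "Central-East China"
res = gradient_test(cm, ds.meta, comp, ds.truth["origin_centers"][comp],
                    n_perm=999, seed=42)
print(f"gradient[{comp}]: rho={res.rho:.3f} p={res.p_perm:.4f} "
      f"direction={res.direction}")

rep = elevation_report(ds.meta, ra)
print("elevation flags:", rep.flags, "| corridor:", rep.corridor_statement)
```

prints

```
records: 9157 | cultivated species removed: 372
regions: 5 | per-level k: {'species': 5, 'genus': 5, 'areal_type': 5}
gradient[Central-East China]: rho=-0.705 p=0.0010 direction=decay
elevation flags: {'elev_base': True, 'elev_mean': True, 'elev_peak': True} | corridor: True
```

Reading the output: the 372 flagged cultivated species are excluded before
analysis; all three levels independently find the five planted regions and
the consensus keeps k = 5; the eastern component's genus counts fall
significantly with distance from its origin center (distance decay, the
signature of a dispersal gradient); and within-region elevation spreads stay
under the 900/800/1000 m thresholds while between-region differences exceed
1000 m — the corridor pattern.

There is also a CLI (`floristics simulate|validate|similarity|regionalize|
components|drivers|run-all`); `floristics run-all --seed 42 --outdir out`
writes every artifact (distance matrices, consensus matrix, region CSV,
component GeoJSON map, importance and elevation reports) plus a manifest
with a config hash — reruns are byte-identical.

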