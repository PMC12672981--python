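# forestuse

Spatial analysis of how agricultural expansion changes the **availability
of** and **access to** forest resources for forest-dependent (e.g.
Indigenous) communities in a dry-forest frontier landscape.

The package is aimed at landscape ecologists and ecosystem-services
analysts who have (or want to simulate) the typical data of such a study:
settlement point lists from multiple sources, surveyed resource-collection
sites, a deforestation plot database with conversion years, annual NDVI
composite stacks, land-claim demarcation lines, and surface-water
seasonality rasters. All layers live in one projected equal-area CRS in
meters; a built-in synthetic-landscape generator produces every input with
the statistical structure the analysis assumes, so the whole pipeline runs
with no external data.

## What it computes

**Resource-use footprints.** Settlement lists are overlaid and cross-source
duplicates within a dedup radius collapsed; settlements coincident with
urban areas are dropped as not forest-dependent. For each resource class
(plant- or animal-based, over nine collection activities), the footprint
radius is the largest per-activity median of the community-to-site trip
distances `r_class = max_a median_i d(c_i, s_i^a)`, and every community
receives a disc footprint of that radius.

**Forest-loss accounting.** Forest available at year *y* inside a footprint
is baseline forest minus deforestation plots with conversion year ≤ *y*
(plots clipped to baseline forest; areas from polygon geometry, ha =
m²/10⁴). Relative loss is reported against the footprint's baseline-epoch
forest, so "lost more than 50% of the resource base" is literal.

**Ecosystem Services Supply Index.** Per pixel and year, over QA-valid NDVI
composites:

    ESSI = NDVI_mean × (1 − NDVI_CV)

where `NDVI_mean` proxies annual productivity and `NDVI_CV` (sample SD /
mean) its intra-annual instability. ESSI is min–max normalized to [0, 1]
jointly across epochs, then averaged over each footprint
(pixel-center-in-polygon inclusion).

**Access restrictions and water.** Demarcation-line density is weighted by
remaining forest: km of line per 100 km² of 2020 forest in the footprint,
with both epochs sharing the 2020 denominator. Water access is the
straight-line distance to the nearest source — seasonal or permanent water
pixels plus urban areas — with ties resolved urban > river > reservoir >
seasonal, and a permanent-natural-only variant (rivers/reservoirs,
urban excluded) compared between epochs.

**Change testing.** Each metric is compared between epochs per community
with a paired protocol: Shapiro–Wilk on the differences gates a paired
t-test (normal) vs the Wilcoxon signed-rank test (otherwise; exact null for
n ≤ 25), with significance stars *** p < 0.001, ** p < 0.01, * p < 0.05.
County-level summaries report mean ± SE.

## Worked example

```python
from forestuse.pipeline import PipelineConfig, run_pipeline, report
from forestuse.synthetic import LandscapeConfig

cfg = PipelineConfig(landscape=LandscapeConfig(
    extent=(0, 0, 100_000, 100_000), pixel_size=500,   # 200 × 200 pixels
    n_counties=4, n_communities=50, seed=1))
bundle = run_pipeline(cfg)
print(report(bundle))
```

prints (abridged):

```
communities: 53 merged, 3 urban-coincident removed, 50 retained
footprint radii: plant 8.6 km, animal 16.0 km
cumulative footprint area: plant 7017 km², animal 12719 km²
mean forest loss inside footprints: 4158.5 ha (10.4% relative); 0 footprints above 50% loss

Paired epoch tests (t1 vs t0)
------------------------------------------------------------
forest_area_ha                   plant    18859.432 ->  16922.634  [paired-t] p=1.36e-33 ***
essi_mean                        plant        0.849 ->      0.777  [paired-t] p=1.51e-37 ***
weighted_demarcation_density     plant        2.435 ->      7.534  [paired-t] p=8.7e-09 ***
permanent_natural_water_km       all          9.249 ->     10.105  [wilcoxon-signed-rank] p=0.036 *
```

Reading this: the generator drew 53 settlement records across two source
lists, 3 of which sat inside urban polygons; the plant-based footprint
radius recovered from the simulated trip distances is 8.6 km (the largest
per-activity median; the configured medians span 2–8 km, so the estimate
sits at the top of that range plus sampling noise). Between the two epochs
the mean footprint lost forest, ESSI declined, demarcation density roughly
tripled, and the nearest permanent natural water source moved almost 1 km
farther — each change significant under the paired protocol.

The same run is available from the shell:

```sh
forestuse run-all --seed 1 --outdir out/
# or stage by stage (resumable; identical outputs):
forestuse simulate --seed 1 --outdir out/
forestuse footprints --outdir out/
forestuse forest-change --outdir out/
forestuse essi --outdir out/
forestuse access --outdir out/
forestuse water --outdir out/
forestuse stats --outdir out/
```

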