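# Methods

This note documents the models, conventions and design choices behind the
package, in the order the pipeline applies them.

## Setting and coordinate conventions

All layers share one projected equal-area CRS in meters; areas are computed
from polygon geometry (ha = m²/10⁴, km² = m²/10⁶) and all distances are
planar Euclidean. Straight-line distances understate real travel (no roads,
barriers or terrain), so the access metrics are conservative by
construction. There is no reprojection machinery: inputs are expected in
the working CRS.

Raster georeferencing is north-up affine (origin + square pixel). The one
pixel-inclusion rule used everywhere is *pixel-center-in-polygon*, strict
on the boundary — deterministic and unambiguous, at the cost of ignoring
partial pixels (an area-weighting option was deliberately left out; at the
500 m analysis resolution against ≥ 8 km footprint radii the bias is
negligible).

## Community merging and footprints

Two settlement source lists are overlaid; a list-B record within the dedup
radius (default 1000 m — the duplicate criterion of real multi-source
settlement registries is rarely documented, and 1 km is below the typical
spacing of distinct rural settlements) of any list-A record is treated as a
duplicate and dropped, so list-A attributes win on conflict. The merge is
idempotent. Settlements inside (or on the boundary of) an urban polygon are
removed as not forest-dependent.

Nine collection activities are recognized, classed as plant-based (firewood
cutting, fruit gathering, charcoal production, carpentry, house
construction, handicraft making) or animal-based (hunting, fishing, honey
harvesting). The class footprint radius is the **maximum over the class's
activities of the per-activity median** community-to-site distance. The
plausible alternative — median over communities of each community's
farthest site — is available as `method="community_farthest"`; the default
was chosen because it reproduces the intended "encompass every activity's
median trip" logic directly from activity medians. Footprints are
64+-vertex disc polygons; cumulative footprint area uses the geometric
union, counting overlaps once.

## Forest-loss accounting

Baseline forest is a polygon layer; deforestation plots carry a conversion
year, and "converted by year *y*" is the closed condition `year ≤ y`. Plots
are clipped to baseline forest before subtraction, so conversion digitized
over non-forest never counts. Relative loss uses the footprint's
baseline-epoch forest as denominator (not total footprint area): both are
computable, but this choice makes a "> 50% of the resource base lost"
threshold literal. The accounting conserves area
(`forest_t0 = forest_t1 + loss`) and is monotone in added plots; both are
enforced by tests, and polygon areas agree with 10 m pixel counting within
the discretization bound.

## ESSI

Per pixel and year, over the QA-valid composites of an annual NDVI stack
(23 composites/yr, MODIS-like cadence):

* `NDVI_mean` — annual mean, a productivity proxy;
* `NDVI_CV` — sample SD (n − 1; the convention is stated nowhere
  authoritative, and the sample estimator is the safer default at n ≈ 20)
  divided by the mean;
* `ESSI = NDVI_mean × (1 − NDVI_CV)`.

A pixel is invalid when fewer than `min_composites` (default 10 of 23 —
half a year of observations, below which the CV estimate is unstable)
composites survive QA or when `NDVI_mean ≤ 0` (water/bare surfaces, where a
CV is meaningless). Raw ESSI may be negative when CV > 1; min–max
normalization to [0, 1] handles the range. Normalization bounds are
**joint across the epochs being compared**, so a change in normalized ESSI
is a change in the index, not in the scaling; per-epoch bounds are
available via `joint=False`. A degenerate (constant) raster normalizes to
zeros with a logged warning. Normalization preserves ordering, and for
fixed mean the index strictly decreases in CV.

## Access restrictions and water

Footprints not entirely inside the demarcation dataset's mapped extent are
excluded from the density analysis (their counts are logged), since a
partial footprint would understate density.

Weighted demarcation density is `100 × length_km / forest_2020_km²` within
the footprint — km of line per 100 km² of remaining forest. Both epochs
share the 2020 forest denominator: the earlier epoch's line stock is a
subset of the later one's by construction (lines inside later-converted
plots are unobservable in the earlier snapshot), so a shared denominator
makes the epoch contrast a pure line-accumulation signal and guarantees
`density_t1 ≥ density_t0`. The scale factor 100 is a reporting constant;
absolute density values are therefore comparable only within this package.
The epoch increase is summarized as the *new-line share*,
`100 × (L_t1 − L_t0)/L_t1`, bounded in [0, 100].

Nearest-water distance per community considers seasonal pixels, permanent
pixels typed river/reservoir (typing is an input attribute), and urban
polygons (piped supply; distance to the polygon, zero inside). Raster
sources are measured to pixel centers. Exact distance ties resolve by
urban > river > reservoir > seasonal — the priority runs from most to least
reliable supply. The epoch comparison of permanent *natural* water uses
rivers and reservoirs only; an epoch with no such source yields a flagged
missing distance rather than an error.

## Paired change testing

Each metric is paired per community across epochs. Normality of the paired
differences is assessed with Shapiro–Wilk at α = 0.05; a paired t-test is
used when normality is not rejected, the Wilcoxon signed-rank test
otherwise. Wilcoxon uses the exact null distribution for n ≤ 25 and the
normal approximation with continuity correction above; zero differences
are discarded (Wilcoxon's convention). All-zero differences take a
degenerate path (p = 1, "ns"). Homogeneity of variances, often quoted next
to normality checks, is not applicable to a paired design and plays no
role. "±" in summaries is the standard error of the mean (sample SD/√n;
SD is available as an option); a single-observation county reports SE 0
and is flagged. No multiple-testing correction is applied. Significance
stars: *** p < 0.001, ** p < 0.01, * p < 0.05.

## Synthetic landscape generator

The generator emulates the statistical structure of the real inputs, not
their geography:

* **Communities** — uniform points outside urban polygons; source list A
  carries all of them, list B duplicates a configured fraction (default
  25%) with sub-dedup-radius jitter; a few extra settlements are planted
  inside urban polygons to exercise the filter. Counties are equal
  vertical strips.
* **Collection sites** — per activity, log-normal trip distances (the
  natural right-skewed positive model when only medians are reported;
  median = configured, default σ of log = 0.5) with uniform bearings.
  Default medians: 2–8 km across the plant activities, 15 km for all three
  animal activities.
* **Forest and plots** — baseline forest is the extent minus urban and
  random non-forest patches (8%). Deforestation plots are axis-aligned
  rectangles with log-normal area (mean 77.0 ha, SD 30 ha), placed
  sequentially and rejected on overlap until each county reaches its
  configured converted fraction per epoch (defaults 5% by t0, +10% by t1);
  realized fractions track targets within ~2 percentage points.
* **NDVI** — 23 composites/yr from a per-cover sinusoid + N(0, 0.02)
  noise; forest is high-mean/low-amplitude (0.75/0.08), cropland
  lower-mean/high-amplitude (0.45/0.30), so conversion lowers ESSI by
  construction. QA flags drop 10% of observations at random. Pixels inside
  plots converted by an epoch use cropland phenology in that epoch.
* **Demarcations** — random straight segments (1–3 km) accepted only
  inside the remaining-2020-forest matrix of a mapped-extent rectangle
  (85% of the extent, so the coverage exclusion has work to do); the t0
  stock is a subset of the t1 stock, with years only appended.
* **Water** — wiggly west-east river polylines rasterized as permanent
  pixels, reservoir point pixels, a 0.3% seasonal background; in t1 a
  stretch of one river (default half) is demoted to seasonal, emulating
  drying reaches so permanent-water distances can grow.

All draws flow from one seed through per-layer child streams, so layers
are individually reproducible and runs are bit-identical. Epoch defaults
are 2001/2021, with demarcations referenced to 2020.

What the generator does **not** emulate: the geography of any real dry-forest region, MODIS
tiling/projection and QA bit semantics, spatial autocorrelation of NDVI
noise, non-rectangular plots, road networks, or water quality. Passing
tests therefore demonstrate correctness of the accounting, index algebra,
geometry and statistics under the assumed data structure — not calibration
to any real landscape.

## Problem sizes and determinism

The standard demonstration configuration is 50 communities on a
100 km × 100 km extent at 500 m pixels (200 × 200), two epochs — small
enough to run the full chain in seconds while leaving every code path
(merging, urban filtering, coverage exclusion, epoch demotion of water)
exercised. Property tests run oracles at reduced sizes (20 × 20 zonal
rasters, 10 m pixel-counting patches, n ≤ 10 enumeration for the exact
Wilcoxon null). Seeds are fixed in tests; stochastic assertions use
tolerances derived from sampling error (3–4 SE) rather than tuned margins.

## Known limitations

* Footprints are epoch-static discs; motorized travel or footprint drift
  over time is not modeled.
* Demarcation density is line length per remaining forest area; absolute
  values depend on the scale constant and are not comparable to other
  definitions of "weighted density".
* ESSI proxies a bundle of supporting services; it says nothing about
  cultural services or resource quality.
* County effects can leak across boundaries: a community's footprint
  extends up to its radius into neighboring counties, so per-county
  statistics attribute some neighbor-county change to the community's home
  county. This is a property of the footprint method itself, visible
  clearly in synthetic hotspot scenarios.
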