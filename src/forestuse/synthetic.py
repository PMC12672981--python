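"""Synthetic study-region generator.

Builds a complete landscape with the statistical structure the downstream
analysis assumes: two overlapping community source lists, activity-labelled
collection sites at log-normal trip distances, a baseline forest matrix,
dated deforestation plots with a configurable per-county conversion
fraction per epoch, MODIS-like annual NDVI composite stacks whose phenology
switches from forest to cropland upon conversion, dated demarcation lines
confined to the remaining forest of a mapped extent, per-epoch surface-water
class rasters with river/reservoir typing, and urban polygons.

Everything is driven by one seed; each layer draws from its own child
stream of the seed sequence, so layers are individually reproducible and
the full landscape is bit-identical across runs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import yaml
from shapely.geometry import LineString, Point, box
from shapely.prepared import prep

from .access import WaterLayer
from .activities import ACTIVITIES
from .georaster import DEFAULT_CRS, Raster
from .geovector import read_geojson, write_geojson

# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class ActivityParams:
    resource_class: str
    distance_median_km: float
    distance_dispersion: float = 0.5  # sigma of log distance
    sites_per_community: int = 2


@dataclass
class PhenologyParams:
    """Seasonal NDVI model for one land cover: level + sine seasonality."""

    mean: float
    amplitude: float
    n_composites: int = 23
    noise_sd: float = 0.02
    qa_dropout: float = 0.10


@dataclass
class DeforestationParams:
    #: fraction of county forest converted by t0 (scalar or per-county dict)
    fraction_by_t0: float | dict = 0.05
    #: additional fraction converted between t0 and t1
    fraction_t0_t1: float | dict = 0.10
    plot_mean_ha: float = 77.0
    plot_sd_ha: float = 30.0
    year_min: int = 1990


@dataclass
class DemarcationParams:
    total_km_t0: float = 150.0
    total_km_t1: float = 400.0  # includes the t0 stock
    segment_km: tuple[float, float] = (1.0, 3.0)
    year_min: int = 1990
    #: fraction of the extent side covered by the mapped-extent rectangle
    mapped_fraction: float = 0.85


@dataclass
class WaterParams:
    n_rivers: int = 2
    n_reservoirs: int = 3
    seasonal_fraction: float = 0.003
    #: fraction of the first river demoted from permanent to seasonal in t1
    demote_fraction: float = 0.5


@dataclass
class UrbanParams:
    n_polygons: int = 3
    size_range_m: tuple[float, float] = (1500.0, 4000.0)


def _default_activity_params() -> dict[str, ActivityParams]:
    return {
        name: ActivityParams(resource_class=cls, distance_median_km=median)
        for name, (cls, median) in ACTIVITIES.items()
    }


def _default_phenology() -> dict[str, PhenologyParams]:
    return {
        "forest": PhenologyParams(mean=0.75, amplitude=0.08),
        "cropland": PhenologyParams(mean=0.45, amplitude=0.30),
        "nonforest": PhenologyParams(mean=0.55, amplitude=0.18),
        "urban": PhenologyParams(mean=0.25, amplitude=0.05),
    }


@dataclass
class LandscapeConfig:
    extent: tuple[float, float, float, float] = (0.0, 0.0, 100_000.0, 100_000.0)
    pixel_size: float = 500.0
    n_counties: int = 4
    n_communities: int = 50
    #: fraction of communities present in both source lists (jittered in B)
    duplicate_fraction: float = 0.25
    #: extra settlements placed inside urban polygons (dropped by the filter)
    n_urban_communities: int = 3
    dedup_radius_m: float = 1000.0
    t0: int = 2001
    t1: int = 2021
    demarcation_t1: int = 2020
    nonforest_fraction: float = 0.08
    activity_params: dict[str, ActivityParams] = field(
        default_factory=_default_activity_params
    )
    ndvi_phenology: dict[str, PhenologyParams] = field(default_factory=_default_phenology)
    deforestation: DeforestationParams = field(default_factory=DeforestationParams)
    demarcation: DemarcationParams = field(default_factory=DemarcationParams)
    water: WaterParams = field(default_factory=WaterParams)
    urban: UrbanParams = field(default_factory=UrbanParams)
    seed: int = 0
    crs: str = DEFAULT_CRS

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.extent
        if x1 <= x0 or y1 <= y0:
            raise ValueError("extent must have positive width and height")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.n_counties < 1 or self.n_communities < 1:
            raise ValueError("counts must be positive")
        if not 0 <= self.duplicate_fraction <= 1:
            raise ValueError("duplicate_fraction must be in [0, 1]")
        if self.t0 >= self.t1:
            raise ValueError("t0 must precede t1")
        for name, ap in self.activity_params.items():
            if ap.distance_median_km <= 0:
                raise ValueError(f"distance median for {name!r} must be positive")
        for frac in (self.deforestation.fraction_by_t0, self.deforestation.fraction_t0_t1):
            vals = frac.values() if isinstance(frac, dict) else [frac]
            if any(not 0 <= v <= 1 for v in vals):
                raise ValueError("conversion fractions must lie in [0, 1]")

    # -- (de)serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "LandscapeConfig":
        d = dict(d)
        if "activity_params" in d:
            d["activity_params"] = {
                k: ActivityParams(**v) if isinstance(v, dict) else v
                for k, v in d["activity_params"].items()
            }
        if "ndvi_phenology" in d:
            d["ndvi_phenology"] = {
                k: PhenologyParams(**v) if isinstance(v, dict) else v
                for k, v in d["ndvi_phenology"].items()
            }
        for key, sub in (
            ("deforestation", DeforestationParams),
            ("demarcation", DemarcationParams),
            ("water", WaterParams),
            ("urban", UrbanParams),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        for key in ("extent",):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "LandscapeConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def _per_county(value: float | dict, county: str) -> float:
    if isinstance(value, dict):
        return float(value.get(county, value.get("default", 0.0)))
    return float(value)


# ---------------------------------------------------------------------------
# landscape container
# ---------------------------------------------------------------------------


@dataclass
class SyntheticLandscape:
    config: LandscapeConfig
    county_polygons: pd.DataFrame
    urban_polygons: pd.DataFrame
    communities_a: pd.DataFrame
    communities_b: pd.DataFrame
    collection_sites: pd.DataFrame
    forest_polygon: shapely.Geometry
    forest_mask: Raster
    deforestation_plots: pd.DataFrame
    ndvi_stacks: dict[int, Raster]
    qa_stacks: dict[int, Raster]
    demarcation_lines: pd.DataFrame
    mapped_extent: shapely.Geometry
    water_layers: dict[int, WaterLayer]
    water_features: pd.DataFrame

    @property
    def epochs(self) -> tuple[int, int]:
        return self.config.t0, self.config.t1


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def generate_landscape(config: LandscapeConfig) -> SyntheticLandscape:
    """Generate every layer of a synthetic study region.

    Collection-site distances per activity are log-normal with the
    configured median; NDVI phenology over converted pixels switches to the
    cropland model from the conversion epoch onward; demarcation lines lie
    only within the remaining forest of the mapped extent.
    """
    streams = np.random.SeedSequence(config.seed).spawn(8)
    rng_urban = np.random.default_rng(streams[0])
    rng_comm = np.random.default_rng(streams[1])
    rng_sites = np.random.default_rng(streams[2])
    rng_forest = np.random.default_rng(streams[3])
    rng_plots = np.random.default_rng(streams[4])
    rng_ndvi = np.random.default_rng(streams[5])
    rng_demarc = np.random.default_rng(streams[6])
    rng_water = np.random.default_rng(streams[7])

    x0, y0, x1, y1 = config.extent
    extent_box = box(x0, y0, x1, y1)

    counties = _make_counties(config)
    urban = _make_urban(config, rng_urban)
    urban_union = shapely.union_all(list(urban["geometry"])) if len(urban) else None

    comm_a, comm_b, master = _make_communities(config, counties, urban, rng_comm)
    sites = _make_sites(config, master, rng_sites)

    forest_polygon = _make_forest(config, extent_box, urban_union, rng_forest)
    grid = _empty_grid(config)
    forest_mask = grid.like(
        grid.geometry_mask(forest_polygon).astype(np.uint8),
        band_labels=["forest"],
    )

    plots = _make_plots(config, counties, forest_polygon, rng_plots)
    converted_t0 = _rasterize_plots(grid, plots, config.t0)
    converted_t1 = _rasterize_plots(grid, plots, config.t1)

    urban_mask = (
        grid.geometry_mask(urban_union) if urban_union is not None else
        np.zeros((grid.n_rows, grid.n_cols), bool)
    )
    forest_bool = forest_mask.data.astype(bool)
    ndvi_stacks, qa_stacks = {}, {}
    for year, converted in ((config.t0, converted_t0), (config.t1, converted_t1)):
        nd, qa = _make_ndvi(config, forest_bool, urban_mask, converted, year, rng_ndvi)
        ndvi_stacks[year] = grid.like(nd, band_labels=_composite_labels(config, year))
        qa_stacks[year] = grid.like(qa, band_labels=_composite_labels(config, year))

    mapped_extent = _make_mapped_extent(config)
    forest_2020 = forest_polygon.difference(
        shapely.union_all(
            list(plots.loc[plots["year"] <= config.demarcation_t1, "geometry"])
        )
        if len(plots)
        else shapely.Polygon()
    )
    lines = _make_demarcations(config, mapped_extent, forest_2020, rng_demarc)

    water_layers, water_features = _make_water(config, grid, urban, rng_water)

    return SyntheticLandscape(
        config=config,
        county_polygons=counties,
        urban_polygons=urban,
        communities_a=comm_a,
        communities_b=comm_b,
        collection_sites=sites,
        forest_polygon=forest_polygon,
        forest_mask=forest_mask,
        deforestation_plots=plots,
        ndvi_stacks=ndvi_stacks,
        qa_stacks=qa_stacks,
        demarcation_lines=lines,
        mapped_extent=mapped_extent,
        water_layers=water_layers,
        water_features=water_features,
    )


def _empty_grid(config: LandscapeConfig) -> Raster:
    x0, y0, x1, y1 = config.extent
    n_cols = int(round((x1 - x0) / config.pixel_size))
    n_rows = int(round((y1 - y0) / config.pixel_size))
    if n_cols < 1 or n_rows < 1:
        raise ValueError("extent smaller than one pixel")
    return Raster(
        np.zeros((n_rows, n_cols), np.uint8), x0, y1, config.pixel_size, crs=config.crs
    )


def _make_counties(config: LandscapeConfig) -> pd.DataFrame:
    """Vertical strips of equal width, named county01.. from west to east."""
    x0, y0, x1, y1 = config.extent
    width = (x1 - x0) / config.n_counties
    rows = []
    for i in range(config.n_counties):
        rows.append(
            {
                "county": f"county{i + 1:02d}",
                "geometry": box(x0 + i * width, y0, x0 + (i + 1) * width, y1),
            }
        )
    return pd.DataFrame(rows)


def _make_urban(config: LandscapeConfig, rng: np.random.Generator) -> pd.DataFrame:
    x0, y0, x1, y1 = config.extent
    lo, hi = config.urban.size_range_m
    rows = []
    for i in range(config.urban.n_polygons):
        s = rng.uniform(lo, hi)
        cx = rng.uniform(x0 + s, x1 - s)
        cy = rng.uniform(y0 + s, y1 - s)
        rows.append(
            {"id": f"urb{i + 1:02d}", "geometry": box(cx - s / 2, cy - s / 2, cx + s / 2, cy + s / 2)}
        )
    return pd.DataFrame(rows) if rows else pd.DataFrame(columns=["id", "geometry"])


_ETHNIC_GROUPS = ["wichi", "guarani", "kolla", "chorote", "qom", None]


def _assign_county(pt: Point, counties: pd.DataFrame) -> str:
    for _, row in counties.iterrows():
        if shapely.intersects(row["geometry"], pt):
            return row["county"]
    return counties.iloc[-1]["county"]


def _make_communities(
    config: LandscapeConfig,
    counties: pd.DataFrame,
    urban: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Master settlements plus the two overlapping source lists.

    Source A carries every settlement (master ids); source B duplicates a
    configured fraction of them with sub-dedup-radius jitter, so the merge
    step has real work to do.  A few extra settlements are planted inside
    urban polygons to exercise the urban filter.
    """
    x0, y0, x1, y1 = config.extent
    urban_union = shapely.union_all(list(urban["geometry"])) if len(urban) else None

    pts: list[Point] = []
    while len(pts) < config.n_communities:
        p = Point(rng.uniform(x0, x1), rng.uniform(y0, y1))
        if urban_union is not None and shapely.intersects(urban_union, p):
            continue
        pts.append(p)

    master_rows = []
    for i, p in enumerate(pts):
        master_rows.append(
            {
                "id": f"cm{i + 1:04d}",
                "county": _assign_county(p, counties),
                "ethnic_group": _ETHNIC_GROUPS[rng.integers(len(_ETHNIC_GROUPS))],
                "source": "list_a",
                "geometry": p,
            }
        )
    # settlements coincident with urban areas (to be filtered out downstream)
    for j in range(config.n_urban_communities):
        if not len(urban):
            break
        poly = urban.iloc[int(rng.integers(len(urban)))]["geometry"]
        ux0, uy0, ux1, uy1 = poly.bounds
        p = Point(rng.uniform(ux0, ux1), rng.uniform(uy0, uy1))
        master_rows.append(
            {
                "id": f"cu{j + 1:04d}",
                "county": _assign_county(p, counties),
                "ethnic_group": None,
                "source": "list_a",
                "geometry": p,
            }
        )
    comm_a = pd.DataFrame(master_rows)
    master = comm_a[comm_a["id"].str.startswith("cm")].copy()

    n_dup = int(round(config.duplicate_fraction * config.n_communities))
    dup_idx = rng.choice(config.n_communities, size=n_dup, replace=False)
    b_rows = []
    for k, idx in enumerate(sorted(dup_idx)):
        base = comm_a.iloc[int(idx)]
        r = rng.uniform(0, 0.4 * config.dedup_radius_m)
        theta = rng.uniform(0, 2 * np.pi)
        p = Point(base["geometry"].x + r * np.cos(theta), base["geometry"].y + r * np.sin(theta))
        b_rows.append(
            {
                "id": f"cb{k + 1:04d}",
                "county": base["county"],
                "ethnic_group": base["ethnic_group"],
                "source": "list_b",
                "geometry": p,
            }
        )
    comm_b = pd.DataFrame(b_rows) if b_rows else pd.DataFrame(
        columns=["id", "county", "ethnic_group", "source", "geometry"]
    )
    return comm_a, comm_b, master


def _make_sites(
    config: LandscapeConfig, master: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Collection sites: log-normal trip distance, uniform bearing."""
    rows = []
    for _, comm in master.iterrows():
        cx, cy = comm["geometry"].x, comm["geometry"].y
        for activity, ap in config.activity_params.items():
            for _ in range(ap.sites_per_community):
                d_m = ap.distance_median_km * 1000.0 * np.exp(
                    ap.distance_dispersion * rng.standard_normal()
                )
                theta = rng.uniform(0, 2 * np.pi)
                rows.append(
                    {
                        "community_id": comm["id"],
                        "activity": activity,
                        "resource_class": ap.resource_class,
                        "geometry": Point(cx + d_m * np.cos(theta), cy + d_m * np.sin(theta)),
                    }
                )
    return pd.DataFrame(rows)


def _make_forest(
    config: LandscapeConfig,
    extent_box,
    urban_union,
    rng: np.random.Generator,
) -> shapely.Geometry:
    """Baseline forest = extent minus urban minus random non-forest patches."""
    x0, y0, x1, y1 = config.extent
    total = extent_box.area
    target = config.nonforest_fraction * total
    holes = []
    carved = 0.0
    while carved < target:
        s = rng.uniform(2000.0, 6000.0)
        cx, cy = rng.uniform(x0, x1), rng.uniform(y0, y1)
        patch = box(cx - s / 2, cy - s / 2, cx + s / 2, cy + s / 2).intersection(extent_box)
        holes.append(patch)
        carved += patch.area
    cut = shapely.union_all(holes + ([urban_union] if urban_union is not None else []))
    return extent_box.difference(cut)


def _sample_plot(
    rng: np.random.Generator, mean_ha: float, sd_ha: float, cx: float, cy: float
):
    """Axis-aligned rectangular plot with log-normal area (given mean/sd in ha)."""
    sigma2 = np.log(1.0 + (sd_ha / mean_ha) ** 2)
    mu = np.log(mean_ha) - sigma2 / 2.0
    area_m2 = np.exp(rng.normal(mu, np.sqrt(sigma2))) * 1e4
    aspect = np.exp(rng.uniform(np.log(0.5), np.log(2.0)))
    w = np.sqrt(area_m2 * aspect)
    h = area_m2 / w
    return box(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2)


def _make_plots(
    config: LandscapeConfig,
    counties: pd.DataFrame,
    forest_polygon,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Sequentially place non-overlapping plots per county until each
    epoch's conversion-fraction target of county forest area is met.

    Overlap rejection uses a fine bookkeeping grid (250 m), so accepted
    plots are pairwise (near-)disjoint and the accepted-area sum tracks the
    realized converted area."""
    d = config.deforestation
    x0, y0, x1, y1 = config.extent
    book_res = 250.0
    nbx = int(np.ceil((x1 - x0) / book_res))
    nby = int(np.ceil((y1 - y0) / book_res))
    occupied = np.zeros((nby, nbx), bool)
    prep_forest = prep(forest_polygon)

    rows = []
    plot_id = 0
    for _, crow in counties.iterrows():
        county, cgeom = crow["county"], crow["geometry"]
        county_forest_area = forest_polygon.intersection(cgeom).area
        cx0, cy0, cx1, cy1 = cgeom.bounds
        for epoch_key, ylo, yhi in (
            ("t0", d.year_min, config.t0),
            ("t1", config.t0 + 1, config.t1),
        ):
            frac = _per_county(
                d.fraction_by_t0 if epoch_key == "t0" else d.fraction_t0_t1, county
            )
            target = frac * county_forest_area
            placed = 0.0
            attempts = 0
            max_attempts = 20000
            while placed < target and attempts < max_attempts:
                attempts += 1
                cx, cy = rng.uniform(cx0, cx1), rng.uniform(cy0, cy1)
                if not prep_forest.contains(Point(cx, cy)):
                    continue
                plot = _sample_plot(rng, d.plot_mean_ha, d.plot_sd_ha, cx, cy)
                px0, py0, px1, py1 = plot.bounds
                i0 = max(0, int((py0 - y0) / book_res))
                i1 = min(nby, int(np.ceil((py1 - y0) / book_res)))
                j0 = max(0, int((px0 - x0) / book_res))
                j1 = min(nbx, int(np.ceil((px1 - x0) / book_res)))
                if occupied[i0:i1, j0:j1].any():
                    continue
                clipped = plot.intersection(cgeom).intersection(forest_polygon)
                if clipped.area < 0.5 * plot.area:
                    continue
                occupied[i0:i1, j0:j1] = True
                plot_id += 1
                rows.append(
                    {
                        "id": f"plot{plot_id:05d}",
                        "county": county,
                        "year": int(rng.integers(ylo, yhi + 1)),
                        "geometry": plot,
                    }
                )
                placed += clipped.area
    return pd.DataFrame(rows) if rows else pd.DataFrame(
        columns=["id", "county", "year", "geometry"]
    )


def _rasterize_plots(grid: Raster, plots: pd.DataFrame, year: int) -> np.ndarray:
    """Pixel-center-in-plot mask of plots converted by ``year`` (closed)."""
    mask = np.zeros((grid.n_rows, grid.n_cols), bool)
    if not len(plots):
        return mask
    sel = plots[plots["year"] <= year]
    if not len(sel):
        return mask
    union = shapely.union_all(list(sel["geometry"]))
    return grid.geometry_mask(union)


def _composite_labels(config: LandscapeConfig, year: int) -> list[str]:
    n = next(iter(config.ndvi_phenology.values())).n_composites
    doys = np.linspace(1, 365, n).round().astype(int)
    return [f"{year}-{d:03d}" for d in doys]


def _make_ndvi(
    config: LandscapeConfig,
    forest_mask: np.ndarray,
    urban_mask: np.ndarray,
    converted_mask: np.ndarray,
    year: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One epoch's NDVI + QA stack from the per-cover seasonal model."""
    phen = config.ndvi_phenology
    n = phen["forest"].n_composites
    rows, cols = forest_mask.shape

    cover = np.full((rows, cols), 2, np.uint8)  # 2 = nonforest matrix
    cover[forest_mask] = 0  # forest
    cover[converted_mask & forest_mask] = 1  # cropland
    cover[urban_mask] = 3  # urban

    keys = ["forest", "cropland", "nonforest", "urban"]
    means = np.array([phen[k].mean for k in keys])[cover]
    amps = np.array([phen[k].amplitude for k in keys])[cover]
    noise_sd = np.array([phen[k].noise_sd for k in keys])[cover]
    qa_drop = np.array([phen[k].qa_dropout for k in keys])[cover]

    t = (np.arange(n) + 0.5) / n
    season = np.sin(2 * np.pi * t - np.pi / 2)  # trough at start/end of year
    ndvi = means[None] + amps[None] * season[:, None, None]
    ndvi = ndvi + rng.standard_normal(ndvi.shape) * noise_sd[None]
    ndvi = np.clip(ndvi, -1.0, 1.0).astype(np.float32)
    qa = (rng.random(ndvi.shape) >= qa_drop[None]).astype(np.uint8)
    return ndvi, qa


def _make_mapped_extent(config: LandscapeConfig):
    x0, y0, x1, y1 = config.extent
    f = config.demarcation.mapped_fraction
    w, h = (x1 - x0) * f, (y1 - y0) * f
    return box(x0, y0, x0 + w, y0 + h)


def _make_demarcations(
    config: LandscapeConfig,
    mapped_extent,
    forest_2020,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Random straight segments, accepted only when fully inside the
    remaining-forest matrix of the mapped extent; the t0 stock is a subset
    of the t1 stock by construction (years only appended)."""
    dm = config.demarcation
    allowed = mapped_extent.intersection(forest_2020)
    prep_allowed = prep(allowed)
    mx0, my0, mx1, my1 = mapped_extent.bounds

    rows = []
    line_id = 0

    def _place(target_km: float, ylo: int, yhi: int, start_km: float) -> float:
        nonlocal line_id
        total = start_km
        attempts = 0
        while total < target_km and attempts < 50000:
            attempts += 1
            cx, cy = rng.uniform(mx0, mx1), rng.uniform(my0, my1)
            length_m = rng.uniform(*dm.segment_km) * 1000.0
            theta = rng.uniform(0, np.pi)
            dx, dy = np.cos(theta) * length_m / 2, np.sin(theta) * length_m / 2
            seg = LineString([(cx - dx, cy - dy), (cx + dx, cy + dy)])
            if not prep_allowed.contains(seg):
                continue
            line_id += 1
            rows.append(
                {
                    "id": f"dem{line_id:05d}",
                    "year": int(rng.integers(ylo, yhi + 1)),
                    "geometry": seg,
                }
            )
            total += length_m / 1000.0
        return total

    placed_t0 = _place(dm.total_km_t0, dm.year_min, config.t0, 0.0)
    _place(dm.total_km_t1, config.t0 + 1, config.demarcation_t1, placed_t0)
    return pd.DataFrame(rows) if rows else pd.DataFrame(columns=["id", "year", "geometry"])


def _make_water(
    config: LandscapeConfig,
    grid: Raster,
    urban: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[dict[int, WaterLayer], pd.DataFrame]:
    """Per-epoch water-class rasters + the typed source features.

    Rivers are wiggly west-east polylines rasterized as permanent pixels;
    reservoirs are single permanent pixels; a background fraction of pixels
    is seasonal.  In t1 a configurable stretch of the first river is demoted
    from permanent to seasonal, emulating drying of river reaches."""
    w = config.water
    x0, y0, x1, y1 = config.extent
    rows, cols = grid.n_rows, grid.n_cols

    feat_rows = []
    river_pixels: list[np.ndarray] = []
    for i in range(w.n_rivers):
        n_pts = 6
        xs = np.linspace(x0, x1, n_pts)
        ys = rng.uniform(y0 + 0.1 * (y1 - y0), y1 - 0.1 * (y1 - y0), n_pts)
        line = LineString(np.column_stack([xs, ys]))
        feat_rows.append({"id": f"riv{i + 1:02d}", "water_type": "river", "geometry": line})
        # rasterize by dense sampling along the line
        dists = np.arange(0, line.length, grid.pixel_size / 2.0)
        pts = [line.interpolate(d) for d in dists]
        rc = np.array([grid.xy_to_rowcol(p.x, p.y) for p in pts])
        rc = rc[(rc[:, 0] >= 0) & (rc[:, 0] < rows) & (rc[:, 1] >= 0) & (rc[:, 1] < cols)]
        river_pixels.append(np.unique(rc, axis=0))

    reservoir_pixels = []
    for i in range(w.n_reservoirs):
        px = rng.uniform(x0, x1)
        py = rng.uniform(y0, y1)
        feat_rows.append(
            {"id": f"res{i + 1:02d}", "water_type": "reservoir", "geometry": Point(px, py)}
        )
        reservoir_pixels.append(grid.xy_to_rowcol(px, py))

    base_class = np.zeros((rows, cols), np.uint8)  # 0 none, 1 seasonal, 2 permanent
    base_type = np.zeros((rows, cols), np.uint8)  # 0 none, 1 river, 2 reservoir
    seasonal = rng.random((rows, cols)) < w.seasonal_fraction
    base_class[seasonal] = 1
    for rc in river_pixels:
        base_class[rc[:, 0], rc[:, 1]] = 2
        base_type[rc[:, 0], rc[:, 1]] = 1
    for r, c in reservoir_pixels:
        if 0 <= r < rows and 0 <= c < cols:
            base_class[r, c] = 2
            base_type[r, c] = 2

    class_t1 = base_class.copy()
    type_t1 = base_type.copy()
    if w.n_rivers and w.demote_fraction > 0:
        rc = river_pixels[0]
        k = int(round(w.demote_fraction * len(rc)))
        order = np.argsort(rc[:, 1])  # demote the western stretch
        demote = rc[order[:k]]
        class_t1[demote[:, 0], demote[:, 1]] = 1
        type_t1[demote[:, 0], demote[:, 1]] = 0

    layers = {
        config.t0: WaterLayer(
            epoch=config.t0,
            class_raster=grid.like(base_class, band_labels=["water_class"]),
            type_raster=grid.like(base_type, band_labels=["water_type"]),
            urban_polygons=urban,
        ),
        config.t1: WaterLayer(
            epoch=config.t1,
            class_raster=grid.like(class_t1, band_labels=["water_class"]),
            type_raster=grid.like(type_t1, band_labels=["water_type"]),
            urban_polygons=urban,
        ),
    }
    return layers, pd.DataFrame(feat_rows)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def write_landscape(landscape: SyntheticLandscape, directory: str | Path) -> None:
    """Write every layer (GeoTIFF rasters, GeoJSON vectors) plus a manifest
    echoing the seed and full configuration."""
    directory = Path(directory)
    if not directory.parent.exists():
        raise FileNotFoundError(f"no such directory: {directory.parent}")
    directory.mkdir(exist_ok=True)
    cfg = landscape.config

    write_geojson(landscape.county_polygons, directory / "counties.geojson", cfg.crs)
    write_geojson(landscape.urban_polygons, directory / "urban.geojson", cfg.crs)
    write_geojson(landscape.communities_a, directory / "communities_a.geojson", cfg.crs)
    write_geojson(landscape.communities_b, directory / "communities_b.geojson", cfg.crs)
    write_geojson(landscape.collection_sites, directory / "collection_sites.geojson", cfg.crs)
    write_geojson(
        landscape.deforestation_plots, directory / "deforestation_plots.geojson", cfg.crs
    )
    write_geojson(landscape.demarcation_lines, directory / "demarcation_lines.geojson", cfg.crs)
    write_geojson(
        pd.DataFrame([{"id": "mapped_extent", "geometry": landscape.mapped_extent}]),
        directory / "mapped_extent.geojson",
        cfg.crs,
    )
    write_geojson(
        pd.DataFrame([{"id": "forest", "geometry": landscape.forest_polygon}]),
        directory / "forest_polygon.geojson",
        cfg.crs,
    )
    write_geojson(landscape.water_features, directory / "water_features.geojson", cfg.crs)

    landscape.forest_mask.write(directory / "forest_mask.tif")
    for year, r in landscape.ndvi_stacks.items():
        r.write(directory / f"ndvi_{year}.tif")
    for year, r in landscape.qa_stacks.items():
        r.write(directory / f"qa_{year}.tif")
    for year, wl in landscape.water_layers.items():
        wl.class_raster.write(directory / f"water_class_{year}.tif")
        wl.type_raster.write(directory / f"water_type_{year}.tif")

    manifest = {"seed": cfg.seed, "config": cfg.to_dict()}
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_landscape(directory: str | Path) -> SyntheticLandscape:
    """Reload a landscape written by :func:`write_landscape`."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    config = LandscapeConfig.from_dict(manifest["config"])

    urban = read_geojson(directory / "urban.geojson")
    ndvi_stacks = {
        y: Raster.read(directory / f"ndvi_{y}.tif") for y in (config.t0, config.t1)
    }
    qa_stacks = {y: Raster.read(directory / f"qa_{y}.tif") for y in (config.t0, config.t1)}
    water_layers = {
        y: WaterLayer(
            epoch=y,
            class_raster=Raster.read(directory / f"water_class_{y}.tif"),
            type_raster=Raster.read(directory / f"water_type_{y}.tif"),
            urban_polygons=urban,
        )
        for y in (config.t0, config.t1)
    }
    return SyntheticLandscape(
        config=config,
        county_polygons=read_geojson(directory / "counties.geojson"),
        urban_polygons=urban,
        communities_a=read_geojson(directory / "communities_a.geojson"),
        communities_b=read_geojson(directory / "communities_b.geojson"),
        collection_sites=read_geojson(directory / "collection_sites.geojson"),
        forest_polygon=read_geojson(directory / "forest_polygon.geojson").iloc[0]["geometry"],
        forest_mask=Raster.read(directory / "forest_mask.tif"),
        deforestation_plots=read_geojson(directory / "deforestation_plots.geojson"),
        ndvi_stacks=ndvi_stacks,
        qa_stacks=qa_stacks,
        demarcation_lines=read_geojson(directory / "demarcation_lines.geojson"),
        mapped_extent=read_geojson(directory / "mapped_extent.geojson").iloc[0]["geometry"],
        water_layers=water_layers,
        water_features=read_geojson(directory / "water_features.geojson"),
    )
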