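"""End-to-end orchestration: simulate → footprints → forest change → ESSI →
access/water → paired statistics, with CSV/GeoJSON outputs and a manifest.

Every stage is a pure function of the landscape and the upstream tables, so
stages can be re-run individually from a written output directory and a
resumed run reproduces a fresh run bit-for-bit (all randomness lives in the
landscape generator, which is seed-driven).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import yaml

from . import __version__
from .access import (
    ALL_SOURCE_TYPES,
    access_table,
    distance_threshold_counts,
    filter_mapped_coverage,
    nearest_water_table,
    permanent_water_change,
)
from .activities import ANIMAL, PLANT
from .changestats import county_summary, paired_summary_table
from .communities import (
    activity_medians,
    build_footprints,
    cumulative_footprint_area,
    estimate_class_radius,
    filter_urban,
    merge_community_sources,
)
from .essi import annual_phenology, essi_raw, normalize_essi, zonal_mean
from .forest import count_above_threshold, loss_table
from .geovector import write_geojson
from .synthetic import (
    LandscapeConfig,
    SyntheticLandscape,
    generate_landscape,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    #: footprint radii: "auto" (estimate from collection sites) or km
    plant_radius_km: float | str = "auto"
    animal_radius_km: float | str = "auto"
    radius_method: str = "activity_median"
    loss_threshold_pct: float = 50.0
    water_thresholds_km: tuple[float, float] = (2.0, 10.0)
    normality_alpha: float = 0.05
    min_composites: int = 10
    joint_normalization: bool = True
    density_scale: float = 100.0

    def __post_init__(self) -> None:
        for r in (self.plant_radius_km, self.animal_radius_km):
            if r != "auto" and (not isinstance(r, (int, float)) or r <= 0):
                raise ValueError("fixed radii must be positive numbers")
        if not 0 <= self.loss_threshold_pct <= 100:
            raise ValueError("loss threshold must be in [0, 100]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "landscape" in d and isinstance(d["landscape"], dict):
            d["landscape"] = LandscapeConfig.from_dict(d["landscape"])
        if "water_thresholds_km" in d and isinstance(d["water_thresholds_km"], list):
            d["water_thresholds_km"] = tuple(d["water_thresholds_km"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_footprints(
    landscape: SyntheticLandscape, config: PipelineConfig
) -> dict:
    """Merge sources, drop urban-coincident settlements, estimate radii,
    and build per-class footprints."""
    cfg = landscape.config
    merged = merge_community_sources(
        landscape.communities_a, landscape.communities_b, cfg.dedup_radius_m
    )
    communities = filter_urban(merged, landscape.urban_polygons)
    # collection sites may reference urban-filtered settlements; keep linked ones
    sites = landscape.collection_sites
    sites = sites[sites["community_id"].isin(set(communities["id"]))].reset_index(drop=True)

    radii = {}
    for cls_name, setting in ((PLANT, config.plant_radius_km), (ANIMAL, config.animal_radius_km)):
        if setting == "auto":
            radii[cls_name] = estimate_class_radius(
                sites, communities, cls_name, method=config.radius_method
            )
        else:
            radii[cls_name] = float(setting)

    footprints = pd.concat(
        [build_footprints(communities, radii[c], c) for c in (PLANT, ANIMAL)],
        ignore_index=True,
    )
    medians = activity_medians(sites, communities)
    cumulative = {
        c: cumulative_footprint_area(footprints[footprints["resource_class"] == c])
        for c in (PLANT, ANIMAL)
    }
    return {
        "communities": communities,
        "n_merged": len(merged),
        "n_urban_filtered": len(merged) - len(communities),
        "collection_sites": sites,
        "activity_medians": medians,
        "radii_km": radii,
        "footprints": footprints,
        "cumulative_area_km2": cumulative,
    }


def stage_forest_change(
    landscape: SyntheticLandscape, footprints: pd.DataFrame, config: PipelineConfig
) -> dict:
    cfg = landscape.config
    losses = loss_table(
        footprints, landscape.forest_polygon, landscape.deforestation_plots, cfg.t0, cfg.t1
    )
    n_above = count_above_threshold(losses, config.loss_threshold_pct)
    # forest standing at the demarcation reference year, density denominator
    losses_2020 = loss_table(
        footprints, landscape.forest_polygon, landscape.deforestation_plots,
        cfg.t0, cfg.demarcation_t1,
    )
    forest_2020_km2 = (
        losses_2020.set_index(["community_id", "resource_class"])["forest_area_t1_ha"]
        / 100.0
    )
    return {
        "forest_loss": losses,
        "n_above_threshold": n_above,
        "forest_2020_km2": forest_2020_km2,
    }


def stage_essi(
    landscape: SyntheticLandscape, footprints: pd.DataFrame, config: PipelineConfig
) -> dict:
    cfg = landscape.config
    layers = []
    for year in (cfg.t0, cfg.t1):
        phen = annual_phenology(
            landscape.ndvi_stacks[year],
            landscape.qa_stacks[year],
            year,
            min_composites=config.min_composites,
        )
        layers.append(essi_raw(phen))
    norm_layers = normalize_essi(layers, joint=config.joint_normalization)
    by_year = {layer.year: layer for layer in norm_layers}

    rows = []
    for _, fp in footprints.iterrows():
        vals = {y: zonal_mean(by_year[y], fp["geometry"]) for y in (cfg.t0, cfg.t1)}
        v0, v1 = vals[cfg.t0], vals[cfg.t1]
        rel = 100.0 * (v1 - v0) / v0 if v0 and np.isfinite(v0) and v0 > 0 else np.nan
        rows.append(
            {
                "community_id": fp["community_id"],
                "county": fp.get("county"),
                "resource_class": fp["resource_class"],
                "essi_t0": v0,
                "essi_t1": v1,
                "change_rel_pct": rel,
            }
        )
    return {"essi_layers": by_year, "essi_zonal": pd.DataFrame(rows)}


def stage_access(
    landscape: SyntheticLandscape,
    footprints: pd.DataFrame,
    forest_2020_km2: pd.Series,
    config: PipelineConfig,
) -> dict:
    cfg = landscape.config
    included, excluded = filter_mapped_coverage(footprints, landscape.mapped_extent)
    per_class_forest = forest_2020_km2.copy()
    tables = []
    for cls_name in (PLANT, ANIMAL):
        fps = included[included["resource_class"] == cls_name]
        if not len(fps):
            continue
        forest = per_class_forest.xs(cls_name, level="resource_class")
        tables.append(
            access_table(
                fps,
                landscape.demarcation_lines,
                forest,
                cfg.t0,
                cfg.demarcation_t1,
                density_scale=config.density_scale,
            )
        )
    access = (
        pd.concat(tables, ignore_index=True)
        if tables
        else pd.DataFrame()
    )
    return {
        "access": access,
        "n_coverage_excluded": len(excluded),
        "excluded_ids": sorted(set(excluded["community_id"])) if len(excluded) else [],
    }


def stage_water(
    landscape: SyntheticLandscape, communities: pd.DataFrame, config: PipelineConfig
) -> dict:
    cfg = landscape.config
    w1 = landscape.water_layers[cfg.t1]
    nearest = nearest_water_table(communities, w1, ALL_SOURCE_TYPES)
    perm = permanent_water_change(
        communities, landscape.water_layers[cfg.t0], landscape.water_layers[cfg.t1]
    )
    water = nearest.merge(
        perm.drop(columns=[c for c in ("county",) if c in perm]), on="community_id"
    )
    counts = distance_threshold_counts(
        water["nearest_distance_km"], list(config.water_thresholds_km)
    )
    return {"water": water, "threshold_counts": counts}


def stage_stats(bundle: dict, config: PipelineConfig) -> dict:
    """Paired epoch tests and county summaries over the upstream tables."""
    losses = bundle["forest_loss"]
    essi_z = bundle["essi_zonal"]
    access = bundle["access"]
    water = bundle["water"]

    samples = []
    for cls_name in (PLANT, ANIMAL):
        sel = losses[losses["resource_class"] == cls_name]
        samples.append(
            {
                "metric": "forest_area_ha",
                "resource_class": cls_name,
                "values_t0": sel["forest_area_t0_ha"].to_numpy(),
                "values_t1": sel["forest_area_t1_ha"].to_numpy(),
            }
        )
        sel = essi_z[essi_z["resource_class"] == cls_name]
        samples.append(
            {
                "metric": "essi_mean",
                "resource_class": cls_name,
                "values_t0": sel["essi_t0"].to_numpy(),
                "values_t1": sel["essi_t1"].to_numpy(),
            }
        )
        if len(access):
            sel = access[access["resource_class"] == cls_name]
            samples.append(
                {
                    "metric": "weighted_demarcation_density",
                    "resource_class": cls_name,
                    "values_t0": sel["density_t0"].to_numpy(),
                    "values_t1": sel["density_t1"].to_numpy(),
                }
            )
    samples.append(
        {
            "metric": "permanent_natural_water_km",
            "resource_class": "all",
            "values_t0": water["permanent_natural_distance_t0_km"].to_numpy(),
            "values_t1": water["permanent_natural_distance_t1_km"].to_numpy(),
        }
    )
    paired = paired_summary_table(samples, alpha=config.normality_alpha)

    county_tables = [
        county_summary(
            losses["loss_rel_pct"].to_numpy(),
            losses["county"].to_numpy(),
            metric="forest_loss_rel_pct",
        ),
        county_summary(
            essi_z["change_rel_pct"].to_numpy(),
            essi_z["county"].to_numpy(),
            metric="essi_change_rel_pct",
        ),
        county_summary(
            water["nearest_distance_km"].to_numpy(),
            water["county"].to_numpy(),
            metric="nearest_water_km",
        ),
    ]
    if len(access):
        county_tables.append(
            county_summary(
                access["new_share_pct"].to_numpy(),
                access["county"].to_numpy(),
                metric="demarcation_new_share_pct",
            )
        )
    # per-county paired ESSI tests (the county contrast of the analysis)
    county_essi = []
    for county in sorted(essi_z["county"].dropna().unique()):
        sel = essi_z[essi_z["county"] == county]
        county_essi.append(
            {
                "metric": "essi_mean",
                "resource_class": "all",
                "scope": county,
                "values_t0": sel["essi_t0"].to_numpy(),
                "values_t1": sel["essi_t1"].to_numpy(),
            }
        )
    paired_by_county = paired_summary_table(county_essi, alpha=config.normality_alpha)
    return {
        "paired_tests": paired,
        "paired_essi_by_county": paired_by_county,
        "county_summaries": pd.concat(county_tables, ignore_index=True),
    }


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path | None = None,
    landscape: SyntheticLandscape | None = None,
) -> dict:
    """Run every stage and return the result bundle; optionally write all
    outputs (CSVs, footprint GeoJSON, manifest, report) to ``outdir``."""
    if landscape is None:
        landscape = generate_landscape(config.landscape)
    bundle: dict = {"config": config, "landscape": landscape}

    logger.info("stage footprints")
    bundle.update(stage_footprints(landscape, config))
    logger.info(
        "communities: %d merged, %d after urban filter",
        bundle["n_merged"],
        len(bundle["communities"]),
    )
    logger.info("stage forest change")
    bundle.update(stage_forest_change(landscape, bundle["footprints"], config))
    logger.info("stage essi")
    bundle.update(stage_essi(landscape, bundle["footprints"], config))
    logger.info("stage access")
    bundle.update(
        stage_access(landscape, bundle["footprints"], bundle["forest_2020_km2"], config)
    )
    logger.info("stage water")
    bundle.update(stage_water(landscape, bundle["communities"], config))
    logger.info("stage stats")
    bundle.update(stage_stats(bundle, config))

    bundle["manifest"] = build_manifest(bundle)
    if outdir is not None:
        write_bundle(bundle, outdir)
    return bundle


def build_manifest(bundle: dict) -> dict:
    config: PipelineConfig = bundle["config"]
    return {
        "software_version": __version__,
        "seed": config.landscape.seed,
        "config": config.to_dict(),
        "stage_counts": {
            "communities_merged": int(bundle["n_merged"]),
            "communities_retained": int(len(bundle["communities"])),
            "urban_filtered": int(bundle["n_urban_filtered"]),
            "collection_sites": int(len(bundle["collection_sites"])),
            "footprints": int(len(bundle["footprints"])),
            "loss_records": int(len(bundle["forest_loss"])),
            "coverage_excluded": int(bundle["n_coverage_excluded"]),
            "access_records": int(len(bundle["access"])),
            "water_records": int(len(bundle["water"])),
        },
        "radii_km": {k: float(v) for k, v in bundle["radii_km"].items()},
        "cumulative_area_km2": {
            k: float(v) for k, v in bundle["cumulative_area_km2"].items()
        },
        "n_loss_above_threshold": int(bundle["n_above_threshold"]),
        "water_threshold_counts": {
            str(k): int(v) for k, v in bundle["threshold_counts"].items()
        },
    }


def write_bundle(bundle: dict, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    comm = bundle["communities"].copy()
    comm["x"] = [g.x for g in comm["geometry"]]
    comm["y"] = [g.y for g in comm["geometry"]]
    comm.drop(columns=["geometry"]).to_csv(outdir / "communities.csv", index=False)
    write_geojson(bundle["footprints"], outdir / "footprints.geojson")
    bundle["activity_medians"].to_csv(outdir / "activity_medians.csv", index=False)
    bundle["forest_loss"].to_csv(outdir / "forest_loss.csv", index=False)
    bundle["essi_zonal"].to_csv(outdir / "essi_zonal.csv", index=False)
    bundle["access"].to_csv(outdir / "access.csv", index=False)
    bundle["water"].to_csv(outdir / "water.csv", index=False)
    bundle["paired_tests"].to_csv(outdir / "paired_tests.csv", index=False)
    bundle["paired_essi_by_county"].to_csv(
        outdir / "paired_essi_by_county.csv", index=False
    )
    bundle["county_summaries"].to_csv(outdir / "county_summaries.csv", index=False)
    (outdir / "manifest.json").write_text(json.dumps(bundle["manifest"], indent=2))
    (outdir / "report.txt").write_text(report(bundle))


def report(bundle: dict) -> str:
    """Human-readable summary: headline numbers, paired tests, and per-county
    mean ± SE tables with significance stars."""
    if "forest_loss" not in bundle or not len(bundle.get("forest_loss", [])):
        raise ValueError("bundle is empty or incomplete; run the pipeline first")
    m = bundle["manifest"]
    lines = []
    lines.append("Forest resource availability & access — run summary")
    lines.append("=" * 60)
    lines.append(f"software version {m['software_version']}, seed {m['seed']}")
    sc = m["stage_counts"]
    lines.append(
        f"communities: {sc['communities_merged']} merged, "
        f"{sc['urban_filtered']} urban-coincident removed, "
        f"{sc['communities_retained']} retained"
    )
    r = m["radii_km"]
    lines.append(
        f"footprint radii: plant {r['plant']:.1f} km, animal {r['animal']:.1f} km"
    )
    c = m["cumulative_area_km2"]
    lines.append(
        f"cumulative footprint area: plant {c['plant']:.0f} km², "
        f"animal {c['animal']:.0f} km²"
    )
    losses = bundle["forest_loss"]
    lines.append(
        f"mean forest loss inside footprints: "
        f"{losses['loss_abs_ha'].mean():.1f} ha "
        f"({losses['loss_rel_pct'].mean():.1f}% relative); "
        f"{m['n_loss_above_threshold']} footprints above "
        f"{bundle['config'].loss_threshold_pct:.0f}% loss"
    )
    lines.append(
        f"footprints excluded by demarcation coverage: {sc['coverage_excluded']}"
    )
    for t, n in m["water_threshold_counts"].items():
        lines.append(f"communities farther than {t} km from any water source: {n}")
    lines.append("")
    lines.append("Paired epoch tests (t1 vs t0)")
    lines.append("-" * 60)
    for _, row in bundle["paired_tests"].iterrows():
        lines.append(
            f"{row['metric']:<32} {row['resource_class']:<7} "
            f"{row['mean_t0']:>10.3f} -> {row['mean_t1']:>10.3f}  "
            f"[{row['test']}] p={row['p_value']:.3g} {row['stars']}"
        )
    lines.append("")
    lines.append("County summaries (mean ± SE)")
    lines.append("-" * 60)
    for metric, grp in bundle["county_summaries"].groupby("metric", sort=True):
        lines.append(metric)
        for _, row in grp.iterrows():
            lines.append(
                f"  {row['county']:<12} {row['mean']:>9.2f} ± {row['standard_error']:<8.2f}"
                f" (n={row['n']})"
            )
    lines.append("")
    lines.append("Per-county paired ESSI tests")
    lines.append("-" * 60)
    for _, row in bundle["paired_essi_by_county"].iterrows():
        lines.append(
            f"  {row['scope']:<12} {row['mean_t0']:.3f} -> {row['mean_t1']:.3f}  "
            f"[{row['test']}] p={row['p_value']:.3g} {row['stars']}"
        )
    return "\n".join(lines) + "\n"
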