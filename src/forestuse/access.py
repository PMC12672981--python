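"""Access restrictions (demarcation-line density) and water accessibility.

Demarcation lines — linear deforested strips marking land claims — restrict
movement through the forest matrix.  Their per-footprint density is
weighted by the forest area still standing in 2020 (km of line per 100 km²
of remaining forest), with both epochs sharing the 2020 denominator so the
epoch contrast reflects line accumulation, not forest loss.  Footprints not
fully covered by the demarcation dataset's mapped extent are excluded.

Water access is the straight-line distance from each settlement to its
nearest source: surface-water pixels (permanent rivers/reservoirs or
seasonal) and urban areas (piped supply; distance to the polygon boundary,
zero inside).  Distance ties resolve by source priority
urban > river > reservoir > seasonal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import cKDTree

from .georaster import Raster

CLASS_NONE, CLASS_SEASONAL, CLASS_PERMANENT = 0, 1, 2
TYPE_RIVER, TYPE_RESERVOIR = 1, 2

#: tie-break priority (lower wins)
_SOURCE_PRIORITY = {"urban": 0, "river": 1, "reservoir": 2, "seasonal": 3}
ALL_SOURCE_TYPES = frozenset(_SOURCE_PRIORITY)
PERMANENT_NATURAL = frozenset({"river", "reservoir"})


@dataclass
class WaterLayer:
    """Per-epoch surface-water classification.

    ``class_raster`` holds {0 none, 1 seasonal, 2 permanent};
    ``type_raster`` types permanent pixels as {1 river, 2 reservoir} and is
    zero elsewhere.  Urban polygons ride along because urban areas act as a
    water source in the accessibility analysis.
    """

    epoch: int
    class_raster: Raster
    type_raster: Raster
    urban_polygons: pd.DataFrame

    def source_pixel_centers(self, source_type: str) -> np.ndarray:
        """(n, 2) x/y pixel centers of one raster source type."""
        cls = self.class_raster.data
        typ = self.type_raster.data
        if source_type == "seasonal":
            mask = cls == CLASS_SEASONAL
        elif source_type == "river":
            mask = (cls == CLASS_PERMANENT) & (typ == TYPE_RIVER)
        elif source_type == "reservoir":
            mask = (cls == CLASS_PERMANENT) & (typ == TYPE_RESERVOIR)
        else:
            raise ValueError(f"unknown raster source type: {source_type!r}")
        rows, cols = np.nonzero(mask)
        xs, ys = self.class_raster.center_coords()
        return np.column_stack([xs[cols], ys[rows]])


# ---------------------------------------------------------------------------
# demarcation density
# ---------------------------------------------------------------------------


def filter_mapped_coverage(
    footprints: pd.DataFrame, mapped_extent
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split footprints into (included, excluded): a footprint is included
    iff it lies entirely within the mapped extent of the demarcation data."""
    if not len(footprints):
        return footprints.copy(), footprints.copy()
    inside = np.array(
        [shapely.covered_by(g, mapped_extent) for g in footprints["geometry"]]
    )
    return (
        footprints[inside].reset_index(drop=True),
        footprints[~inside].reset_index(drop=True),
    )


def demarcation_length(footprint, lines: pd.DataFrame, epoch_year: int) -> float:
    """Total length (km) of demarcation lines existing by ``epoch_year``,
    clipped to the footprint."""
    if not len(lines):
        return 0.0
    sel = lines[lines["year"] <= epoch_year]
    if not len(sel):
        return 0.0
    total_m = sum(g.intersection(footprint).length for g in sel["geometry"])
    return float(total_m) / 1000.0


def weighted_density(
    length_km: float, forest_area_2020_km2: float, scale: float = 100.0
) -> float:
    """Demarcation density weighted by available forest:
    km of line per ``scale`` km² of remaining 2020 forest."""
    if forest_area_2020_km2 <= 0:
        raise ValueError("forest area must be positive for a weighted density")
    return scale * length_km / forest_area_2020_km2


def new_share(length_t0: float, length_t1: float) -> float:
    """Share (%) of the t1 line stock that appeared after t0."""
    if not 0 <= length_t0 <= length_t1 + 1e-9:
        raise ValueError("line lengths must satisfy 0 <= t0 <= t1 (nested stocks)")
    if length_t1 == 0:
        return 0.0
    return 100.0 * (length_t1 - length_t0) / length_t1


def access_table(
    footprints: pd.DataFrame,
    lines: pd.DataFrame,
    forest_area_2020_km2: pd.Series,
    t0: int,
    t1: int,
    density_scale: float = 100.0,
) -> pd.DataFrame:
    """Per-community demarcation lengths, weighted densities and new-line
    share.  ``forest_area_2020_km2`` is indexed by community_id; zero-forest
    records get NaN densities and are flagged."""
    rows = []
    for _, fp in footprints.iterrows():
        cid = fp["community_id"]
        l0 = demarcation_length(fp["geometry"], lines, t0)
        l1 = demarcation_length(fp["geometry"], lines, t1)
        forest = float(forest_area_2020_km2.get(cid, np.nan))
        flagged = not np.isfinite(forest) or forest <= 0
        d0 = np.nan if flagged else weighted_density(l0, forest, density_scale)
        d1 = np.nan if flagged else weighted_density(l1, forest, density_scale)
        rows.append(
            {
                "community_id": cid,
                "county": fp.get("county"),
                "resource_class": fp["resource_class"],
                "length_t0_km": l0,
                "length_t1_km": l1,
                "forest_2020_km2": forest,
                "density_t0": d0,
                "density_t1": d1,
                "new_share_pct": new_share(l0, l1),
                "zero_forest_flag": flagged,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# water accessibility
# ---------------------------------------------------------------------------


def _nearest_raster_source(
    points_xy: np.ndarray, water: WaterLayer, source_type: str
) -> np.ndarray:
    centers = water.source_pixel_centers(source_type)
    if not len(centers):
        return np.full(len(points_xy), np.inf)
    d, _ = cKDTree(centers).query(points_xy, k=1)
    return d


def nearest_water_table(
    communities: pd.DataFrame,
    water: WaterLayer,
    include: frozenset | set = ALL_SOURCE_TYPES,
) -> pd.DataFrame:
    """Nearest water source per community over the included source types.

    Raster sources are measured to pixel centers; urban to the polygon
    (zero inside).  Ties break by priority urban > river > reservoir >
    seasonal.
    """
    include = set(include)
    unknown = include - ALL_SOURCE_TYPES
    if unknown:
        raise ValueError(f"unknown source types: {sorted(unknown)}")
    if not include:
        raise ValueError("no source types requested")
    pts = np.array([[g.x, g.y] for g in communities["geometry"]])

    dist_by_type: dict[str, np.ndarray] = {}
    for st in include & {"river", "reservoir", "seasonal"}:
        dist_by_type[st] = _nearest_raster_source(pts, water, st)
    if "urban" in include:
        polys = list(water.urban_polygons["geometry"]) if len(water.urban_polygons) else []
        if polys:
            union = shapely.union_all(polys)
            dist_by_type["urban"] = np.array(
                [shapely.distance(union, g) for g in communities["geometry"]]
            )
        else:
            dist_by_type["urban"] = np.full(len(pts), np.inf)

    if all(np.isinf(d).all() for d in dist_by_type.values()):
        raise ValueError("no water sources of the requested types exist")

    ordered = sorted(dist_by_type, key=_SOURCE_PRIORITY.__getitem__)
    dist_mat = np.column_stack([dist_by_type[t] for t in ordered])
    best = dist_mat.argmin(axis=1)  # argmin takes the first (highest-priority) tie
    best_d = dist_mat[np.arange(len(pts)), best]
    return pd.DataFrame(
        {
            "community_id": communities["id"].to_numpy(),
            "county": communities["county"].to_numpy()
            if "county" in communities
            else None,
            "nearest_distance_km": best_d / 1000.0,
            "nearest_source_type": [ordered[i] for i in best],
        }
    )


def nearest_water(
    community_point, water: WaterLayer, include: frozenset | set = ALL_SOURCE_TYPES
) -> tuple[float, str]:
    """Single-community convenience wrapper around :func:`nearest_water_table`."""
    df = nearest_water_table(
        pd.DataFrame({"id": ["x"], "county": [None], "geometry": [community_point]}),
        water,
        include,
    )
    return float(df["nearest_distance_km"].iloc[0]), str(df["nearest_source_type"].iloc[0])


def permanent_water_change(
    communities: pd.DataFrame, water_t0: WaterLayer, water_t1: WaterLayer
) -> pd.DataFrame:
    """Distance to the nearest permanent *natural* source (river/reservoir,
    urban excluded) in each epoch and its change delta = d_t1 − d_t0.

    An epoch with no permanent natural water yields NaN distances and a
    flag rather than an error, so the record survives into the tables.
    """
    out = {"community_id": communities["id"].to_numpy()}
    if "county" in communities:
        out["county"] = communities["county"].to_numpy()
    for label, wl in (("t0", water_t0), ("t1", water_t1)):
        try:
            df = nearest_water_table(communities, wl, PERMANENT_NATURAL)
            out[f"permanent_natural_distance_{label}_km"] = df[
                "nearest_distance_km"
            ].to_numpy()
        except ValueError:
            out[f"permanent_natural_distance_{label}_km"] = np.full(
                len(communities), np.nan
            )
    df = pd.DataFrame(out)
    df["delta_km"] = (
        df["permanent_natural_distance_t1_km"] - df["permanent_natural_distance_t0_km"]
    )
    df["missing_epoch_flag"] = (
        ~np.isfinite(df["permanent_natural_distance_t0_km"])
        | ~np.isfinite(df["permanent_natural_distance_t1_km"])
    )
    return df


def distance_threshold_counts(
    distances_km: pd.Series | np.ndarray, thresholds_km: list[float]
) -> dict[float, int]:
    """Per threshold, the number of communities strictly farther than it."""
    if list(thresholds_km) != sorted(thresholds_km):
        raise ValueError("thresholds must be sorted ascending")
    d = np.asarray(distances_km, float)
    return {float(t): int((d > t).sum()) for t in thresholds_km}
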