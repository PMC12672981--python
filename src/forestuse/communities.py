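"""Community-settlement merging, urban filtering, and resource-use footprints.

Settlement lists from two sources are overlaid and cross-source duplicates
within a dedup radius are collapsed (the first list's attributes win).
Settlements coincident with urban areas are discarded as not
forest-dependent.  Per resource class (plant / animal), a footprint radius
is estimated from surveyed collection sites as the largest per-activity
median trip distance, and each community receives a disc footprint of that
radius.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import cKDTree

from .activities import RESOURCE_CLASSES


def merge_community_sources(
    list_a: pd.DataFrame, list_b: pd.DataFrame, dedup_radius_m: float
) -> pd.DataFrame:
    """Overlay two settlement lists, dropping list-B records that fall within
    ``dedup_radius_m`` of any list-A record.

    The retained record keeps list-A attributes on conflict.  Merging the
    merged output with itself is a no-op (idempotence).
    """
    if dedup_radius_m < 0:
        raise ValueError("dedup_radius_m must be non-negative")
    if not len(list_b):
        merged = list_a.copy()
    elif not len(list_a):
        merged = list_b.copy()
    else:
        a_xy = np.array([[g.x, g.y] for g in list_a["geometry"]])
        b_xy = np.array([[g.x, g.y] for g in list_b["geometry"]])
        tree = cKDTree(a_xy)
        d, _ = tree.query(b_xy, k=1)
        keep_b = d > dedup_radius_m
        merged = pd.concat([list_a, list_b[keep_b]], ignore_index=True)
    if merged["id"].duplicated().any():
        raise ValueError("duplicate settlement ids after merging")
    return merged.reset_index(drop=True)


def filter_urban(communities: pd.DataFrame, urban_polygons: pd.DataFrame) -> pd.DataFrame:
    """Drop settlements whose point lies inside (or on the boundary of) any
    urban polygon.  With no urban polygons this is the identity."""
    if not len(urban_polygons) or not len(communities):
        return communities.copy().reset_index(drop=True)
    union = shapely.union_all(list(urban_polygons["geometry"]))
    inside = np.array([shapely.intersects(union, g) for g in communities["geometry"]])
    return communities[~inside].reset_index(drop=True)


def site_distances(sites: pd.DataFrame, communities: pd.DataFrame) -> pd.Series:
    """Euclidean community-to-site distance (km) for every collection site."""
    loc = communities.set_index("id")["geometry"]
    missing = set(sites["community_id"]) - set(loc.index)
    if missing:
        raise ValueError(f"sites reference unknown communities: {sorted(missing)[:5]}")
    d_m = np.array(
        [
            site_geom.distance(loc[cid])
            for cid, site_geom in zip(sites["community_id"], sites["geometry"])
        ]
    )
    return pd.Series(d_m / 1000.0, index=sites.index, name="distance_km")


def estimate_class_radius(
    sites: pd.DataFrame,
    communities: pd.DataFrame,
    resource_class: str,
    method: str = "activity_median",
) -> float:
    """Footprint radius (km) for one resource class.

    ``activity_median`` (default): per activity, the median community-to-site
    distance over all its sites; the class radius is the maximum of these
    per-activity medians, so every activity's median trip is encompassed.
    ``community_farthest``: median over communities of each community's
    farthest site of the class.
    """
    if resource_class not in RESOURCE_CLASSES:
        raise ValueError(f"unknown resource class: {resource_class!r}")
    sel = sites[sites["resource_class"] == resource_class]
    if not len(sel):
        raise ValueError(f"no collection sites of class {resource_class!r}")
    dist = site_distances(sel, communities)
    if method == "activity_median":
        medians = dist.groupby(sel["activity"]).median()
        return float(medians.max())
    if method == "community_farthest":
        farthest = dist.groupby(sel["community_id"]).max()
        return float(farthest.median())
    raise ValueError(f"unknown method: {method!r}")


def activity_medians(sites: pd.DataFrame, communities: pd.DataFrame) -> pd.DataFrame:
    """Median trip distance (km) per activity — the survey summary behind the
    footprint radii."""
    dist = site_distances(sites, communities)
    out = (
        pd.DataFrame(
            {
                "activity": sites["activity"],
                "resource_class": sites["resource_class"],
                "distance_km": dist,
            }
        )
        .groupby(["resource_class", "activity"], sort=True)["distance_km"]
        .agg(median_km="median", n_sites="count")
        .reset_index()
    )
    return out


def build_footprints(
    communities: pd.DataFrame, radius_km: float, resource_class: str
) -> pd.DataFrame:
    """One disc footprint per community (≥ 64-vertex polygonal circles)."""
    if radius_km <= 0:
        raise ValueError("radius_km must be positive")
    rows = [
        {
            "community_id": c["id"],
            "county": c.get("county"),
            "resource_class": resource_class,
            "radius_km": radius_km,
            "geometry": c["geometry"].buffer(radius_km * 1000.0, quad_segs=32),
        }
        for _, c in communities.iterrows()
    ]
    return pd.DataFrame(rows)


def cumulative_footprint_area(footprints: pd.DataFrame) -> float:
    """Area (km²) of the geometric union of footprints; overlaps count once."""
    if not len(footprints):
        raise ValueError("no footprints supplied")
    union = shapely.union_all(list(footprints["geometry"]))
    return float(union.area / 1e6)
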