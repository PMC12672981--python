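import numpy as np
import pandas as pd
import pytest
import shapely
from shapely.geometry import Point, box

from forestuse.communities import (
    build_footprints,
    cumulative_footprint_area,
    estimate_class_radius,
    filter_urban,
    merge_community_sources,
)
from .conftest import point_df


# ---------------------------------------------------------------------------
# source merging
# ---------------------------------------------------------------------------


def test_merge_identical_lists_collapses():
    pts = [(i * 5000.0, i * 5000.0) for i in range(10)]
    a = point_df(pts, "a")
    b = point_df(pts, "b")
    merged = merge_community_sources(a, b, dedup_radius_m=1000.0)
    assert len(merged) == 10
    assert set(merged["source"]) == {"list_a"}  # list-a attributes win


def test_merge_close_pair_collapses_far_pair_survives():
    a = point_df([(0.0, 0.0)], "a")
    b_close = point_df([(500.0, 0.0)], "b")
    b_far = point_df([(1500.0, 0.0)], "b")
    assert len(merge_community_sources(a, b_close, 1000.0)) == 1
    assert len(merge_community_sources(a, b_far, 1000.0)) == 2


def test_merge_matches_brute_force_oracle(rng):
    """349 + 202 random points with 120 planted cross-source duplicates
    must reproduce the O(n²) pairwise-distance dedup count."""
    radius = 1000.0
    a_pts = rng.uniform(0, 200_000, size=(349, 2))
    dup_idx = rng.choice(349, size=120, replace=False)
    jitter = rng.uniform(-radius / 3, radius / 3, size=(120, 2))
    b_pts = np.vstack([a_pts[dup_idx] + jitter, rng.uniform(0, 200_000, size=(82, 2))])
    a = point_df(a_pts, "a")
    b = point_df(b_pts, "b")

    keep_b = [
        not any(np.hypot(*(bp - ap)) <= radius for ap in a_pts) for bp in b_pts
    ]
    expected = 349 + sum(keep_b)
    merged = merge_community_sources(a, b, radius)
    assert len(merged) == expected


def test_merge_is_idempotent(rng):
    pts = rng.uniform(0, 50_000, size=(40, 2))
    a = point_df(pts[:25], "a")
    b = point_df(pts[20:], "b")
    merged = merge_community_sources(a, b, 500.0)
    again = merge_community_sources(merged, merged, 500.0)
    assert len(again) == len(merged)
    assert again["id"].tolist() == merged["id"].tolist()


def test_merge_rejects_negative_radius():
    a = point_df([(0, 0)], "a")
    with pytest.raises(ValueError):
        merge_community_sources(a, a, -1.0)


# ---------------------------------------------------------------------------
# urban filter
# ---------------------------------------------------------------------------


def test_urban_filter_trivial_cases():
    comms = point_df([(0, 0), (10_000, 0)], "a")
    urban_none = pd.DataFrame(columns=["id", "geometry"])
    assert len(filter_urban(comms, urban_none)) == 2
    urban_all = pd.DataFrame(
        {"id": ["u"], "geometry": [box(-20_000, -20_000, 20_000, 20_000)]}
    )
    assert len(filter_urban(comms, urban_all)) == 0


def test_urban_boundary_point_counts_as_inside():
    comms = point_df([(1000.0, 0.0)], "a")
    urban = pd.DataFrame({"id": ["u"], "geometry": [box(1000, -500, 2000, 500)]})
    assert len(filter_urban(comms, urban)) == 0


def test_urban_filter_matches_point_in_polygon_oracle(rng):
    comms = point_df(rng.uniform(0, 10_000, size=(60, 2)), "a")
    polys = [
        box(x, y, x + rng.uniform(500, 3000), y + rng.uniform(500, 3000))
        for x, y in rng.uniform(0, 9000, size=(5, 2))
    ]
    urban = pd.DataFrame({"id": [f"u{i}" for i in range(5)], "geometry": polys})
    kept = filter_urban(comms, urban)
    expected = [
        c["id"]
        for _, c in comms.iterrows()
        if not any(p.intersects(c["geometry"]) for p in polys)
    ]
    assert kept["id"].tolist() == expected


# ---------------------------------------------------------------------------
# radius estimation
# ---------------------------------------------------------------------------


def _sites_at_distances(comm_id, activity, resource_class, dists_km):
    return pd.DataFrame(
        {
            "community_id": comm_id,
            "activity": activity,
            "resource_class": resource_class,
            "geometry": [Point(d * 1000.0, 0.0) for d in dists_km],
        }
    )


def test_radius_single_activity_is_median():
    comm = point_df([(0.0, 0.0)], "c")
    sites = _sites_at_distances(comm["id"][0], "firewood cutting", "plant", [2, 4, 6])
    assert estimate_class_radius(sites, comm, "plant") == pytest.approx(4.0)


def test_radius_takes_max_of_activity_medians():
    """Two plant activities with medians 2 and 8 km: the class footprint
    must encompass both, i.e. radius 8 km."""
    comm = point_df([(0.0, 0.0)], "c")
    sites = pd.concat(
        [
            _sites_at_distances(comm["id"][0], "firewood cutting", "plant", [1, 2, 3]),
            _sites_at_distances(comm["id"][0], "house construction", "plant", [7, 8, 9]),
        ],
        ignore_index=True,
    )
    assert estimate_class_radius(sites, comm, "plant") == pytest.approx(8.0)


def test_radius_recovers_lognormal_median(rng):
    """Log-normal trips with median 15 km, n=1000 → estimate within 5%."""
    comm = point_df([(0.0, 0.0)], "c")
    d_km = 15.0 * np.exp(0.5 * rng.standard_normal(1000))
    theta = rng.uniform(0, 2 * np.pi, 1000)
    sites = pd.DataFrame(
        {
            "community_id": comm["id"][0],
            "activity": "hunting",
            "resource_class": "animal",
            "geometry": [
                Point(1000 * d * np.cos(t), 1000 * d * np.sin(t))
                for d, t in zip(d_km, theta)
            ],
        }
    )
    est = estimate_class_radius(sites, comm, "animal")
    assert abs(est - 15.0) / 15.0 < 0.05


def test_radius_invariant_to_order_and_translation(rng):
    comm = point_df([(0.0, 0.0)], "c")
    sites = _sites_at_distances(comm["id"][0], "fishing", "animal", rng.uniform(2, 30, 21))
    base = estimate_class_radius(sites, comm, "animal")
    shuffled = sites.sample(frac=1, random_state=1).reset_index(drop=True)
    assert estimate_class_radius(shuffled, comm, "animal") == pytest.approx(base)
    dx, dy = 123_456.0, -77_000.0
    comm_t = comm.copy()
    comm_t["geometry"] = [Point(g.x + dx, g.y + dy) for g in comm["geometry"]]
    sites_t = sites.copy()
    sites_t["geometry"] = [Point(g.x + dx, g.y + dy) for g in sites["geometry"]]
    assert estimate_class_radius(sites_t, comm_t, "animal") == pytest.approx(base)


def test_radius_errors():
    comm = point_df([(0.0, 0.0)], "c")
    empty = pd.DataFrame(columns=["community_id", "activity", "resource_class", "geometry"])
    with pytest.raises(ValueError):
        estimate_class_radius(empty, comm, "plant")
    with pytest.raises(ValueError):
        estimate_class_radius(empty, comm, "mineral")


# ---------------------------------------------------------------------------
# footprints and cumulative area
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("radius_km,expected_km2", [(8.0, 201.0619), (15.0, 706.8583)])
def test_footprint_disc_area(radius_km, expected_km2):
    comm = point_df([(0.0, 0.0)], "c")
    fp = build_footprints(comm, radius_km, "plant")
    area = fp["geometry"][0].area / 1e6
    assert area == pytest.approx(expected_km2, rel=0.01)
    assert shapely.get_num_coordinates(fp["geometry"][0]) >= 64


def test_footprints_disjoint_when_far_apart():
    comm = point_df([(0.0, 0.0), (100_000.0, 0.0)], "c")
    fp = build_footprints(comm, 8.0, "plant")
    assert not fp["geometry"][0].intersects(fp["geometry"][1])


def test_nonpositive_radius_rejected():
    with pytest.raises(ValueError):
        build_footprints(point_df([(0, 0)], "c"), 0.0, "plant")


def test_cumulative_area_disjoint_and_identical():
    two_far = build_footprints(point_df([(0, 0), (100_000, 0)], "c"), 8.0, "plant")
    assert cumulative_footprint_area(two_far) == pytest.approx(2 * 201.0619, rel=0.01)
    two_same = build_footprints(point_df([(0, 0), (0, 0)], "c"), 8.0, "plant")
    assert cumulative_footprint_area(two_same) == pytest.approx(201.0619, rel=0.01)


def test_cumulative_area_matches_monte_carlo(rng):
    """Union area of overlapping discs vs rejection-sampling estimate."""
    centers = rng.uniform(0, 30_000, size=(6, 2))
    comm = point_df(centers, "c")
    fp = build_footprints(comm, 8.0, "plant")
    union_km2 = cumulative_footprint_area(fp)

    lo, hi = -10_000.0, 40_000.0
    n = 200_000
    pts = rng.uniform(lo, hi, size=(n, 2))
    inside = np.zeros(n, bool)
    for g in fp["geometry"]:
        inside |= shapely.contains_xy(g, pts[:, 0], pts[:, 1])
    mc_km2 = inside.mean() * (hi - lo) ** 2 / 1e6
    assert abs(union_km2 - mc_km2) / mc_km2 < 0.005


def test_union_area_bounded_by_sum(rng):
    centers = rng.uniform(0, 20_000, size=(5, 2))
    fp = build_footprints(point_df(centers, "c"), 8.0, "plant")
    union = cumulative_footprint_area(fp)
    total = sum(g.area for g in fp["geometry"]) / 1e6
    assert union <= total + 1e-9
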