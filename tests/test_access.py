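import numpy as np
import pandas as pd
import pytest
import shapely
from shapely.geometry import LineString, Point, box

from forestuse.access import (
    WaterLayer,
    demarcation_length,
    distance_threshold_counts,
    filter_mapped_coverage,
    nearest_water,
    nearest_water_table,
    new_share,
    permanent_water_change,
    weighted_density,
)
from forestuse.georaster import Raster
from .conftest import point_df


def lines_df(geoms, years):
    return pd.DataFrame({"geometry": geoms, "year": years})


def water_layer(class_arr, type_arr=None, urban=None, pixel_size=1000.0, epoch=2021):
    class_arr = np.asarray(class_arr, np.uint8)
    if type_arr is None:
        type_arr = np.where(class_arr == 2, 1, 0).astype(np.uint8)  # permanent=river
    grid = Raster(class_arr, 0.0, class_arr.shape[0] * pixel_size, pixel_size)
    urban = (
        urban
        if urban is not None
        else pd.DataFrame(columns=["id", "geometry"])
    )
    return WaterLayer(epoch, grid, grid.like(np.asarray(type_arr, np.uint8)), urban)


# ---------------------------------------------------------------------------
# mapped-coverage filter
# ---------------------------------------------------------------------------


def test_coverage_filter_inside_and_outside():
    extent = box(0, 0, 50_000, 50_000)
    fps = pd.DataFrame(
        {
            "community_id": ["in", "touch_out", "partial"],
            "resource_class": "plant",
            "geometry": [
                box(10_000, 10_000, 20_000, 20_000),
                box(50_000, 10_000, 60_000, 20_000),  # touches from outside
                box(45_000, 10_000, 55_000, 20_000),
            ],
        }
    )
    included, excluded = filter_mapped_coverage(fps, extent)
    assert included["community_id"].tolist() == ["in"]
    assert sorted(excluded["community_id"]) == ["partial", "touch_out"]


def test_coverage_filter_matches_containment_oracle(rng):
    extent = box(5000, 5000, 45_000, 45_000)
    geoms = [
        Point(x, y).buffer(rng.uniform(1000, 9000))
        for x, y in rng.uniform(0, 50_000, size=(40, 2))
    ]
    fps = pd.DataFrame(
        {
            "community_id": [f"c{i}" for i in range(40)],
            "resource_class": "plant",
            "geometry": geoms,
        }
    )
    included, _ = filter_mapped_coverage(fps, extent)
    expected = [f"c{i}" for i, g in enumerate(geoms) if g.difference(extent).is_empty]
    assert included["community_id"].tolist() == expected


# ---------------------------------------------------------------------------
# demarcation length and density
# ---------------------------------------------------------------------------


def test_line_fully_inside_counts_whole_length():
    fp = box(0, 0, 20_000, 20_000)
    lines = lines_df([LineString([(1000, 1000), (11_000, 1000)])], [2000])
    assert demarcation_length(fp, lines, 2001) == pytest.approx(10.0)
    assert demarcation_length(fp, lines, 1999) == pytest.approx(0.0)


def test_clipped_line_length_matches_dense_sampling(rng):
    """Line crossing a disc boundary: clipped length vs vertex-sampling."""
    disc = Point(10_000, 10_000).buffer(8000, quad_segs=64)
    for _ in range(10):
        p0 = rng.uniform(-5000, 25_000, 2)
        p1 = rng.uniform(-5000, 25_000, 2)
        line = LineString([p0, p1])
        got = demarcation_length(disc, lines_df([line], [2000]), 2001)
        ts = np.linspace(0, 1, 20_001)
        pts = p0[None] + ts[:, None] * (p1 - p0)[None]
        inside = shapely.contains_xy(disc, pts[:, 0], pts[:, 1])
        oracle = inside.mean() * np.hypot(*(p1 - p0)) / 1000.0
        assert got == pytest.approx(oracle, abs=max(0.01 * oracle, 0.01))


def test_demarcation_length_additive_and_monotone(rng):
    fp = box(0, 0, 30_000, 30_000)
    geoms = [
        LineString([rng.uniform(0, 30_000, 2), rng.uniform(0, 30_000, 2)])
        for _ in range(12)
    ]
    years = list(rng.integers(1995, 2021, 12))
    lines = lines_df(geoms, years)
    half_a, half_b = lines.iloc[:6], lines.iloc[6:]
    total = demarcation_length(fp, lines, 2025)
    assert total == pytest.approx(
        demarcation_length(fp, half_a, 2025) + demarcation_length(fp, half_b, 2025)
    )
    lengths = [demarcation_length(fp, lines, y) for y in range(1995, 2026)]
    assert all(b >= a - 1e-12 for a, b in zip(lengths, lengths[1:]))


def test_weighted_density_definition_and_invariance():
    assert weighted_density(10.0, 100.0) == pytest.approx(10.0)
    assert weighted_density(0.0, 55.0) == 0.0
    assert weighted_density(20.0, 200.0) == pytest.approx(weighted_density(10.0, 100.0))
    with pytest.raises(ValueError):
        weighted_density(10.0, 0.0)


def test_new_share_examples():
    assert new_share(5.0, 10.0) == pytest.approx(50.0)
    assert new_share(7.0, 7.0) == 0.0
    assert new_share(0.0, 4.0) == pytest.approx(100.0)
    assert new_share(0.0, 0.0) == 0.0
    with pytest.raises(ValueError):
        new_share(5.0, 4.0)


# ---------------------------------------------------------------------------
# nearest water
# ---------------------------------------------------------------------------


def test_nearest_water_prefers_closer_source():
    # river pixel centred at (500, 3500); community 3 km east of it
    cls = np.zeros((4, 4), np.uint8)
    cls[0, 0] = 2
    urban = pd.DataFrame(
        {"id": ["u"], "geometry": [box(8000, 2000, 9000, 5000)]}
    )  # 4.5 km away
    wl = water_layer(cls, urban=urban)
    d, t = nearest_water(Point(3500.0, 3500.0), wl)
    assert d == pytest.approx(3.0)
    assert t == "river"


def test_nearest_water_inside_urban_is_zero():
    cls = np.zeros((4, 4), np.uint8)
    cls[0, 0] = 2
    urban = pd.DataFrame({"id": ["u"], "geometry": [box(1000, 1000, 3000, 3000)]})
    wl = water_layer(cls, urban=urban)
    d, t = nearest_water(Point(2000.0, 2000.0), wl)
    assert d == 0.0
    assert t == "urban"


def test_nearest_water_tie_breaks_by_priority():
    cls = np.zeros((3, 3), np.uint8)
    cls[0, 0] = 2  # river at (500, 2500)
    cls[0, 2] = 1  # seasonal at (2500, 2500), same distance from (1500, 2500)
    wl = water_layer(cls)
    d, t = nearest_water(Point(1500.0, 2500.0), wl)
    assert d == pytest.approx(1.0)
    assert t == "river"


def test_nearest_water_matches_exhaustive_scan(rng):
    """50 random configurations vs a brute-force scan over every water
    pixel and urban geometry."""
    for _ in range(50):
        cls = (rng.random((10, 10)) < 0.08).astype(np.uint8)  # seasonal
        perm = rng.random((10, 10)) < 0.05
        typ = np.zeros((10, 10), np.uint8)
        typ[perm] = rng.integers(1, 3, perm.sum())
        cls[perm] = 2
        urban_geoms = [
            box(x, y, x + 800, y + 800) for x, y in rng.uniform(0, 9000, size=(2, 2))
        ]
        urban = pd.DataFrame({"id": ["u1", "u2"], "geometry": urban_geoms})
        wl = water_layer(cls, typ, urban)
        pt = Point(*rng.uniform(0, 10_000, 2))

        # oracle
        xs, ys = wl.class_raster.center_coords()
        best = (np.inf, None)
        prio = {"urban": 0, "river": 1, "reservoir": 2, "seasonal": 3}
        for i in range(10):
            for j in range(10):
                if cls[i, j] == 0:
                    continue
                st = (
                    "seasonal"
                    if cls[i, j] == 1
                    else ("river" if typ[i, j] == 1 else "reservoir")
                )
                d = np.hypot(xs[j] - pt.x, ys[i] - pt.y)
                if (d, prio[st]) < (best[0], prio.get(best[1], 9)):
                    best = (d, st)
        for g in urban_geoms:
            d = pt.distance(g)
            if (d, prio["urban"]) < (best[0], prio.get(best[1], 9)):
                best = (d, "urban")

        d_km, st = nearest_water(pt, wl)
        assert d_km == pytest.approx(best[0] / 1000.0)
        assert st == best[1]


def test_adding_water_never_increases_distance(rng):
    cls = np.zeros((10, 10), np.uint8)
    cls[9, 9] = 2
    wl = water_layer(cls)
    comms = point_df(rng.uniform(0, 10_000, size=(15, 2)), "c")
    comms = comms.rename(columns={})
    base = nearest_water_table(comms, wl)["nearest_distance_km"]
    cls2 = cls.copy()
    cls2[rng.integers(0, 10, 5), rng.integers(0, 10, 5)] = 1
    wl2 = water_layer(cls2)
    more = nearest_water_table(comms, wl2)["nearest_distance_km"]
    assert (more <= base + 1e-12).all()


def test_nearest_water_no_sources_errors():
    wl = water_layer(np.zeros((3, 3)))
    with pytest.raises(ValueError):
        nearest_water(Point(0, 0), wl, include={"river"})
    with pytest.raises(ValueError):
        nearest_water(Point(0, 0), wl, include={"lake"})


# ---------------------------------------------------------------------------
# permanent-water change
# ---------------------------------------------------------------------------


def test_permanent_change_identical_layers_zero_delta():
    cls = np.zeros((5, 5), np.uint8)
    cls[2, 2] = 2
    wl = water_layer(cls)
    comms = point_df([(100.0, 100.0), (4000.0, 4000.0)], "c")
    out = permanent_water_change(comms, wl, wl)
    np.testing.assert_allclose(out["delta_km"], 0.0)


def test_permanent_change_demotion_shifts_distance():
    """Nearest river reach 2 km away demoted to seasonal; next permanent
    source 12 km away → delta +10 km."""
    cls0 = np.zeros((1, 16), np.uint8)
    cls0[0, 0] = 2  # center x = 500
    cls0[0, 10] = 2  # center x = 10_500
    wl0 = water_layer(cls0, pixel_size=1000.0)
    cls1 = cls0.copy()
    cls1[0, 0] = 1  # demoted to seasonal
    typ1 = np.where(cls1 == 2, 1, 0)
    wl1 = water_layer(cls1, typ1, pixel_size=1000.0)
    comms = point_df([(2500.0, 500.0)], "c")  # 2 km west pixel, 8 km to next
    out = permanent_water_change(comms, wl0, wl1)
    assert out["permanent_natural_distance_t0_km"][0] == pytest.approx(2.0)
    assert out["permanent_natural_distance_t1_km"][0] == pytest.approx(8.0)
    assert out["delta_km"][0] == pytest.approx(6.0)


def test_permanent_change_missing_epoch_flagged():
    cls_perm = np.zeros((3, 3), np.uint8)
    cls_perm[0, 0] = 2
    cls_none = np.zeros((3, 3), np.uint8)
    comms = point_df([(500.0, 500.0)], "c")
    out = permanent_water_change(comms, water_layer(cls_perm), water_layer(cls_none))
    assert np.isfinite(out["permanent_natural_distance_t0_km"][0])
    assert np.isnan(out["permanent_natural_distance_t1_km"][0])
    assert bool(out["missing_epoch_flag"][0])


def test_permanent_change_random_matches_oracle(rng):
    for _ in range(10):
        cls0 = np.zeros((8, 8), np.uint8)
        perm = rng.random((8, 8)) < 0.15
        cls0[perm] = 2
        if not perm.any():
            continue
        demote = perm & (rng.random((8, 8)) < 0.5)
        cls1 = cls0.copy()
        cls1[demote] = 1
        wl0, wl1 = water_layer(cls0), water_layer(cls1)
        comms = point_df(rng.uniform(0, 8000, size=(5, 2)), "c")
        out = permanent_water_change(comms, wl0, wl1)
        xs, ys = wl0.class_raster.center_coords()
        for k, (_, c) in enumerate(comms.iterrows()):
            for cls_arr, col in (
                (cls0, "permanent_natural_distance_t0_km"),
                (cls1, "permanent_natural_distance_t1_km"),
            ):
                ii, jj = np.nonzero(cls_arr == 2)
                if len(ii) == 0:
                    assert np.isnan(out[col][k])
                    continue
                d = np.hypot(xs[jj] - c["geometry"].x, ys[ii] - c["geometry"].y).min()
                assert out[col][k] == pytest.approx(d / 1000.0)


def test_distance_threshold_counts_strict():
    counts = distance_threshold_counts(pd.Series([1.9, 2.0, 2.1]), [2.0])
    assert counts[2.0] == 1
    counts = distance_threshold_counts(pd.Series([], dtype=float), [2.0, 10.0])
    assert counts == {2.0: 0, 10.0: 0}
    with pytest.raises(ValueError):
        distance_threshold_counts(pd.Series([1.0]), [10.0, 2.0])
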