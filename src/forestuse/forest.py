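"""Forest-area and conversion accounting within resource-use footprints.

Forest available to a community at year ``y`` is the baseline forest inside
its footprint minus the plots converted to agriculture by ``y`` (closed:
``plot.year <= y``).  Plots are clipped to baseline forest before
subtraction so a plot digitized over non-forest cannot double-count.  All
areas come from polygon geometry in the equal-area CRS; hectares = m²/10⁴.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
import shapely

M2_PER_HA = 1e4


@dataclass
class ForestLossRecord:
    community_id: str
    resource_class: str
    forest_area_t0_ha: float
    forest_area_t1_ha: float
    loss_abs_ha: float
    loss_rel_pct: float


def _converted_union(plots: pd.DataFrame, year: int):
    sel = plots[plots["year"] <= year] if len(plots) else plots
    if not len(sel):
        return None
    return shapely.union_all(list(sel["geometry"]))


def forest_area_in(
    footprint,
    baseline_forest,
    plots: pd.DataFrame,
    year: int,
) -> float:
    """Remaining forest area (ha) inside ``footprint`` at ``year``.

    ``baseline_forest`` is the baseline forest geometry (polygon /
    multipolygon).  Plots with ``year`` attribute ≤ the requested year are
    subtracted after clipping to the baseline forest and the footprint.
    """
    base = baseline_forest.intersection(footprint)
    converted = _converted_union(plots, year)
    if converted is None:
        return base.area / M2_PER_HA
    lost = base.intersection(converted)
    return (base.area - lost.area) / M2_PER_HA


def loss_record(
    footprint,
    baseline_forest,
    plots: pd.DataFrame,
    t0: int,
    t1: int,
    community_id: str = "",
    resource_class: str = "",
) -> ForestLossRecord:
    """Forest loss between two epochs, relative to the footprint's t0 forest."""
    if t0 >= t1:
        raise ValueError("t0 must precede t1")
    area_t0 = forest_area_in(footprint, baseline_forest, plots, t0)
    area_t1 = forest_area_in(footprint, baseline_forest, plots, t1)
    loss = area_t0 - area_t1
    rel = 100.0 * loss / area_t0 if area_t0 > 0 else 0.0
    return ForestLossRecord(
        community_id=community_id,
        resource_class=resource_class,
        forest_area_t0_ha=area_t0,
        forest_area_t1_ha=area_t1,
        loss_abs_ha=loss,
        loss_rel_pct=rel,
    )


def loss_table(
    footprints: pd.DataFrame,
    baseline_forest,
    plots: pd.DataFrame,
    t0: int,
    t1: int,
) -> pd.DataFrame:
    """Per-community loss records for a footprint set (one resource class)."""
    if t0 >= t1:
        raise ValueError("t0 must precede t1")
    # the converted unions are shared by every footprint; build them once
    converted = {y: _converted_union(plots, y) for y in (t0, t1)}
    records = []
    for _, fp in footprints.iterrows():
        base = baseline_forest.intersection(fp["geometry"])
        areas = {}
        for y in (t0, t1):
            if converted[y] is None:
                areas[y] = base.area / M2_PER_HA
            else:
                areas[y] = (base.area - base.intersection(converted[y]).area) / M2_PER_HA
        loss = areas[t0] - areas[t1]
        rel = 100.0 * loss / areas[t0] if areas[t0] > 0 else 0.0
        records.append(
            {
                "community_id": fp["community_id"],
                "resource_class": fp["resource_class"],
                "forest_area_t0_ha": areas[t0],
                "forest_area_t1_ha": areas[t1],
                "loss_abs_ha": loss,
                "loss_rel_pct": rel,
                "county": fp.get("county"),
            }
        )
    return pd.DataFrame(records)


def count_above_threshold(records: pd.DataFrame, threshold_pct: float) -> int:
    """Number of communities whose relative loss strictly exceeds the
    threshold (e.g. 'lost more than 50% of their resource base')."""
    if not 0 <= threshold_pct <= 100:
        raise ValueError("threshold_pct must be in [0, 100]")
    if not len(records):
        return 0
    return int((records["loss_rel_pct"] > threshold_pct).sum())
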