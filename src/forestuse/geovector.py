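"""GeoJSON I/O for pandas DataFrames carrying a shapely ``geometry`` column.

All vector layers in the package are ordinary DataFrames whose ``geometry``
column holds shapely objects; attribute columns are plain scalars.  This
keeps the whole stack on numpy/pandas/shapely with no extra geospatial
dependency, at the cost of a single, explicit CRS convention: every layer
lives in the same projected equal-area CRS in meters.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

GEOMETRY = "geometry"


def write_geojson(df: pd.DataFrame, path: str | Path, crs: str | None = None) -> None:
    """Write a geometry-bearing DataFrame as a GeoJSON FeatureCollection."""
    path = Path(path)
    features = []
    for _, row in df.iterrows():
        props = {}
        for k, v in row.items():
            if k == GEOMETRY:
                continue
            if isinstance(v, (np.integer,)):
                v = int(v)
            elif isinstance(v, (np.floating,)):
                v = float(v)
            elif isinstance(v, (np.bool_,)):
                v = bool(v)
            props[k] = None if (isinstance(v, float) and np.isnan(v)) else v
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(row[GEOMETRY]),
                "properties": props,
            }
        )
    collection: dict = {"type": "FeatureCollection", "features": features}
    if crs:
        collection["crs_note"] = crs
    path.write_text(json.dumps(collection))


def read_geojson(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"vector layer not found: {path}")
    collection = json.loads(path.read_text())
    records = []
    for feat in collection.get("features", []):
        rec = dict(feat.get("properties") or {})
        rec[GEOMETRY] = shape(feat["geometry"])
        records.append(rec)
    if not records:
        return pd.DataFrame(columns=[GEOMETRY])
    df = pd.DataFrame.from_records(records)
    # geometry last for readability
    cols = [c for c in df.columns if c != GEOMETRY] + [GEOMETRY]
    return df[cols]
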