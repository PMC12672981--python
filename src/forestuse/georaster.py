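"""Minimal georeferenced raster container with GeoTIFF I/O.

A :class:`Raster` is a numpy grid (``(rows, cols)`` or ``(bands, rows,
cols)``) plus a north-up affine georeference in a projected equal-area CRS
(units: meters).  GeoTIFF round-tripping uses :mod:`tifffile` with the
standard ``ModelPixelScale`` / ``ModelTiepoint`` tags; auxiliary metadata
(band labels, nodata, CRS description) travels in the image description as
JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
import tifffile

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922

DEFAULT_CRS = "LOCAL_EQUAL_AREA_METERS"


@dataclass
class Raster:
    """Grid + georeference.  Row 0 is the northernmost row."""

    data: np.ndarray
    x_min: float
    y_max: float
    pixel_size: float
    crs: str = DEFAULT_CRS
    band_labels: list[str] | None = None
    nodata: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.ndim not in (2, 3):
            raise ValueError("raster data must be 2-D or 3-D (bands first)")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    # -- geometry of the grid -------------------------------------------------

    @property
    def n_bands(self) -> int:
        return 1 if self.data.ndim == 2 else self.data.shape[0]

    @property
    def n_rows(self) -> int:
        return self.data.shape[-2]

    @property
    def n_cols(self) -> int:
        return self.data.shape[-1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(x_min, y_min, x_max, y_max) of the full grid."""
        return (
            self.x_min,
            self.y_max - self.n_rows * self.pixel_size,
            self.x_min + self.n_cols * self.pixel_size,
            self.y_max,
        )

    @property
    def pixel_area_m2(self) -> float:
        return self.pixel_size**2

    def center_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """1-D arrays of pixel-center x (per column) and y (per row)."""
        xs = self.x_min + (np.arange(self.n_cols) + 0.5) * self.pixel_size
        ys = self.y_max - (np.arange(self.n_rows) + 0.5) * self.pixel_size
        return xs, ys

    def center_grids(self) -> tuple[np.ndarray, np.ndarray]:
        """2-D meshgrids of pixel-center coordinates (shape rows × cols)."""
        xs, ys = self.center_coords()
        return np.meshgrid(xs, ys)

    def xy_to_rowcol(self, x: float, y: float) -> tuple[int, int]:
        col = int(np.floor((x - self.x_min) / self.pixel_size))
        row = int(np.floor((self.y_max - y) / self.pixel_size))
        return row, col

    def geometry_mask(self, geometry) -> np.ndarray:
        """Boolean (rows × cols) mask of pixels whose *center* lies strictly
        inside ``geometry`` (deterministic pixel-center-in-polygon rule).

        Only the window under the geometry's bounding box is tested."""
        mask = np.zeros((self.n_rows, self.n_cols), bool)
        gx0, gy0, gx1, gy1 = shapely.bounds(geometry)
        px = self.pixel_size
        j0 = max(0, int(np.floor((gx0 - self.x_min) / px)))
        j1 = min(self.n_cols, int(np.ceil((gx1 - self.x_min) / px)))
        i0 = max(0, int(np.floor((self.y_max - gy1) / px)))
        i1 = min(self.n_rows, int(np.ceil((self.y_max - gy0) / px)))
        if j1 <= j0 or i1 <= i0:
            return mask
        xs = self.x_min + (np.arange(j0, j1) + 0.5) * px
        ys = self.y_max - (np.arange(i0, i1) + 0.5) * px
        gx, gy = np.meshgrid(xs, ys)
        mask[i0:i1, j0:j1] = shapely.contains_xy(
            geometry, gx.ravel(), gy.ravel()
        ).reshape(i1 - i0, j1 - j0)
        return mask

    def like(self, data: np.ndarray, **kw) -> "Raster":
        """New raster on the same grid."""
        return Raster(
            data,
            self.x_min,
            self.y_max,
            self.pixel_size,
            crs=self.crs,
            **kw,
        )

    # -- I/O ------------------------------------------------------------------

    def write(self, path: str | Path) -> None:
        path = Path(path)
        desc = json.dumps(
            {
                "crs": self.crs,
                "band_labels": self.band_labels,
                "nodata": self.nodata,
                "meta": self.meta,
            }
        )
        extratags = [
            (
                _TAG_MODEL_PIXEL_SCALE,
                "d",
                3,
                (float(self.pixel_size), float(self.pixel_size), 0.0),
            ),
            (
                _TAG_MODEL_TIEPOINT,
                "d",
                6,
                (0.0, 0.0, 0.0, float(self.x_min), float(self.y_max), 0.0),
            ),
        ]
        tifffile.imwrite(
            path, self.data, description=desc, extratags=extratags, metadata=None
        )

    @classmethod
    def read(cls, path: str | Path) -> "Raster":
        path = Path(path)
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            page = tif.pages[0]
            scale = page.tags[_TAG_MODEL_PIXEL_SCALE].value
            tiepoint = page.tags[_TAG_MODEL_TIEPOINT].value
            desc = page.description or "{}"
        info = json.loads(desc)
        return cls(
            data,
            x_min=float(tiepoint[3]),
            y_max=float(tiepoint[4]),
            pixel_size=float(scale[0]),
            crs=info.get("crs", DEFAULT_CRS),
            band_labels=info.get("band_labels"),
            nodata=info.get("nodata"),
            meta=info.get("meta") or {},
        )
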