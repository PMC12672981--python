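"""Annual NDVI phenology and the Ecosystem Services Supply Index (ESSI).

ESSI = NDVI_mean × (1 − NDVI_CV): high where productivity (annual NDVI
mean) is high and its intra-annual variability (coefficient of variation)
is low, i.e. where carbon gains are both large and stable through the year.
Composites flagged by QA (clouds, shadows, aerosols) are excluded before
the annual statistics; ESSI is min–max normalized to [0, 1], by default
jointly across epochs so change is comparable between years.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import box

from .georaster import Raster

logger = logging.getLogger(__name__)


@dataclass
class AnnualPhenology:
    """Per-pixel annual NDVI statistics for one year."""

    year: int
    ndvi_mean: np.ndarray
    ndvi_cv: np.ndarray
    valid: np.ndarray
    grid: Raster  # georeference template


@dataclass
class ESSILayer:
    year: int
    essi_raw: np.ndarray
    valid: np.ndarray
    grid: Raster
    essi_norm: np.ndarray | None = None
    normalization_bounds: tuple[float, float] | None = None


def annual_phenology(
    ndvi_stack: Raster, qa_stack: Raster, year: int, min_composites: int = 10
) -> AnnualPhenology:
    """Per-pixel NDVI mean and CV over QA-valid composites.

    CV uses the sample standard deviation (n−1).  A pixel is invalid when
    fewer than ``min_composites`` composites survive QA or its mean is ≤ 0
    (water / bare surfaces, where CV is meaningless).
    """
    nd = np.asarray(ndvi_stack.data, float)
    qa = np.asarray(qa_stack.data, bool)
    if nd.ndim != 3 or nd.shape[0] == 0:
        raise ValueError("NDVI stack must be 3-D with at least one composite")
    if nd.shape != qa.shape:
        raise ValueError("NDVI and QA stacks are misaligned")
    if (
        ndvi_stack.pixel_size != qa_stack.pixel_size
        or ndvi_stack.x_min != qa_stack.x_min
        or ndvi_stack.y_max != qa_stack.y_max
    ):
        raise ValueError("NDVI and QA grids are misaligned")

    count = qa.sum(axis=0)
    masked = np.where(qa, nd, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.nanmean(masked, axis=0)
        # sample SD needs >= 2 observations
        sd = np.nanstd(masked, axis=0, ddof=1)
        cv = np.where(mean != 0, sd / mean, np.nan)
    valid = (count >= min_composites) & (mean > 0) & np.isfinite(cv)
    mean = np.where(valid, mean, np.nan)
    cv = np.where(valid, cv, np.nan)
    return AnnualPhenology(year=year, ndvi_mean=mean, ndvi_cv=cv, valid=valid, grid=ndvi_stack)


def essi_raw(phenology: AnnualPhenology) -> ESSILayer:
    """Raw ESSI = NDVI_mean × (1 − NDVI_CV); invalid pixels propagate as NaN.
    Raw values may be negative when CV > 1; normalization handles the range."""
    raw = phenology.ndvi_mean * (1.0 - phenology.ndvi_cv)
    raw = np.where(phenology.valid, raw, np.nan)
    return ESSILayer(
        year=phenology.year, essi_raw=raw, valid=phenology.valid, grid=phenology.grid
    )


def normalize_essi(layers: list[ESSILayer], joint: bool = True) -> list[ESSILayer]:
    """Min–max normalize raw ESSI to [0, 1].

    With ``joint=True`` (default) the bounds are the min/max over the valid
    pixels of *all* supplied epochs, so normalized values are comparable
    across years; ``joint=False`` normalizes each epoch on its own bounds.
    A constant raster maps to all zeros with a logged warning.
    """
    if not layers:
        raise ValueError("no ESSI layers supplied")

    def _bounds(vals: np.ndarray) -> tuple[float, float]:
        finite = vals[np.isfinite(vals)]
        if finite.size == 0:
            raise ValueError("no valid pixels to normalize")
        return float(finite.min()), float(finite.max())

    if joint:
        lo, hi = _bounds(np.concatenate([l.essi_raw.ravel() for l in layers]))
        bounds = [(lo, hi)] * len(layers)
    else:
        bounds = [_bounds(l.essi_raw.ravel()) for l in layers]

    out = []
    for layer, (lo, hi) in zip(layers, bounds):
        if hi == lo:
            logger.warning("constant ESSI raster: normalized values set to 0")
            norm = np.where(layer.valid, 0.0, np.nan)
        else:
            norm = (layer.essi_raw - lo) / (hi - lo)
        out.append(
            ESSILayer(
                year=layer.year,
                essi_raw=layer.essi_raw,
                valid=layer.valid,
                grid=layer.grid,
                essi_norm=norm,
                normalization_bounds=(lo, hi),
            )
        )
    return out


def zonal_mean(layer: ESSILayer, geometry, use_norm: bool = True) -> float:
    """Mean ESSI over the pixels whose center falls inside ``geometry``.

    Inclusion is strict pixel-center-in-polygon.  Raises if the geometry
    misses the raster entirely; returns NaN when no valid pixel center is
    included.
    """
    grid = layer.grid
    if not shapely.intersects(geometry, box(*grid.bounds)):
        raise ValueError("geometry does not intersect the raster extent")
    values = layer.essi_norm if (use_norm and layer.essi_norm is not None) else layer.essi_raw
    mask = grid.geometry_mask(geometry)
    sel = values[mask & layer.valid]
    sel = sel[np.isfinite(sel)]
    return float(sel.mean()) if sel.size else float("nan")
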