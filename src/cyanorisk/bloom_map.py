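"""Bloom thresholding and county-level bloom coverage.

Cyanobacterial cell density relates to phycocyanin (PC) through a log-linear
calibration, log10(cells/ml) = slope·log10(PC μg/L) + intercept.  Inverting
it at the WHO recreational guideline of 20,000 cells/ml gives the PC level
marking a significant bloom (≈ 4.11 μg/L with the default calibration);
4 μg/L is used as the operational threshold as a precaution.  Pixels at or
above the threshold are bloom pixels, and a county's bloom coverage is the
percentage of its area covered by bloom pixels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely

from .rasters import GridSpec, PigmentRaster
from .regions import CountyMap

logger = logging.getLogger(__name__)

__all__ = [
    "BloomThreshold",
    "cells_from_pc",
    "pc_from_cells",
    "derived_pc_threshold",
    "bloom_mask",
    "county_coverage",
]


@dataclass(frozen=True)
class BloomThreshold:
    """Log10-linear cell-abundance calibration and operational PC threshold."""

    cells_per_ml: float = 20_000.0     # WHO recreational guideline density
    slope: float = 0.360               # log10(cells) per log10(PC)
    intercept: float = 4.08            # log10(cells) at PC = 1 ug/L
    pc_threshold_ug_L: float = 4.0     # precautionary operational threshold

    def __post_init__(self) -> None:
        if self.cells_per_ml <= 0 or self.pc_threshold_ug_L <= 0:
            raise ValueError("thresholds must be positive")
        if self.slope == 0:
            raise ValueError("slope must be nonzero")
        if self.intercept <= 0:
            raise ValueError("intercept must be positive")


def cells_from_pc(pc, t: BloomThreshold | None = None):
    """Cell density (cells/ml) from PC concentration (μg/L), pc > 0."""
    t = t or BloomThreshold()
    pc = np.asarray(pc, dtype=float)
    if np.any(pc <= 0):
        raise ValueError("pc must be > 0 for the log-linear abundance relation")
    out = 10.0 ** (t.slope * np.log10(pc) + t.intercept)
    return out if out.ndim else float(out)


def pc_from_cells(cells, t: BloomThreshold | None = None):
    """PC concentration (μg/L) from cell density (cells/ml), cells > 0."""
    t = t or BloomThreshold()
    cells = np.asarray(cells, dtype=float)
    if np.any(cells <= 0):
        raise ValueError("cells must be > 0")
    out = 10.0 ** ((np.log10(cells) - t.intercept) / t.slope)
    return out if out.ndim else float(out)


def derived_pc_threshold(t: BloomThreshold | None = None) -> float:
    """PC level (μg/L) equivalent to the guideline cell density."""
    t = t or BloomThreshold()
    return float(pc_from_cells(t.cells_per_ml, t))


def bloom_mask(pig: PigmentRaster, t: BloomThreshold | None = None) -> np.ndarray:
    """Binary bloom raster: water pixel with PC at or above the threshold.

    The comparison is ``>=``: boundary pixels count as bloom, matching the
    precautionary lowering of the derived 4.11 μg/L to 4 μg/L.
    """
    t = t or BloomThreshold()
    return pig.water_mask & (pig.pc >= t.pc_threshold_ug_L)


def county_coverage(mask: np.ndarray, counties: CountyMap, grid: GridSpec,
                    water_mask: np.ndarray | None = None,
                    denominator: str = "county_area") -> pd.DataFrame:
    """Aggregate a bloom mask to county coverage percentages.

    Each pixel is assigned to the county containing its center (standard
    zonal-statistics convention).  Coverage is
    ``100 · bloom_pixel_count · pixel_area / county_area`` by default;
    ``denominator="water_area"`` divides by the county's water-pixel area
    instead.

    Returns a DataFrame with columns county_id, coverage_pct, water_pixels,
    bloom_pixels, total_pixels, aligned with ``counties``.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid.shape:
        raise ValueError("mask shape does not match grid")
    if water_mask is None:
        water_mask = mask
    water_mask = np.asarray(water_mask, dtype=bool)
    if denominator not in ("county_area", "water_area"):
        raise ValueError("denominator must be 'county_area' or 'water_area'")

    xs, ys = grid.pixel_centers()
    bloom_flat = mask.ravel()
    water_flat = water_mask.ravel()

    rows = []
    for cid, poly in zip(counties.ids, counties.polygons):
        minx, miny, maxx, maxy = poly.bounds
        cand = np.flatnonzero((xs >= minx) & (xs <= maxx) &
                              (ys >= miny) & (ys <= maxy))
        if cand.size:
            inside = cand[shapely.contains_xy(poly, xs[cand], ys[cand])]
        else:
            inside = cand
        total = int(inside.size)
        n_water = int(water_flat[inside].sum())
        n_bloom = int(bloom_flat[inside].sum())
        if total == 0:
            logger.warning("county %s overlaps no pixel centers; coverage 0", cid)
            pct = 0.0
        elif denominator == "county_area":
            pct = 100.0 * n_bloom * grid.pixel_area / poly.area
        else:
            pct = 100.0 * n_bloom / n_water if n_water else 0.0
        rows.append((cid, pct, n_water, n_bloom, total))

    return pd.DataFrame(rows, columns=["county_id", "coverage_pct",
                                       "water_pixels", "bloom_pixels",
                                       "total_pixels"])
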