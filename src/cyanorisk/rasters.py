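"""Gridded raster containers for reflectance scenes and pigment maps.

Rasters are plain 2-D numpy arrays tied to a :class:`GridSpec` describing the
geolocation of pixel (row, col): pixel centers sit at
``(origin_x + (col + 0.5) * dx, origin_y + (row + 0.5) * dy)``.  Scenes are
stored on disk as ``.npz`` bundles with a JSON sidecar holding the grid
metadata and band wavelengths, so every artifact stays inspectable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

__all__ = ["GridSpec", "ReflectanceScene", "PigmentRaster"]

BAND_WAVELENGTHS_NM = (620, 665, 705, 779)


@dataclass(frozen=True)
class GridSpec:
    """Geolocation of a raster: origin corner, cell size, pixel counts."""

    origin_x: float
    origin_y: float
    dx: float
    dy: float
    n_cols: int
    n_rows: int

    def __post_init__(self) -> None:
        if self.dx <= 0 or self.dy <= 0:
            raise ValueError("cell sizes must be positive")
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("pixel counts must be >= 1")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def pixel_area(self) -> float:
        return self.dx * self.dy

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Flattened (x, y) coordinates of all pixel centers, row-major."""
        xs = self.origin_x + (np.arange(self.n_cols) + 0.5) * self.dx
        ys = self.origin_y + (np.arange(self.n_rows) + 0.5) * self.dy
        xx, yy = np.meshgrid(xs, ys)
        return xx.ravel(), yy.ravel()


def _check_grid(grid: GridSpec, *arrays: np.ndarray) -> None:
    for a in arrays:
        if a.shape != grid.shape:
            raise ValueError(f"array shape {a.shape} != grid shape {grid.shape}")


@dataclass
class ReflectanceScene:
    """Four-band water-leaving reflectance (dimensionless) plus water mask.

    Bands are centered at 620, 665, 705 and 779 nm — the spectral regions
    where phycocyanin absorbs (620), chlorophyll-a absorbs (665), both
    pigments are nearly transparent (705) and particulate backscatter
    dominates (779).
    """

    B620: np.ndarray
    B665: np.ndarray
    B705: np.ndarray
    B779: np.ndarray
    water_mask: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        self.water_mask = np.asarray(self.water_mask, dtype=bool)
        for name in ("B620", "B665", "B705", "B779"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        _check_grid(self.grid, self.B620, self.B665, self.B705, self.B779,
                    self.water_mask)
        for name in ("B620", "B665", "B705", "B779"):
            band = getattr(self, name)
            if np.any(band[self.water_mask] < 0):
                raise ValueError(f"negative reflectance in {name} on water pixels")

    def save(self, path) -> None:
        _save_bundle(path, self.grid,
                     {"B620": self.B620, "B665": self.B665, "B705": self.B705,
                      "B779": self.B779, "water_mask": self.water_mask},
                     extra={"band_wavelengths_nm": list(BAND_WAVELENGTHS_NM)})

    @classmethod
    def load(cls, path) -> "ReflectanceScene":
        arrays, grid = _load_bundle(path)
        return cls(B620=arrays["B620"], B665=arrays["B665"], B705=arrays["B705"],
                   B779=arrays["B779"], water_mask=arrays["water_mask"], grid=grid)


@dataclass
class PigmentRaster:
    """Per-pixel phycocyanin and chlorophyll-a concentrations (μg/L).

    ``qa_mask`` is True where retrieval was non-physical (invalid band
    ratios, negative concentrations clamped to zero, or land pixels).
    """

    pc: np.ndarray
    chl: np.ndarray
    qa_mask: np.ndarray
    water_mask: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        self.pc = np.asarray(self.pc, dtype=float)
        self.chl = np.asarray(self.chl, dtype=float)
        self.qa_mask = np.asarray(self.qa_mask, dtype=bool)
        self.water_mask = np.asarray(self.water_mask, dtype=bool)
        _check_grid(self.grid, self.pc, self.chl, self.qa_mask, self.water_mask)
        if np.any(self.pc < 0) or np.any(self.chl < 0):
            raise ValueError("pigment concentrations must be non-negative")

    def save(self, path) -> None:
        _save_bundle(path, self.grid,
                     {"pc": self.pc, "chl": self.chl, "qa_mask": self.qa_mask,
                      "water_mask": self.water_mask},
                     extra={"units": "ug/L"})

    @classmethod
    def load(cls, path) -> "PigmentRaster":
        arrays, grid = _load_bundle(path)
        return cls(pc=arrays["pc"], chl=arrays["chl"], qa_mask=arrays["qa_mask"],
                   water_mask=arrays["water_mask"], grid=grid)


def _sidecar_path(path) -> Path:
    return Path(str(path) + ".json")


def _save_bundle(path, grid: GridSpec, arrays: dict, extra: dict | None = None) -> None:
    np.savez(path, **arrays)
    meta = {"grid": asdict(grid)}
    if extra:
        meta.update(extra)
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=1)


def _load_bundle(path):
    npz_path = Path(path)
    if not npz_path.suffix:
        npz_path = npz_path.with_suffix(".npz")
    with np.load(npz_path) as data:
        arrays = {k: data[k] for k in data.files}
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        sidecar = _sidecar_path(npz_path)
    with open(sidecar) as fh:
        meta = json.load(fh)
    return arrays, GridSpec(**meta["grid"])
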