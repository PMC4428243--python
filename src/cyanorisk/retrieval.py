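"""Semi-empirical band-ratio retrieval of phycocyanin and chlorophyll-a.

The nested band-ratio model estimates pigment absorption from four
water-leaving reflectance bands.  With ``B(λ)`` the dimensionless
reflectance, ``a_w(λ)`` pure-water absorption (m⁻¹) and ``b_b`` the
particulate backscattering coefficient (m⁻¹):

    a_chl(665) = { (B705/B665)·(a_w(709)+b_b) − b_b − a_w(665) } / γ
    a_pc(620)  = { (B705/B620)·(a_w(709)+b_b) − b_b − a_w(620) } / δ
                 − ε·a_chl(665)

with γ = 0.68 (chlorophyll-a specific-absorption correction), δ = 0.82
(phycocyanin correction factor) and ε = 0.24 (chlorophyll cross-talk into
the 620 nm band).  ``b_b`` is estimated from the 779 nm band alone, where
pigment absorption is negligible.  Absorptions convert to concentrations by
dividing by the pigment-specific absorption coefficient (μg/L ≡ mg/m³).

Negative retrievals are clamped to zero and flagged in a QA mask —
concentrations are physical quantities, and the downstream bloom-threshold
step requires non-negative inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import yaml

from .rasters import GridSpec, PigmentRaster, ReflectanceScene

__all__ = [
    "OpticalConstants",
    "estimate_backscatter",
    "chl_absorption",
    "pc_absorption",
    "pc_concentration",
    "chl_concentration",
    "retrieve_pigments",
    "max_value_composite",
]


@dataclass(frozen=True)
class OpticalConstants:
    """Constants of the band-ratio model, all strictly positive.

    Pure-water absorptions are the standard published values used by the
    source algorithm family; the single-band backscatter estimator at
    779 nm is ``b_b = c1·B779 / (c2 − c3·B779)``.  Every constant is
    overridable for sensitivity analysis.
    """

    a_w620: float = 0.281  # pure-water absorption at 620 nm, 1/m
    a_w665: float = 0.401  # 1/m
    a_w709: float = 0.727  # 1/m
    gamma: float = 0.68    # chl-a specific-absorption correction
    delta: float = 0.82    # phycocyanin correction factor
    epsilon: float = 0.24  # chl-a cross-term at 620 nm
    pc_specific_absorption: float = 0.007    # m^2/mg
    chl_specific_absorption: float = 0.0153  # m^2/mg
    bb_c1: float = 1.61
    bb_c2: float = 0.082
    bb_c3: float = 0.6

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if not value > 0:
                raise ValueError(f"optical constant {name} must be > 0")

    def replace(self, **kwargs) -> "OpticalConstants":
        return replace(self, **kwargs)

    @classmethod
    def from_yaml(cls, path) -> "OpticalConstants":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def estimate_backscatter(B779, consts: OpticalConstants | None = None):
    """Particulate backscatter b_b (m⁻¹) from the 779 nm band alone.

    ``b_b = c1·B779 / (c2 − c3·B779)``; strictly increasing on the valid
    domain ``0 ≤ B779 < c2/c3``.  Outside it (or for negative reflectance)
    the result is NaN, to be flagged by the caller's QA mask.
    """
    consts = consts or OpticalConstants()
    B779 = np.asarray(B779, dtype=float)
    denom = consts.bb_c2 - consts.bb_c3 * B779
    with np.errstate(divide="ignore", invalid="ignore"):
        b_b = consts.bb_c1 * B779 / denom
    b_b = np.where((denom > 0) & (B779 >= 0), b_b, np.nan)
    return b_b if b_b.ndim else float(b_b)


def chl_absorption(B665, B705, b_b, consts: OpticalConstants | None = None):
    """Chlorophyll-a absorption a_chl(665) in m⁻¹ (may be negative).

    NaN where B665 ≤ 0 or b_b is invalid; the caller clamps and flags.
    """
    consts = consts or OpticalConstants()
    B665 = np.asarray(B665, dtype=float)
    B705 = np.asarray(B705, dtype=float)
    b_b = np.asarray(b_b, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        bracket = (B705 / B665) * (consts.a_w709 + b_b) - b_b - consts.a_w665
    a = np.where(B665 > 0, bracket / consts.gamma, np.nan)
    return a if a.ndim else float(a)


def pc_absorption(B620, B705, b_b, a_chl665, consts: OpticalConstants | None = None):
    """Phycocyanin absorption a_pc(620) in m⁻¹ (may be negative).

    NaN where B620 ≤ 0 or any input is invalid.
    """
    consts = consts or OpticalConstants()
    B620 = np.asarray(B620, dtype=float)
    B705 = np.asarray(B705, dtype=float)
    b_b = np.asarray(b_b, dtype=float)
    a_chl665 = np.asarray(a_chl665, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        bracket = (B705 / B620) * (consts.a_w709 + b_b) - b_b - consts.a_w620
        a = bracket / consts.delta - consts.epsilon * a_chl665
    a = np.where(B620 > 0, a, np.nan)
    return a if a.ndim else float(a)


def pc_concentration(a_pc620, consts: OpticalConstants | None = None):
    """Convert a_pc(620) (m⁻¹) to phycocyanin concentration (μg/L)."""
    consts = consts or OpticalConstants()
    return np.asarray(a_pc620, dtype=float) / consts.pc_specific_absorption


def chl_concentration(a_chl665, consts: OpticalConstants | None = None):
    """Convert a_chl(665) (m⁻¹) to chlorophyll-a concentration (μg/L)."""
    consts = consts or OpticalConstants()
    return np.asarray(a_chl665, dtype=float) / consts.chl_specific_absorption


def retrieve_pigments(scene: ReflectanceScene,
                      consts: OpticalConstants | None = None,
                      b_b=None) -> PigmentRaster:
    """Full per-pixel retrieval chain on the water pixels of a scene.

    b_b is estimated from B779 unless supplied directly (an array or scalar
    override, useful because the pure band-ratio part of the model is
    invariant to uniform scaling of the bands only when b_b is held fixed).
    Non-physical pixels (invalid ratios, negative pigments clamped to 0)
    and land pixels are flagged in ``qa_mask``.
    """
    consts = consts or OpticalConstants()
    if b_b is None:
        b_b = estimate_backscatter(scene.B779, consts)
    b_b = np.broadcast_to(np.asarray(b_b, dtype=float), scene.grid.shape)

    a_chl = chl_absorption(scene.B665, scene.B705, b_b, consts)
    a_pc = pc_absorption(scene.B620, scene.B705, b_b, a_chl, consts)

    invalid = ~np.isfinite(a_chl) | ~np.isfinite(a_pc)
    clamped = ((a_chl < 0) | (a_pc < 0)) & ~invalid
    a_chl = np.where(np.isfinite(a_chl), np.clip(a_chl, 0.0, None), 0.0)
    a_pc = np.where(np.isfinite(a_pc), np.clip(a_pc, 0.0, None), 0.0)

    water = scene.water_mask
    pc = np.where(water, pc_concentration(a_pc, consts), 0.0)
    chl = np.where(water, chl_concentration(a_chl, consts), 0.0)
    qa = ~water | invalid | clamped
    return PigmentRaster(pc=pc, chl=chl, qa_mask=qa, water_mask=water,
                         grid=scene.grid)


def max_value_composite(scenes: list[PigmentRaster]) -> PigmentRaster:
    """Per-pixel maximum across dates: the maximum value composite.

    The multi-date mosaic keeps each pixel's highest retrieved value,
    suppressing cloud gaps and transient misses.  Flagged pixels do not
    contribute unless a pixel is flagged in every scene, in which case it
    stays flagged (qa = AND of the per-scene flags).
    """
    if not scenes:
        raise ValueError("need at least one scene to composite")
    grid = scenes[0].grid
    for s in scenes[1:]:
        if s.grid != grid:
            raise ValueError("composite requires identical grids")

    pc_stack = np.stack([s.pc for s in scenes])
    chl_stack = np.stack([s.chl for s in scenes])
    qa_stack = np.stack([s.qa_mask for s in scenes])
    all_flagged = qa_stack.all(axis=0)

    # exclude flagged pixels from the max unless every scene flags them
    neg = np.where(qa_stack, -np.inf, 0.0)
    pc = np.max(pc_stack + neg, axis=0)
    chl = np.max(chl_stack + neg, axis=0)
    pc = np.where(all_flagged, np.max(pc_stack, axis=0), pc)
    chl = np.where(all_flagged, np.max(chl_stack, axis=0), chl)

    water = scenes[0].water_mask.copy()
    return PigmentRaster(pc=pc, chl=chl, qa_mask=all_flagged, water_mask=water,
                         grid=grid)
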