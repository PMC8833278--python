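"""Automated construction of planning/optimization structures.

Builds the helper contours the planning pipeline needs: the anterior-beam
avoidance structure (oral cavity minus target, plus dental hardware, plus a
margin of half the spot FWHM), the posterior-beam shoulder avoidance, the
posterior-neck midline structure, a skin rind, the below-shoulder SFO region
and external-minus-target.

All morphology is Euclidean and voxel-center based: a dilation by margin m
adds every voxel whose center lies within m of an input voxel center.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields

import numpy as np
from scipy import ndimage

from .core import ImageGrid, StructureSet

__all__ = [
    "AutomationStructures",
    "expand",
    "erode",
    "anisotropic_expand",
    "build_ant_avoid",
    "build_post_avoid",
    "build_postneck",
    "build_skin_rind",
    "build_sfo_region",
    "build_all",
]

log = logging.getLogger(__name__)

_EPS = 1e-9


@dataclass
class AutomationStructures:
    """The masks the automation stage constructs."""

    ant_avoid: np.ndarray
    post_avoid: np.ndarray
    postneck: np.ndarray
    skin_rind: np.ndarray
    sfo_region: np.ndarray
    external_minus_target: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def expand(mask: np.ndarray, margin_mm: float, spacing_mm) -> np.ndarray:
    """Euclidean dilation: voxels whose center is within ``margin_mm`` of the mask."""
    if margin_mm < 0:
        raise ValueError("expansion margin must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    if margin_mm == 0 or not mask.any():
        return mask.copy()
    dist = ndimage.distance_transform_edt(~mask, sampling=spacing_mm)
    return dist <= margin_mm + _EPS


def erode(mask: np.ndarray, margin_mm: float, spacing_mm) -> np.ndarray:
    """Euclidean erosion: mask voxels farther than ``margin_mm`` from the complement."""
    if margin_mm < 0:
        raise ValueError("erosion margin must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    if margin_mm == 0 or not mask.any():
        return mask.copy()
    dist = ndimage.distance_transform_edt(mask, sampling=spacing_mm)
    return dist > margin_mm + _EPS


def anisotropic_expand(
    mask: np.ndarray,
    spacing_mm,
    x_margin_mm: float = 0.0,
    y_neg_margin_mm: float = 0.0,
) -> np.ndarray:
    """Per-axis half-space-restricted dilation (used for PostNeck).

    Grows ``mask`` by up to ``x_margin_mm`` in +/-x and up to
    ``y_neg_margin_mm`` in -y (posterior) only, never in +y or +/-z.
    Offsets are accepted per-axis (rectangular footprint, corners included).
    """
    spacing = np.broadcast_to(np.asarray(spacing_mm, dtype=float), (3,))
    kx = int(np.floor(x_margin_mm / spacing[0] + _EPS))
    ky = int(np.floor(y_neg_margin_mm / spacing[1] + _EPS))
    if kx == 0 and ky == 0:
        return np.asarray(mask, dtype=bool).copy()
    foot = np.zeros((2 * kx + 1, 2 * ky + 1, 1), dtype=bool)
    foot[:, : ky + 1, 0] = True  # offsets dy in [-ky, 0]: posterior growth only
    return ndimage.binary_dilation(np.asarray(mask, dtype=bool), structure=foot)


def build_ant_avoid(
    oral_cavity: np.ndarray,
    dental: np.ndarray,
    ctv: np.ndarray,
    spacing_mm,
    margin_mm: float = 8.0,
    subtract_target: bool = True,
) -> np.ndarray:
    """Anterior-beam avoidance: (oral cavity minus target) union dental, expanded.

    The default 8 mm margin is half the 16 mm spot FWHM, so spots may sit next
    to, but not within a 50% dose fall-off of, the avoided region.
    """
    oral = np.asarray(oral_cavity, dtype=bool)
    if subtract_target:
        oral = oral & ~np.asarray(ctv, dtype=bool)
    seed = oral | np.asarray(dental, dtype=bool)
    return expand(seed, margin_mm, spacing_mm)


def build_post_avoid(grid: ImageGrid, apex_z_mm: float) -> np.ndarray:
    """Posterior-beam avoidance: every voxel with center below the shoulder apex."""
    z = grid.axis_coords(2)
    if apex_z_mm < z[0] or apex_z_mm > z[-1] + grid.spacing[2]:
        raise ValueError(
            f"shoulder apex z={apex_z_mm} mm is outside the grid z extent "
            f"[{z[0]}, {z[-1] + grid.spacing[2]}] mm"
        )
    below = z < apex_z_mm
    mask = np.zeros(grid.shape, dtype=bool)
    mask[:, :, below] = True
    return mask


def build_postneck(
    cord: np.ndarray,
    spacing_mm,
    lateral_margin_mm: float = 10.0,
    posterior_margin_mm: float = 10.0,
) -> np.ndarray:
    """Midline posterior-neck structure: cord grown laterally and posteriorly.

    The cord itself is subtracted, leaving the shell used for the midline
    max-dose objective.
    """
    cord = np.asarray(cord, dtype=bool)
    if not cord.any():
        raise ValueError("spinal cord mask is empty")
    grown = anisotropic_expand(
        cord, spacing_mm, x_margin_mm=lateral_margin_mm, y_neg_margin_mm=posterior_margin_mm
    )
    return grown & ~cord


def build_skin_rind(external: np.ndarray, spacing_mm, thickness_mm: float = 5.0) -> np.ndarray:
    """Skin rind: external minus its erosion by ``thickness_mm``."""
    if thickness_mm <= 0:
        raise ValueError("skin rind thickness must be > 0")
    external = np.asarray(external, dtype=bool)
    if not external.any():
        raise ValueError("external mask is empty")
    return external & ~erode(external, thickness_mm, spacing_mm)


def build_sfo_region(ctv: np.ndarray, grid: ImageGrid, apex_z_mm: float) -> np.ndarray:
    """Supraclavicular SFO region: the target below the shoulder apex plane."""
    z = grid.axis_coords(2)
    below = np.zeros(grid.shape, dtype=bool)
    below[:, :, z < apex_z_mm] = True
    return np.asarray(ctv, dtype=bool) & below


def build_all(
    grid: ImageGrid,
    structures: StructureSet,
    apex_z_mm: float,
    *,
    target_name: str = "CTV50",
    ant_avoid_margin_mm: float = 8.0,
    subtract_target_from_ant_avoid: bool = True,
    postneck_lateral_mm: float = 10.0,
    postneck_posterior_mm: float = 10.0,
    skin_rind_mm: float = 5.0,
) -> AutomationStructures:
    """Build every automation structure for a case (pure function of its inputs)."""
    sp = grid.spacing
    ctv = structures[target_name]
    dental = structures["dental"] if "dental" in structures else np.zeros(grid.shape, bool)
    oral = structures["oral_cavity"] if "oral_cavity" in structures else np.zeros(grid.shape, bool)
    autos = AutomationStructures(
        ant_avoid=build_ant_avoid(
            oral, dental, ctv, sp, margin_mm=ant_avoid_margin_mm,
            subtract_target=subtract_target_from_ant_avoid,
        ),
        post_avoid=build_post_avoid(grid, apex_z_mm),
        postneck=build_postneck(
            structures["spinal_cord"], sp,
            lateral_margin_mm=postneck_lateral_mm, posterior_margin_mm=postneck_posterior_mm,
        ),
        skin_rind=build_skin_rind(structures["external"], sp, thickness_mm=skin_rind_mm),
        sfo_region=build_sfo_region(ctv, grid, apex_z_mm),
        external_minus_target=structures["external"] & ~ctv,
    )
    vv = grid.voxel_volume_cm3()
    for name, mask in autos.as_dict().items():
        log.info("automation structure %-22s %8.1f cm^3", name, mask.sum() * vv)
    return autos
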