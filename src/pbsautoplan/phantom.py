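"""Seeded synthetic bilateral head-and-neck phantom.

Builds a voxelized stopping-power grid plus a structure set that mimics the
geometry of a bilateral H&N case: an external contour (head atop neck atop a
shoulder slab), a horseshoe-shaped CTV50 wrapping the midline with a
supraclavicular tail below the shoulder apex, peripheral OARs (parotids,
larynx, air-filled trachea, esophagus, spinal cord with a bony shell,
brainstem, brachial plexus), an oral cavity anterior to the target, and
optional high-density dental hardware.

The default geometry is fixed; a per-seed anatomical jitter moves structure
centers by a few millimetres so that different seeds give different but
topologically identical patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import CaseValidationError, ImageGrid, StructureSet

__all__ = ["PhantomSpec", "generate_phantom", "generate_toy_case"]

RSP_SOFT_TISSUE = 1.0
RSP_BONE = 1.4
RSP_AIR = 0.001
RSP_DENTAL = 7.0


@dataclass
class PhantomSpec:
    """Parameters of the synthetic bilateral H&N phantom.

    All lengths in mm. The defaults are tuned once so the CTV50 volume falls
    in the 350-540 cm^3 range typical of bilateral H&N nodal targets.
    """

    seed: int = 0
    spacing_mm: float = 4.0
    shape: tuple[int, int, int] = (56, 56, 72)

    # external contour (stacked elliptical cylinders)
    shoulder_top_mm: float = 64.0  # shoulder apex plane (z)
    neck_top_mm: float = 192.0  # neck/head transition (z)
    shoulder_half_axes: tuple[float, float] = (105.0, 80.0)
    neck_half_axes: tuple[float, float] = (55.0, 60.0)
    head_half_axes: tuple[float, float] = (75.0, 90.0)

    # horseshoe target: annulus wrapping the midline anteriorly and laterally,
    # open posteriorly around the spinal cord / posterior neck midline
    target_center_y_mm: float = -8.0
    target_inner_radius_mm: float = 26.0
    target_outer_radius_mm: float = 46.0
    target_open_half_angle_deg: float = 35.0  # posterior wedge left open
    target_inferior_mm: float = 44.0  # tail extends below the shoulder apex
    target_superior_mm: float = 208.0
    tail_top_mm: float = 100.0  # below this, only the lateral nodal arms remain
    tail_arm_angles_deg: tuple[float, float] = (45.0, 110.0)

    # OAR placement
    oral_cavity_center: tuple[float, float, float] = (0.0, 30.0, 190.0)
    oral_cavity_radii: tuple[float, float, float] = (22.0, 18.0, 22.0)
    parotid_center_x_mm: float = 58.0
    parotid_center_z_mm: float = 212.0
    parotid_radii: tuple[float, float, float] = (10.0, 13.0, 17.0)
    cord_center_y_mm: float = -30.0
    cord_radius_mm: float = 5.0
    cord_top_mm: float = 240.0
    bone_shell_outer_mm: float = 10.0
    larynx_center_y_mm: float = 10.0
    larynx_radius_mm: float = 6.0
    larynx_z_mm: tuple[float, float] = (100.0, 150.0)
    trachea_radius_mm: float = 7.0
    trachea_z_mm: tuple[float, float] = (16.0, 100.0)
    esophagus_center_y_mm: float = -4.0
    esophagus_radius_mm: float = 6.0
    esophagus_z_mm: tuple[float, float] = (16.0, 110.0)
    plexus_radius_mm: float = 4.0
    plexus_top: tuple[float, float, float] = (36.0, -14.0, 100.0)
    plexus_bottom: tuple[float, float, float] = (58.0, -18.0, 40.0)

    dental_hardware: bool = True
    dental_radius_mm: float = 6.0
    dental_offset: tuple[float, float, float] = (12.0, 4.0, 14.0)  # from oral cavity center

    jitter_mm: float = 2.0

    def __post_init__(self) -> None:
        if self.spacing_mm <= 0 or any(s <= 0 for s in self.shape):
            raise ValueError("phantom dimensions must be positive")
        if self.target_inferior_mm >= self.shoulder_top_mm:
            raise ValueError(
                "target inferior limit must extend below the shoulder apex "
                "(the supraclavicular region must exist)"
            )
        if self.oral_cavity_center[1] <= self.target_center_y_mm:
            raise ValueError("oral cavity must be anterior to the target midline")


def _coords(spec: PhantomSpec):
    n = spec.shape
    sp = spec.spacing_mm
    origin = np.array([-(n[0] - 1) / 2.0 * sp, -(n[1] - 1) / 2.0 * sp, sp / 2.0])
    x = origin[0] + sp * np.arange(n[0])
    y = origin[1] + sp * np.arange(n[1])
    z = origin[2] + sp * np.arange(n[2])
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    return origin, X, Y, Z


def _ellipsoid(X, Y, Z, center, radii):
    return (
        ((X - center[0]) / radii[0]) ** 2
        + ((Y - center[1]) / radii[1]) ** 2
        + ((Z - center[2]) / radii[2]) ** 2
    ) <= 1.0


def _vcyl(X, Y, Z, cx, cy, radius, z_lo, z_hi):
    """Vertical cylinder over z in [z_lo, z_hi)."""
    return (((X - cx) ** 2 + (Y - cy) ** 2) <= radius**2) & (Z >= z_lo) & (Z < z_hi)


def generate_phantom(spec: PhantomSpec | None = None):
    """Generate the phantom.

    Returns
    -------
    grid : ImageGrid
        Relative stopping power volume.
    structures : StructureSet
        CTV50, external, OARs, optional dental hardware.
    apex_z_mm : float
        Ground-truth shoulder apex plane (z, mm).
    """
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.seed)

    def jit(n=2):
        return rng.uniform(-spec.jitter_mm, spec.jitter_mm, size=n)

    origin, X, Y, Z = _coords(spec)

    # external: shoulder slab, neck, head
    ax, ay = spec.shoulder_half_axes
    external = ((X / ax) ** 2 + (Y / ay) ** 2 <= 1) & (Z < spec.shoulder_top_mm)
    nx_, ny_ = spec.neck_half_axes
    external |= ((X / nx_) ** 2 + (Y / ny_) ** 2 <= 1) & (Z >= spec.shoulder_top_mm) & (
        Z < spec.neck_top_mm
    )
    hx, hy = spec.head_half_axes
    external |= ((X / hx) ** 2 + (Y / hy) ** 2 <= 1) & (Z >= spec.neck_top_mm)

    # horseshoe CTV50: annulus wrapping midline, open anteriorly, with a
    # bilateral supraclavicular tail below the shoulder apex
    jx, jy = jit()
    cyl_r2 = (X - jx) ** 2 + (Y - spec.target_center_y_mm - jy) ** 2
    annulus = (cyl_r2 >= spec.target_inner_radius_mm**2) & (
        cyl_r2 <= spec.target_outer_radius_mm**2
    )
    theta = np.degrees(np.arctan2(X - jx, Y - spec.target_center_y_mm - jy))  # 0 = anterior
    horseshoe = annulus & (np.abs(theta) <= 180.0 - spec.target_open_half_angle_deg)
    ctv = horseshoe & (Z >= spec.target_inferior_mm) & (Z < spec.target_superior_mm)
    # below tail_top keep only the lateral supraclavicular nodal arms
    a0, a1 = spec.tail_arm_angles_deg
    ctv &= (Z >= spec.tail_top_mm) | ((np.abs(theta) >= a0) & (np.abs(theta) <= a1))

    if np.any(ctv & ~external):
        raise CaseValidationError("phantom spec makes the CTV exceed the external contour")

    # oral cavity (may overlap CTV anteriorly)
    oc_c = np.asarray(spec.oral_cavity_center) + np.r_[jit(), 0.0]
    oral = _ellipsoid(X, Y, Z, oc_c, spec.oral_cavity_radii)

    # parotids
    pj = jit()
    par_l = _ellipsoid(
        X, Y, Z, (spec.parotid_center_x_mm + pj[0], pj[1], spec.parotid_center_z_mm),
        spec.parotid_radii,
    )
    par_r = _ellipsoid(
        X, Y, Z, (-spec.parotid_center_x_mm + pj[0], pj[1], spec.parotid_center_z_mm),
        spec.parotid_radii,
    )

    # midline cylinders
    cy_j = spec.cord_center_y_mm + jit(1)[0] * 0.5
    cord = _vcyl(X, Y, Z, 0.0, cy_j, spec.cord_radius_mm, 0.0, spec.cord_top_mm)
    brainstem = _vcyl(X, Y, Z, 0.0, cy_j, spec.cord_radius_mm + 2.0, spec.cord_top_mm, 1e9)
    bone = _vcyl(X, Y, Z, 0.0, cy_j, spec.bone_shell_outer_mm, 0.0, spec.cord_top_mm) & ~cord
    larynx = _vcyl(X, Y, Z, 0.0, spec.larynx_center_y_mm, spec.larynx_radius_mm,
                   *spec.larynx_z_mm)
    trachea = _vcyl(X, Y, Z, 0.0, spec.larynx_center_y_mm, spec.trachea_radius_mm,
                    *spec.trachea_z_mm)
    esoph = _vcyl(X, Y, Z, 0.0, spec.esophagus_center_y_mm, spec.esophagus_radius_mm,
                  *spec.esophagus_z_mm)

    # brachial plexus: paired oblique cords interpolated between two endpoints
    top = np.asarray(spec.plexus_top)
    bot = np.asarray(spec.plexus_bottom)
    frac = np.clip((Z - bot[2]) / (top[2] - bot[2]), 0.0, 1.0)
    in_z = (Z >= bot[2]) & (Z <= top[2])
    plexus = np.zeros_like(external)
    for side in (+1.0, -1.0):
        cx = side * (bot[0] + frac * (top[0] - bot[0]))
        cy = bot[1] + frac * (top[1] - bot[1])
        plexus |= in_z & (((X - cx) ** 2 + (Y - cy) ** 2) <= spec.plexus_radius_mm**2)

    dental = np.zeros_like(external)
    if spec.dental_hardware:
        dx, dy, dz = spec.dental_offset
        for side in (+1.0, -1.0):
            c = (oc_c[0] + side * dx, oc_c[1] + dy, oc_c[2] + dz)
            dental |= _ellipsoid(X, Y, Z, c, (spec.dental_radius_mm,) * 3)
        dental &= oral  # hardware lives inside the oral-cavity region

    # stopping power map
    values = np.where(external, RSP_SOFT_TISSUE, 0.0)
    values[bone & external] = RSP_BONE
    values[trachea] = RSP_AIR
    values[dental] = RSP_DENTAL

    grid = ImageGrid(origin=origin, spacing=np.full(3, spec.spacing_mm), values=values)
    ss = StructureSet(grid=grid)
    ss.add("external", external, role="external")
    ss.add("CTV50", ctv & external, role="target")
    for name, mask in [
        ("oral_cavity", oral),
        ("parotid_l", par_l),
        ("parotid_r", par_r),
        ("spinal_cord", cord),
        ("brainstem", brainstem),
        ("larynx", larynx),
        ("trachea", trachea),
        ("esophagus", esoph),
        ("brachial_plexus", plexus),
    ]:
        ss.add(name, mask & external, role="oar")
    ss.add("dental", dental, role="oar")
    ss.validate()
    return grid, ss, float(spec.shoulder_top_mm)


def generate_toy_case():
    """Deterministic miniature case (16^3 voxels, 4 mm grid) for unit oracles.

    Water box external, a 3x3x3-voxel target, a single-voxel oral cavity and a
    single-voxel-column spinal cord. Voxel counts are fixed constants:
    external 1728 (12^3), CTV 27, oral cavity 1, cord 8.
    """
    n = 16
    sp = 4.0
    origin = np.array([-(n - 1) / 2.0 * sp] * 3)
    values = np.zeros((n, n, n))
    external = np.zeros((n, n, n), dtype=bool)
    external[2:14, 2:14, 2:14] = True
    values[external] = 1.0

    ctv = np.zeros_like(external)
    ctv[7:10, 7:10, 7:10] = True
    oral = np.zeros_like(external)
    oral[8, 11, 8] = True  # anterior midline single voxel
    cord = np.zeros_like(external)
    cord[8, 4, 4:12] = True

    grid = ImageGrid(origin=origin, spacing=np.full(3, sp), values=values)
    ss = StructureSet(grid=grid)
    ss.add("external", external, role="external")
    ss.add("CTV50", ctv, role="target")
    ss.add("oral_cavity", oral, role="oar")
    ss.add("spinal_cord", cord, role="oar")
    ss.add("dental", np.zeros_like(external), role="oar")
    ss.validate()
    apex_z = float(origin[2] + 6 * sp)  # mid-grid shoulder plane
    return grid, ss, apex_z
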