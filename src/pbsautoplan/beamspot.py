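"""Beam geometry, water-equivalent ray tracing, and spot placement.

The machine model follows a Bragg-Kleeman range-energy law R(E) = alpha*E^p
with p = 1.77 and alpha calibrated so the minimum deliverable energy of
97.5 MeV treats to exactly 7.5 cm of water. Spot spacing follows the
80%-overlap rule s = 2*sigma_air*sqrt(2*ln(1/0.8)); the default 16 mm FWHM
gives s ~ 9.08 mm.

Spot placement covers the beam's-eye-view projection of the target with a
lateral lattice and energy layers on a fixed WET grid, then removes spots
that (a) sit shallower than the 0.5 cm minimum radiological depth, (b) need
less than the machine's minimum energy, or (c, d) whose ray passes through,
or whose Bragg position lies within, the beam's avoidance structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.spatial import cKDTree

from .core import Beam, ImageGrid, Scenario, Spot, StructureSet
from .geometry import BeamFrame, apply_scenario, effective_beam_geometry

__all__ = [
    "MachineModel",
    "RayTrace",
    "AvoidanceEliminatesBeamError",
    "trace_wet",
    "default_beams",
    "place_spots",
    "spot_peak_positions",
]


class AvoidanceEliminatesBeamError(RuntimeError):
    """Raised when avoidance filtering removes every spot of a beam."""


@dataclass
class MachineModel:
    """PBS delivery-system constants.

    ``min_spot_mu`` is the smallest deliverable spot weight; together with the
    150x max/min cap it defines the deliverable MU window.
    """

    min_energy_mev: float = 97.5
    anchor_range_cm: float = 7.5  # range in water at the minimum energy
    bragg_kleeman_p: float = 1.77
    spot_fwhm_mm: float = 16.0
    overlap_level: float = 0.8  # spots overlap at this dose fall-off
    min_spot_mu: float = 0.2
    max_min_mu_ratio: float = 150.0
    layer_spacing_wet_mm: float = 5.0
    distal_margin_wet_mm: float = 5.0  # extra layer depth beyond the distal target WET
    min_spot_depth_cm: float = 0.5
    lateral_margin_sigma: float = 1.0  # lattice margin beyond the projected target
    # analytic kernel constants
    peak_plateau_ratio: float = 3.5
    sigma_r_coeff: float = 0.012  # range straggling: coeff * R^expo, cm
    sigma_r_expo: float = 0.935
    energy_spread_range_pct: float = 4.5  # beam energy spread as % of range
    k_mcs: float = 0.05  # lateral growth: sigma^2 = sigma_air^2 + (k*depth)^2

    @property
    def alpha(self) -> float:
        return self.anchor_range_cm / self.min_energy_mev**self.bragg_kleeman_p

    @property
    def sigma_air_mm(self) -> float:
        return self.spot_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))

    @property
    def spot_spacing_mm(self) -> float:
        return 2.0 * self.sigma_air_mm * np.sqrt(2.0 * np.log(1.0 / self.overlap_level))

    def range_from_energy(self, energy_mev):
        """Proton range in water (cm) from energy (MeV), Bragg-Kleeman."""
        return self.alpha * np.asarray(energy_mev, dtype=float) ** self.bragg_kleeman_p

    def energy_from_range(self, range_cm):
        """Inverse of :meth:`range_from_energy`."""
        return (np.asarray(range_cm, dtype=float) / self.alpha) ** (1.0 / self.bragg_kleeman_p)

    def sigma_at_depth_mm(self, depth_cm):
        """Lateral spot sigma (mm) at radiological depth (cm) in patient."""
        d = np.maximum(np.asarray(depth_cm, dtype=float), 0.0)
        return np.sqrt(self.sigma_air_mm**2 + (10.0 * self.k_mcs * d) ** 2)

    def sigma_r_cm(self, range_cm):
        """Bragg-peak width (cm): range straggling plus beam energy spread."""
        r = np.asarray(range_cm, dtype=float)
        straggle = self.sigma_r_coeff * r**self.sigma_r_expo
        spread = self.energy_spread_range_pct / 100.0 * r
        return np.sqrt(straggle**2 + spread**2)

    def to_dict(self) -> dict:
        return asdict(self)


# --------------------------------------------------------------------------
# Siddon ray tracing
# --------------------------------------------------------------------------


@dataclass
class RayTrace:
    """One traced ray: crossed voxels with cumulative WET (cm, incl. shifter)."""

    beam_index: int
    lateral_uv: tuple[float, float]
    voxels: np.ndarray  # (n, 3) int indices, in traversal order
    t_edges_mm: np.ndarray  # (n + 1,) parametric positions of segment edges
    seg_mm: np.ndarray  # (n,) segment lengths
    wet_end_cm: np.ndarray  # cumulative WET at each segment end
    shifter_cm: float
    origin: np.ndarray  # ray point at t = 0 (isocenter plane)
    direction: np.ndarray
    missed_external: bool = False

    @property
    def wet_start_cm(self) -> np.ndarray:
        return np.concatenate([[self.shifter_cm], self.wet_end_cm[:-1]])

    def t_at_wet(self, wet_cm: float) -> float:
        """Parametric depth at which cumulative WET reaches ``wet_cm``."""
        if self.wet_end_cm.size == 0 or wet_cm <= self.shifter_cm:
            return float(self.t_edges_mm[0]) if self.t_edges_mm.size else 0.0
        k = int(np.searchsorted(self.wet_end_cm, wet_cm))
        if k >= self.wet_end_cm.size:
            return float(self.t_edges_mm[-1])
        w0 = self.wet_start_cm[k]
        w1 = self.wet_end_cm[k]
        f = 0.0 if w1 <= w0 else (wet_cm - w0) / (w1 - w0)
        return float(self.t_edges_mm[k] + f * self.seg_mm[k])

    def point_at_wet(self, wet_cm: float) -> np.ndarray:
        return self.origin + self.t_at_wet(wet_cm) * self.direction

    def first_block_wet(self, mask: np.ndarray) -> float:
        """Cumulative WET at entry of the first traversed voxel inside ``mask``."""
        if self.voxels.size == 0:
            return np.inf
        inside = mask[self.voxels[:, 0], self.voxels[:, 1], self.voxels[:, 2]]
        hits = np.nonzero(inside)[0]
        if hits.size == 0:
            return np.inf
        return float(self.wet_start_cm[hits[0]])


def trace_wet(
    grid: ImageGrid,
    beam: Beam,
    lateral_uv: tuple[float, float],
    beam_index: int = 0,
    scenario: Scenario | None = None,
) -> RayTrace:
    """Siddon-style traversal accumulating stopping power x path length.

    The ray runs parallel to the beam axis through lateral position
    ``(u, v)`` mm on the isocenter plane; WET includes the beam's
    range-shifter WET and the scenario's range scale (patient material only).
    """
    frame = apply_scenario(scenario)
    lat, up, d, iso = effective_beam_geometry(beam, beam_index, frame)
    u, v = lateral_uv
    p0 = iso + u * lat + v * up
    lo = grid.origin - grid.spacing / 2.0
    hi = lo + np.array(grid.shape) * grid.spacing

    # slab intersection of the ray with the grid bounding box
    t_lo, t_hi = -np.inf, np.inf
    for a in range(3):
        if abs(d[a]) < 1e-12:
            if not (lo[a] <= p0[a] <= hi[a]):
                t_lo, t_hi = 1.0, 0.0  # no intersection
                break
        else:
            ta = (lo[a] - p0[a]) / d[a]
            tb = (hi[a] - p0[a]) / d[a]
            t_lo = max(t_lo, min(ta, tb))
            t_hi = min(t_hi, max(ta, tb))
    empty = RayTrace(
        beam_index=beam_index, lateral_uv=(u, v), voxels=np.zeros((0, 3), int),
        t_edges_mm=np.zeros(0), seg_mm=np.zeros(0), wet_end_cm=np.zeros(0),
        shifter_cm=beam.range_shifter_wet_cm, origin=p0, direction=d, missed_external=True,
    )
    if not t_lo < t_hi:
        return empty

    ts = [np.array([t_lo, t_hi])]
    for a in range(3):
        if abs(d[a]) > 1e-12:
            planes = lo[a] + grid.spacing[a] * np.arange(grid.shape[a] + 1)
            ta = (planes - p0[a]) / d[a]
            ts.append(ta[(ta > t_lo) & (ta < t_hi)])
    t_edges = np.unique(np.concatenate(ts))
    if t_edges.size < 2:
        return empty
    t_mid = 0.5 * (t_edges[:-1] + t_edges[1:])
    pts = p0 + t_mid[:, None] * d
    ijk = np.floor((pts - grid.origin) / grid.spacing + 0.5).astype(int)
    ok = np.all((ijk >= 0) & (ijk < np.array(grid.shape)), axis=1)
    ijk = ijk[ok]
    seg = np.diff(t_edges)[ok]
    # rebuild contiguous edges for the kept segments
    t_starts = t_edges[:-1][ok]
    t_edges_kept = np.concatenate([t_starts, [t_starts[-1] + seg[-1]]]) if seg.size else np.zeros(0)
    rsp = grid.values[ijk[:, 0], ijk[:, 1], ijk[:, 2]]
    dwet = frame.range_scale * rsp * seg / 10.0
    wet_end = beam.range_shifter_wet_cm + np.cumsum(dwet)
    return RayTrace(
        beam_index=beam_index, lateral_uv=(u, v), voxels=ijk, t_edges_mm=t_edges_kept,
        seg_mm=seg, wet_end_cm=wet_end, shifter_cm=beam.range_shifter_wet_cm,
        origin=p0, direction=d,
        missed_external=bool(dwet.sum() < 1e-9),
    )


# --------------------------------------------------------------------------
# standard beams
# --------------------------------------------------------------------------

STANDARD_GANTRY_DEG = (30.0, 330.0, 135.0, 225.0)


def default_beams(
    grid: ImageGrid,
    structures: StructureSet,
    machine: MachineModel | None = None,
    target_name: str = "CTV50",
    anterior_gap_cm: float = 5.0,
    posterior_gap_cm: float = 10.0,
    range_shifter_wet_cm: float = 7.5,
) -> list[Beam]:
    """The standard four-field modified-X configuration (30/330/135/225 deg).

    Anterior beams carry the anterior avoidance binding and a 5 cm air gap
    from the most proximal external point; posterior beams carry the shoulder
    avoidance and a 10 cm gap. All beams get the 7.5 cm WET range shifter and
    share the target-centroid isocenter.
    """
    machine = machine or MachineModel()
    if "external" not in structures or not structures["external"].any():
        raise ValueError("external structure is required to set air gaps")
    ctv = structures[target_name]
    iso = grid.voxel_centers(np.flatnonzero(ctv)).mean(axis=0)
    ext_pts = grid.voxel_centers(np.flatnonzero(structures["external"]))
    beams = []
    for g in STANDARD_GANTRY_DEG:
        anterior = Beam(g, iso).is_anterior
        gap = anterior_gap_cm if anterior else posterior_gap_cm
        beam = Beam(
            gantry_deg=g,
            isocenter_mm=iso,
            range_shifter_wet_cm=range_shifter_wet_cm,
            air_gap_cm=gap,
            avoidance=("ant_avoid",) if anterior else ("post_avoid",),
            sigma_air_mm=machine.sigma_air_mm,
        )
        _, _, d = beam.axes()
        t_entry = float(((ext_pts - iso) @ d).min())
        beam.snout_t_mm = t_entry - gap * 10.0
        beams.append(beam)
    return beams


# --------------------------------------------------------------------------
# spot placement
# --------------------------------------------------------------------------


def place_spots(
    grid: ImageGrid,
    structures: StructureSet,
    beams: list[Beam],
    machine: MachineModel | None = None,
    avoid_masks: dict[str, np.ndarray] | None = None,
    target_name: str = "CTV50",
) -> list[Spot]:
    """Place unit-weight spots for every beam (lattice + energy layers + filters)."""
    machine = machine or MachineModel()
    avoid_masks = avoid_masks or {}
    ctv = structures[target_name]
    if not ctv.any():
        raise ValueError("target mask is empty")
    ctv_pts = grid.voxel_centers(np.flatnonzero(ctv))
    s = machine.spot_spacing_mm
    margin = machine.lateral_margin_sigma * machine.sigma_air_mm
    keep_radius = max(margin, 0.75 * s)
    dlayer_cm = machine.layer_spacing_wet_mm / 10.0

    spots: list[Spot] = []
    for bi, beam in enumerate(beams):
        bf = BeamFrame(grid, beam, beam_index=bi)
        uvt = bf.points_to_uvt(ctv_pts)
        wet = bf.wet_at_points(ctv_pts)
        tree = cKDTree(uvt[:, :2])

        def lattice(lo, hi):
            k0 = int(np.floor((lo - margin) / s))
            k1 = int(np.ceil((hi + margin) / s))
            return s * np.arange(k0, k1 + 1)

        uu = lattice(uvt[:, 0].min(), uvt[:, 0].max())
        vv = lattice(uvt[:, 1].min(), uvt[:, 1].max())
        UU, VV = np.meshgrid(uu, vv, indexing="ij")
        nodes = np.column_stack([UU.ravel(), VV.ravel()])
        dist, _ = tree.query(nodes, k=1)
        nodes = nodes[dist <= keep_radius]

        wmax = float(wet.max())
        shifter = beam.range_shifter_wet_cm
        avoid = np.zeros(grid.shape, dtype=bool)
        for name in beam.avoidance:
            if name in avoid_masks:
                avoid |= avoid_masks[name]
            elif name in structures:
                avoid |= structures[name]
        use_avoid = bool(avoid.any())

        n_before_avoid = 0
        n_after_avoid = 0
        for u, v in nodes:
            nb = tree.query_ball_point([u, v], r=s)
            if not nb:
                continue
            w_nb = wet[nb]
            distal = machine.distal_margin_wet_mm / 10.0
            k0 = int(np.floor((wmax + distal - w_nb.max()) / dlayer_cm))
            k1 = int(np.ceil((wmax - w_nb.min()) / dlayer_cm))
            layers = wmax - dlayer_cm * np.arange(k0, k1 + 1)
            near = np.abs(layers[:, None] - w_nb[None, :]).min(axis=1) <= dlayer_cm / 2 + 1e-9
            # distal range margin: keep layers just beyond the deepest target WET
            near |= (layers > w_nb.max()) & (layers <= w_nb.max() + distal + 1e-9)
            layers = layers[near]
            # (a) minimum radiological depth, (b) minimum energy
            layers = layers[layers - shifter >= machine.min_spot_depth_cm - 1e-12]
            layers = layers[layers >= machine.range_from_energy(machine.min_energy_mev) - 1e-12]
            if layers.size == 0:
                continue
            n_before_avoid += layers.size
            if use_avoid:
                ray = trace_wet(grid, beam, (u, v), beam_index=bi)
                w_block = ray.first_block_wet(avoid)
                layers = layers[layers < w_block]  # (c) through or (d) within
            n_after_avoid += layers.size
            for wl in layers:
                spots.append(
                    Spot(beam=bi, energy_mev=float(machine.energy_from_range(wl)),
                         x_mm=float(u), y_mm=float(v), weight_mu=1.0)
                )
        if n_after_avoid == 0:
            raise AvoidanceEliminatesBeamError(
                f"avoidance eliminates beam at gantry {beam.gantry_deg:g} deg "
                f"({n_before_avoid} spots before avoidance filtering)"
            )
    return spots


def spot_peak_positions(
    grid: ImageGrid,
    beams: list[Beam],
    spots: list[Spot],
    machine: MachineModel | None = None,
    scenario: Scenario | None = None,
) -> np.ndarray:
    """World position (n, 3) of each spot's Bragg peak, by per-ray WET inversion."""
    machine = machine or MachineModel()
    out = np.zeros((len(spots), 3))
    cache: dict[tuple[int, float, float], RayTrace] = {}
    for i, sp in enumerate(spots):
        key = (sp.beam, sp.x_mm, sp.y_mm)
        if key not in cache:
            cache[key] = trace_wet(grid, beams[sp.beam], (sp.x_mm, sp.y_mm),
                                   beam_index=sp.beam, scenario=scenario)
        ray = cache[key]
        out[i] = ray.point_at_wet(float(machine.range_from_energy(sp.energy_mev)))
    return out
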