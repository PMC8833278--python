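"""Beam-frame geometry shared by spot placement and the dose engine.

A beam frame is the orthonormal system (lat, up, dir) of a beam after a
scenario's rigid perturbation has been folded in: patient translation and
rotation are realized as the inverse transform of the beam geometry about the
isocenter, per-beam shifts translate only that beam's frame, and the range
scale multiplies accumulated water-equivalent thickness (WET) of patient
material (never the range shifter).

:class:`BeamFrame` resamples the stopping-power grid onto a beam-aligned
lattice and accumulates WET along the depth axis, giving fast lookups of
(u, v, t) coordinates and radiological depth for arbitrary world points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import Beam, ImageGrid, Scenario

__all__ = ["ScenarioFrame", "apply_scenario", "BeamFrame"]

MAX_ROTATION_DEG = 15.0


def _rot_y(deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rot_z(deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


@dataclass
class ScenarioFrame:
    """Rigid transform parameters of one scenario, ready for beam geometry."""

    rotation: np.ndarray  # patient rotation matrix (roll about y, then yaw about z)
    translation_mm: np.ndarray
    range_scale: float
    per_beam_mm: dict[int, np.ndarray]


def apply_scenario(scenario: Scenario | None) -> ScenarioFrame:
    """Validate a scenario and return its transform frame.

    Rotations beyond 15 degrees are rejected (outside the small-angle validity
    of the rigid-beam-transform model).
    """
    if scenario is None:
        scenario = Scenario()
    if abs(scenario.roll_deg) > MAX_ROTATION_DEG or abs(scenario.yaw_deg) > MAX_ROTATION_DEG:
        raise ValueError("scenario rotation exceeds 15 degrees (small-angle validity)")
    rot = _rot_z(scenario.yaw_deg) @ _rot_y(scenario.roll_deg)
    return ScenarioFrame(
        rotation=rot,
        translation_mm=np.asarray(scenario.translation_mm, dtype=float),
        range_scale=float(scenario.range_scale),
        per_beam_mm=scenario.per_beam_mm,
    )


def effective_beam_geometry(
    beam: Beam, beam_index: int, frame: ScenarioFrame
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Beam axes and isocenter with the scenario folded in (inverse transform)."""
    lat, up, d = beam.axes()
    rt = frame.rotation.T  # inverse patient rotation applied to the beam
    lat, up, d = rt @ lat, rt @ up, rt @ d
    shift = frame.translation_mm + frame.per_beam_mm.get(beam_index, np.zeros(3))
    iso = beam.isocenter_mm - shift
    return lat, up, d, iso


class BeamFrame:
    """Beam-aligned resampling of a stopping-power grid with accumulated WET.

    Point p(u, v, t) = iso + u*lat + v*up + t*dir; t increases with depth and
    is 0 at the isocenter plane. WET values are in cm and include the beam's
    range-shifter WET.
    """

    def __init__(
        self,
        grid: ImageGrid,
        beam: Beam,
        beam_index: int = 0,
        scenario: Scenario | None = None,
        step_mm: float | None = None,
    ):
        self.grid = grid
        self.beam = beam
        self.frame = apply_scenario(scenario)
        self.lat, self.up, self.dir, self.iso = effective_beam_geometry(
            beam, beam_index, self.frame
        )
        self.step = float(step_mm or min(grid.spacing))

        # beam-frame extents from the grid bounding box corners
        lo = grid.origin - grid.spacing / 2.0
        hi = grid.origin + (np.array(grid.shape) - 0.5) * grid.spacing
        corners = np.array([[a, b, c] for a in (lo[0], hi[0]) for b in (lo[1], hi[1])
                            for c in (lo[2], hi[2])])
        rel = corners - self.iso
        axes = np.stack([self.lat, self.up, self.dir])
        proj = rel @ axes.T
        pad = self.step
        self.u0, self.v0, self.t0 = proj.min(axis=0) - pad
        u1, v1, t1 = proj.max(axis=0) + pad
        self.nu = int(np.ceil((u1 - self.u0) / self.step)) + 1
        self.nv = int(np.ceil((v1 - self.v0) / self.step)) + 1
        self.nt = int(np.ceil((t1 - self.t0) / self.step)) + 1

        self._rsp = self._resample(grid.values, order=1)
        dwet = self.frame.range_scale * self._rsp * (self.step / 10.0)  # cm per step
        self.wet_cm = (
            beam.range_shifter_wet_cm + np.cumsum(dwet, axis=2) - 0.5 * dwet
        )

    # -- sampling helpers --------------------------------------------------

    def _bf_points(self):
        u = self.u0 + self.step * np.arange(self.nu)
        v = self.v0 + self.step * np.arange(self.nv)
        t = self.t0 + self.step * np.arange(self.nt)
        return u, v, t

    def _resample(self, values: np.ndarray, order: int) -> np.ndarray:
        u, v, t = self._bf_points()
        U, V, T = np.meshgrid(u, v, t, indexing="ij")
        pts = (
            self.iso
            + U[..., None] * self.lat
            + V[..., None] * self.up
            + T[..., None] * self.dir
        )
        idx = (pts - self.grid.origin) / self.grid.spacing
        coords = np.moveaxis(idx, -1, 0)
        return ndimage.map_coordinates(
            np.asarray(values, dtype=float), coords, order=order, mode="constant", cval=0.0
        )

    def resample_mask(self, mask: np.ndarray) -> np.ndarray:
        """Nearest-neighbour resampling of a binary mask onto the beam frame."""
        return self._resample(mask.astype(float), order=0) >= 0.5

    def points_to_uvt(self, points: np.ndarray) -> np.ndarray:
        rel = np.atleast_2d(points) - self.iso
        return rel @ np.stack([self.lat, self.up, self.dir]).T

    def wet_at_points(self, points: np.ndarray) -> np.ndarray:
        """WET (cm, incl. shifter) at world points, interpolated in the beam frame."""
        uvt = self.points_to_uvt(points)
        idx = (uvt - np.array([self.u0, self.v0, self.t0])) / self.step
        return ndimage.map_coordinates(self.wet_cm, idx.T, order=1, mode="nearest")

    def block_wet_cm(self, avoid_bf: np.ndarray) -> np.ndarray:
        """Per (u, v) ray: WET at which the avoidance mask is first entered.

        ``avoid_bf`` is the avoidance mask already resampled onto this frame.
        Rays never touching the mask get +inf.
        """
        hit = avoid_bf.astype(bool)
        first = np.where(hit.any(axis=2), hit.argmax(axis=2), -1)
        out = np.full((self.nu, self.nv), np.inf)
        ii, jj = np.nonzero(first >= 0)
        kk = first[ii, jj]
        # WET at entry of the blocking voxel (half a step proximal of its center)
        dstep = self.frame.range_scale * self._rsp[ii, jj, kk] * (self.step / 10.0)
        out[ii, jj] = self.wet_cm[ii, jj, kk] - 0.5 * dstep
        return out

    def sample_uv(self, field: np.ndarray, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        """Nearest-neighbour lookup of a per-(u, v) field at lateral positions."""
        iu = np.clip(np.rint((np.asarray(u) - self.u0) / self.step).astype(int), 0, self.nu - 1)
        iv = np.clip(np.rint((np.asarray(v) - self.v0) / self.step).astype(int), 0, self.nv - 1)
        return field[iu, iv]
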