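"""Analytic pencil-beam dose engine and influence matrices.

Each spot deposits a separable dose kernel: a depth-dose curve (plateau rising
into a Gaussian Bragg peak of width sigma_R(R) at the spot's range R) times a
normalized lateral Gaussian whose width grows with depth,
sigma(d)^2 = sigma_air^2 + (k_mcs * d)^2. The absolute scale is set so one MU
gives one CGE at the Bragg peak in water; the lateral profile integrates to 1
at every depth and is truncated at 3.5 sigma.

Scenario perturbations enter through the beam frame (see
:mod:`pbsautoplan.geometry`): patient shifts/rotations as the inverse beam
transform, range uncertainty as a multiplicative WET scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse, special

from .beamspot import MachineModel
from .core import Beam, ImageGrid, Plan, Scenario, Spot
from .geometry import BeamFrame

__all__ = ["InfluenceMatrix", "DoseCalculator", "spot_dose", "compute_influence"]

LATERAL_TRUNC_SIGMA = 3.5
DISTAL_TRUNC_SIGMA = 5.0


def depth_dose(wet_cm: np.ndarray, range_cm: float, machine: MachineModel) -> np.ndarray:
    """Normalized depth-dose: plateau 1 rising into a Gaussian peak of height
    ``peak_plateau_ratio`` at ``range_cm``."""
    sr = float(machine.sigma_r_cm(range_cm))
    x = (np.asarray(wet_cm, dtype=float) - range_cm) / sr
    return 0.5 * special.erfc(x / np.sqrt(2.0)) + (
        machine.peak_plateau_ratio - 0.5
    ) * np.exp(-0.5 * x**2)


def _spot_scale(machine: MachineModel, range_cm: float, shifter_cm: float) -> float:
    """MU-to-CGE scale: unit weight gives 1 CGE at the peak in water."""
    sigma_peak = machine.sigma_at_depth_mm(max(range_cm - shifter_cm, 0.0))
    return 2.0 * np.pi * float(sigma_peak) ** 2 / machine.peak_plateau_ratio


@dataclass
class InfluenceMatrix:
    """Sparse dose-per-MU map: rows are selected voxels, columns are spots."""

    matrix: sparse.csr_matrix  # (n_voxels, n_spots), CGE per MU
    voxel_ids: np.ndarray  # flat grid indices of the rows
    scenario: Scenario
    spot_beams: np.ndarray  # beam index per column

    def dose(self, weights: np.ndarray) -> np.ndarray:
        return self.matrix @ np.asarray(weights, dtype=np.float64)

    def beam_dose(self, weights: np.ndarray, beam_index: int) -> np.ndarray:
        w = np.where(self.spot_beams == beam_index, weights, 0.0)
        return self.matrix @ w


class DoseCalculator:
    """Caches per-(beam, scenario) beam frames and row projections."""

    def __init__(self, grid: ImageGrid, beams: list[Beam], machine: MachineModel | None = None):
        self.grid = grid
        self.beams = beams
        self.machine = machine or MachineModel()
        self._frames: dict = {}

    def _scenario_key(self, beam_index: int, scenario: Scenario):
        s = scenario
        pb = tuple(sorted((k, tuple(v)) for k, v in s.per_beam_mm.items()))
        return (beam_index, tuple(s.translation_mm), s.roll_deg, s.yaw_deg, s.range_scale, pb)

    def beam_frame(self, beam_index: int, scenario: Scenario) -> BeamFrame:
        key = self._scenario_key(beam_index, scenario)
        if key not in self._frames:
            self._frames[key] = BeamFrame(
                self.grid, self.beams[beam_index], beam_index=beam_index, scenario=scenario
            )
        return self._frames[key]

    def clear_cache(self) -> None:
        self._frames.clear()

    # -- row projections ----------------------------------------------------

    def _rows(self, beam_index: int, scenario: Scenario, voxel_ids: np.ndarray):
        bf = self.beam_frame(beam_index, scenario)
        pts = self.grid.voxel_centers(voxel_ids)
        uvt = bf.points_to_uvt(pts)
        wet = bf.wet_at_points(pts)
        order = np.argsort(uvt[:, 0], kind="stable")
        return bf, uvt[order], wet[order], order

    def spot_dose_rows(
        self,
        spot: Spot,
        uvt_sorted: np.ndarray,
        wet_sorted: np.ndarray,
        order: np.ndarray,
        shifter_cm: float,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Dose per unit MU of one spot on pre-projected, U-sorted rows.

        Returns (row positions into the *original* voxel_ids order, dose).
        """
        m = self.machine
        R = float(m.range_from_energy(spot.energy_mev))
        sr = float(m.sigma_r_cm(R))
        depth = np.maximum(wet_sorted - shifter_cm, 0.0)
        # conservative candidate window from the deepest possible sigma
        sigma_max = float(m.sigma_at_depth_mm(max(R - shifter_cm, 0.0)) * 1.5 + 2.0)
        rad = LATERAL_TRUNC_SIGMA * sigma_max
        lo = int(np.searchsorted(uvt_sorted[:, 0], spot.x_mm - rad))
        hi = int(np.searchsorted(uvt_sorted[:, 0], spot.x_mm + rad))
        if hi <= lo:
            return np.zeros(0, int), np.zeros(0)
        sel = slice(lo, hi)
        dv = uvt_sorted[sel, 1] - spot.y_mm
        keep = (np.abs(dv) <= rad) & (wet_sorted[sel] <= R + DISTAL_TRUNC_SIGMA * sr)
        if not keep.any():
            return np.zeros(0, int), np.zeros(0)
        idx = np.arange(lo, hi)[keep]
        du = uvt_sorted[idx, 0] - spot.x_mm
        dvk = uvt_sorted[idx, 1] - spot.y_mm
        sigma = m.sigma_at_depth_mm(depth[idx])
        rho2 = du**2 + dvk**2
        inside = rho2 <= (LATERAL_TRUNC_SIGMA * sigma) ** 2
        if not inside.any():
            return np.zeros(0, int), np.zeros(0)
        idx = idx[inside]
        sigma = sigma[inside]
        rho2 = rho2[inside]
        dd = depth_dose(wet_sorted[idx], R, m)
        lat = np.exp(-0.5 * rho2 / sigma**2) / (2.0 * np.pi * sigma**2)
        dose = _spot_scale(m, R, shifter_cm) * spot.weight_mu * dd * lat
        return order[idx], dose


def spot_dose(
    grid: ImageGrid,
    beam: Beam,
    spot: Spot,
    scenario: Scenario | None = None,
    machine: MachineModel | None = None,
    voxel_ids: np.ndarray | None = None,
    beam_index: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sparse dose of one spot: (flat voxel indices, CGE per this spot's MU)."""
    scenario = scenario or Scenario()
    beams = [beam] * (beam_index + 1)  # pad so beam_index addresses this beam
    calc = DoseCalculator(grid, beams, machine)
    if voxel_ids is None:
        voxel_ids = np.arange(int(np.prod(grid.shape)))
    bf, uvt_s, wet_s, order = calc._rows(beam_index, scenario, voxel_ids)
    rows, dose = calc.spot_dose_rows(spot, uvt_s, wet_s, order, beam.range_shifter_wet_cm)
    return voxel_ids[rows], dose


def compute_influence(
    grid: ImageGrid,
    plan: Plan,
    scenario: Scenario | None = None,
    machine: MachineModel | None = None,
    voxel_ids: np.ndarray | None = None,
    calculator: DoseCalculator | None = None,
    size_cap: float = 4e9,
) -> InfluenceMatrix:
    """Stack spot-dose columns into a sparse influence matrix.

    ``voxel_ids`` restricts the rows (default: every grid voxel). A memory
    guard rejects problems whose rows x columns product exceeds ``size_cap``;
    use a coarser grid or a row restriction in that case.
    """
    scenario = scenario or Scenario()
    machine = machine or (calculator.machine if calculator else MachineModel())
    if voxel_ids is None:
        voxel_ids = np.arange(int(np.prod(grid.shape)))
    voxel_ids = np.asarray(voxel_ids)
    n_spots = len(plan.spots)
    if float(voxel_ids.size) * max(n_spots, 1) > size_cap:
        raise ValueError(
            f"influence problem size {voxel_ids.size} voxels x {n_spots} spots exceeds "
            f"the cap ({size_cap:g}); use a coarser dose grid or restrict the rows"
        )
    calc = calculator or DoseCalculator(grid, plan.beams, machine)
    spot_beams = plan.spot_beam_indices()

    rows_all: list[np.ndarray] = []
    cols_all: list[np.ndarray] = []
    vals_all: list[np.ndarray] = []
    for bi in range(len(plan.beams)):
        cols = np.flatnonzero(spot_beams == bi)
        if cols.size == 0:
            continue
        bf, uvt_s, wet_s, order = calc._rows(bi, scenario, voxel_ids)
        shifter = plan.beams[bi].range_shifter_wet_cm
        for c in cols:
            sp = plan.spots[c]
            unit = Spot(beam=sp.beam, energy_mev=sp.energy_mev, x_mm=sp.x_mm,
                        y_mm=sp.y_mm, weight_mu=1.0)
            r, d = calc.spot_dose_rows(unit, uvt_s, wet_s, order, shifter)
            if r.size:
                rows_all.append(r)
                cols_all.append(np.full(r.size, c, dtype=np.int64))
                vals_all.append(d.astype(np.float32))
    if rows_all:
        mat = sparse.coo_matrix(
            (np.concatenate(vals_all),
             (np.concatenate(rows_all), np.concatenate(cols_all))),
            shape=(voxel_ids.size, n_spots),
        ).tocsr()
    else:
        mat = sparse.csr_matrix((voxel_ids.size, n_spots), dtype=np.float32)
    return InfluenceMatrix(matrix=mat, voxel_ids=voxel_ids, scenario=scenario,
                           spot_beams=spot_beams)
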