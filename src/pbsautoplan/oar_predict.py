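"""Geometry-based OAR dose prediction from simulated isodose rings.

The model is a monotone non-increasing fall-off of dose (as a fraction of
prescription) versus Euclidean distance from the target surface. Isodose
rings are simulated around the target at every 10% of prescription dose; the
overlap of these rings with an OAR predicts its mean dose and DVH points.
Voxels in ring [k*10%, (k+1)*10%) are assigned the ring midpoint
(k*10% + 5%); voxels inside the target get full prescription.

The prediction is intended for structures peripheral to the target (parotids,
oral cavity, larynx, trachea) and is not used for structures the target
surrounds, such as the esophagus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import ImageGrid

__all__ = [
    "FalloffModel",
    "RingSet",
    "PREDICTED_OARS",
    "default_falloff",
    "calibrate_falloff",
    "simulate_rings",
    "predict_mean_dose",
    "predict_dvh_point",
    "predict_all",
]

#: structures the ring model predicts well (peripheral to the target);
#: the esophagus is deliberately excluded.
PREDICTED_OARS = ("parotid_l", "parotid_r", "oral_cavity", "larynx", "trachea")

TARGET_RING = 10  # ring label for voxels inside the target
N_RINGS = 10


@dataclass
class FalloffModel:
    """Piecewise-linear dose fall-off: distance (mm) -> fraction of prescription.

    Fractions are clipped to [0, 1], forced non-increasing, anchored at
    fraction(0) = 1 and 0 beyond the last knot.
    """

    knot_mm: np.ndarray
    knot_fraction: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.knot_mm, dtype=float)
        f = np.clip(np.asarray(self.knot_fraction, dtype=float), 0.0, 1.0)
        if d.size == 0 or d[0] != 0.0:
            d = np.concatenate([[0.0], d])
            f = np.concatenate([[1.0], f])
        f[0] = 1.0
        f = np.minimum.accumulate(f)  # enforce monotone non-increasing
        self.knot_mm = d
        self.knot_fraction = f

    def __call__(self, distance_mm) -> np.ndarray:
        return np.interp(np.asarray(distance_mm, dtype=float), self.knot_mm,
                         self.knot_fraction, left=1.0, right=0.0)

    def to_dict(self) -> dict:
        return {"knot_mm": self.knot_mm.tolist(), "knot_fraction": self.knot_fraction.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "FalloffModel":
        return cls(np.asarray(d["knot_mm"]), np.asarray(d["knot_fraction"]))


def default_falloff() -> FalloffModel:
    """Default fall-off when no calibration reference is supplied.

    100% at the target boundary, 50% at 8 mm (the half-FWHM distance at which
    a spot has fallen to half dose), 0 at 25 mm.
    """
    return FalloffModel(np.array([0.0, 8.0, 25.0]), np.array([1.0, 0.5, 0.0]))


def target_distance_mm(target: np.ndarray, grid: ImageGrid) -> np.ndarray:
    """Euclidean distance (mm) from the target (0 on target voxels)."""
    return ndimage.distance_transform_edt(~np.asarray(target, dtype=bool),
                                          sampling=grid.spacing)


def calibrate_falloff(
    dose: np.ndarray,
    target: np.ndarray,
    external: np.ndarray,
    grid: ImageGrid,
    prescription_cge: float,
    n_knots: int = 20,
) -> FalloffModel:
    """Fit the fall-off from a reference dose grid.

    External voxels outside the target are binned by distance-to-target; the
    per-bin mean dose fraction is made monotone non-increasing from the target
    boundary outward by isotonic regression.
    """
    from sklearn.isotonic import IsotonicRegression

    outside = np.asarray(external, dtype=bool) & ~np.asarray(target, dtype=bool)
    if not outside.any():
        raise ValueError("no voxels outside the target to calibrate on")
    dist = target_distance_mm(target, grid)[outside]
    frac = np.asarray(dose, dtype=float)[outside] / prescription_cge
    edges = np.linspace(0.0, dist.max() + 1e-9, n_knots + 1)
    which = np.digitize(dist, edges) - 1
    centers, means = [], []
    for k in range(n_knots):
        sel = which == k
        if sel.any():
            centers.append(0.5 * (edges[k] + edges[k + 1]))
            means.append(float(frac[sel].mean()))
    iso = IsotonicRegression(increasing=False, y_min=0.0, y_max=1.0)
    fitted = iso.fit_transform(centers, means)
    return FalloffModel(np.asarray(centers), fitted)


@dataclass
class RingSet:
    """Per-voxel ring labels: k = 0..9 for fraction in [k*10%, (k+1)*10%),
    10 for inside the target, -1 outside the fall-off support."""

    labels: np.ndarray

    def ring_mask(self, k: int) -> np.ndarray:
        return self.labels == k

    def assigned_fraction(self) -> np.ndarray:
        """Midpoint dose fraction per voxel (0 outside support, 1 in target)."""
        out = np.zeros(self.labels.shape, dtype=float)
        inside = self.labels == TARGET_RING
        ring = (self.labels >= 0) & ~inside
        out[ring] = self.labels[ring] * 0.1 + 0.05
        out[inside] = 1.0
        return out


def simulate_rings(target: np.ndarray, falloff: FalloffModel, grid: ImageGrid) -> RingSet:
    """Simulate isodose rings around the target at every 10% of prescription."""
    target = np.asarray(target, dtype=bool)
    if not target.any():
        raise ValueError("target mask is empty")
    dist = target_distance_mm(target, grid)
    frac = falloff(dist)
    labels = np.full(grid.shape, -1, dtype=np.int8)
    pos = frac > 0.0
    labels[pos] = np.minimum((frac[pos] * N_RINGS).astype(int), N_RINGS - 1)
    labels[target] = TARGET_RING
    return RingSet(labels=labels)


def _assigned_dose(oar: np.ndarray, rings: RingSet, prescription_cge: float) -> np.ndarray:
    oar = np.asarray(oar, dtype=bool)
    if not oar.any():
        raise ValueError("OAR mask is empty")
    return rings.assigned_fraction()[oar] * prescription_cge


def predict_mean_dose(oar: np.ndarray, rings: RingSet, prescription_cge: float) -> float:
    """Predicted mean dose (CGE): average of assigned ring doses over the OAR."""
    return float(_assigned_dose(oar, rings, prescription_cge).mean())


def predict_dvh_point(
    oar: np.ndarray, rings: RingSet, prescription_cge: float, volume_fraction: float
) -> float:
    """Predicted Dv (CGE): dose received by at least ``volume_fraction`` of the OAR."""
    if not 0.0 < volume_fraction <= 1.0:
        raise ValueError("volume fraction must be in (0, 1]")
    doses = np.sort(_assigned_dose(oar, rings, prescription_cge))[::-1]
    k = int(np.ceil(volume_fraction * doses.size)) - 1
    return float(doses[k])


def predict_all(
    structures,
    rings: RingSet,
    prescription_cge: float,
    oar_names=PREDICTED_OARS,
    dvh_points=(0.5,),
) -> dict[str, dict[str, float]]:
    """Predicted mean dose (and Dv points) for every peripheral OAR present."""
    out: dict[str, dict[str, float]] = {}
    for name in oar_names:
        if name not in structures or not structures[name].any():
            continue
        row = {"mean_cge": predict_mean_dose(structures[name], rings, prescription_cge)}
        for v in dvh_points:
            row[f"d{int(round(v * 100))}_cge"] = predict_dvh_point(
                structures[name], rings, prescription_cge, v
            )
        out[name] = row
    return out
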