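"""DVH computation, clinical-goal checks, and robust plan evaluation.

The robust evaluation recomputes the target dose under 24 perturbations:
3 mm collective patient shifts along +/-x, +/-y, +/-z (6), +/-3.5% range
scaling (2), +/-3 degree roll and yaw (4), and 3 mm shifts of one anterior
and one posterior beam independently along the six axes (12). The plan
passes the in-house robustness rule when the target D95% changes by no more
than 3% of its nominal value on any perturbation. DVH-band statistics report
the fraction of perturbed DVH points (volume fractions 1%..100%, step 1%)
within 2% and 5% of prescription of the nominal curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .beamspot import MachineModel
from .core import DVHCurve, ImageGrid, Plan, Prescription, Scenario, StructureSet
from .dose_engine import DoseCalculator, compute_influence

__all__ = [
    "RobustReport",
    "compute_dvh",
    "evaluation_scenarios",
    "robust_evaluate",
    "check_clinical_goals",
]

D95_PASS_PCT = 3.0  # max allowed D95% change on any perturbation, % of nominal
BAND_LEVELS_PCT = (2.0, 5.0)
VOLUME_SAMPLES = np.arange(1, 101) / 100.0  # 1%..100% step 1%


def compute_dvh(
    dose: np.ndarray,
    mask: np.ndarray | None = None,
    bin_width_cge: float = 0.1,
    structure: str = "",
) -> DVHCurve:
    """Cumulative DVH by voxel counting.

    ``dose`` is either a per-voxel vector (with ``mask`` None) or a grid-shaped
    array with a boolean mask selecting the structure.
    """
    if mask is not None:
        vals = np.asarray(dose)[np.asarray(mask, dtype=bool)]
    else:
        vals = np.asarray(dose).ravel()
    if vals.size == 0:
        raise ValueError(f"empty structure '{structure}' has no DVH")
    top = float(vals.max()) + bin_width_cge
    edges = np.arange(0.0, top + bin_width_cge, bin_width_cge)
    counts, _ = np.histogram(vals, bins=edges)
    # fraction of voxels with dose >= edge k
    ge = vals.size - np.concatenate([[0], np.cumsum(counts)])
    return DVHCurve(structure=structure, dose_edges_cge=edges, volume_fraction=ge / vals.size)


# --------------------------------------------------------------------------
# evaluation scenarios
# --------------------------------------------------------------------------

_AXES = {"X": np.array([1.0, 0, 0]), "Y": np.array([0, 1.0, 0]), "Z": np.array([0, 0, 1.0])}


def evaluation_scenarios(
    plan_or_beams,
    shift_mm: float = 3.0,
    range_pct: float = 3.5,
    rotation_deg: float = 3.0,
    anterior_beam: int | None = None,
    posterior_beam: int | None = None,
) -> list[Scenario]:
    """The 24-perturbation robust-evaluation set.

    6 collective translations + 2 range scalings + 4 rotations (+/- roll,
    +/- yaw) + 6 independent shifts of one anterior beam + 6 of one posterior
    beam. The nominal scenario is not in the list (it is the reference).
    """
    beams = plan_or_beams.beams if isinstance(plan_or_beams, Plan) else list(plan_or_beams)
    ant = [i for i, b in enumerate(beams) if b.is_anterior]
    post = [i for i, b in enumerate(beams) if not b.is_anterior]
    if not ant or not post:
        raise ValueError("evaluation needs at least one anterior and one posterior beam")
    a = anterior_beam if anterior_beam is not None else ant[0]
    p = posterior_beam if posterior_beam is not None else post[0]

    out: list[Scenario] = []
    for name, axis in _AXES.items():
        for sign in (+1.0, -1.0):
            out.append(Scenario(translation_mm=sign * shift_mm * axis,
                                tag=f"shift {'+' if sign > 0 else '-'}{name}",
                                category="shift"))
    for sign in (+1.0, -1.0):
        out.append(Scenario(range_scale=1.0 + sign * range_pct / 100.0,
                            tag=f"range {sign * range_pct:+g}%", category="range"))
    for angle_name in ("roll", "yaw"):
        for sign in (+1.0, -1.0):
            kwargs = {f"{angle_name}_deg": sign * rotation_deg}
            out.append(Scenario(tag=f"{angle_name} {sign * rotation_deg:+g} deg",
                                category="rotation", **kwargs))
    for b, cls in ((a, "ant"), (p, "post")):
        for name, axis in _AXES.items():
            for sign in (+1.0, -1.0):
                out.append(Scenario(per_beam_mm={b: sign * shift_mm * axis},
                                    tag=f"{cls} beam {'+' if sign > 0 else '-'}{name}",
                                    category="beam_shift"))
    assert len(out) == 24
    return out


# --------------------------------------------------------------------------
# robust evaluation
# --------------------------------------------------------------------------


@dataclass
class RobustReport:
    """Per-scenario robustness metrics for the target."""

    nominal_d95_cge: float
    worst_d95_deviation_pct: float  # % of nominal D95
    fraction_within_2pct: float
    fraction_within_5pct: float
    passes: bool
    table: pd.DataFrame = field(repr=False)
    nominal_curve_cge: np.ndarray = field(repr=False, default=None)
    band_min_cge: np.ndarray = field(repr=False, default=None)
    band_max_cge: np.ndarray = field(repr=False, default=None)
    convention: str = (
        "DVH points within q% means |Dv(scenario) - Dv(nominal)| <= q% of prescription; "
        "D95 deviation is relative to the nominal D95"
    )


def robust_evaluate(
    grid: ImageGrid,
    plan: Plan,
    scenarios: list[Scenario],
    target_mask: np.ndarray,
    machine: MachineModel | None = None,
    bin_width_cge: float = 0.1,
    calculator: DoseCalculator | None = None,
) -> RobustReport:
    """Recompute target dose per scenario and report robustness metrics."""
    machine = machine or MachineModel()
    calc = calculator or DoseCalculator(grid, plan.beams, machine)
    w = plan.weights()
    vox = np.flatnonzero(np.asarray(target_mask, dtype=bool).ravel())
    presc = plan.prescription.dose_cge

    def dvh_points(scenario: Scenario | None) -> np.ndarray:
        infl = compute_influence(grid, plan, scenario, machine, voxel_ids=vox, calculator=calc)
        calc.clear_cache()  # beam frames are one-use here; keep memory flat
        curve = compute_dvh(infl.dose(w), bin_width_cge=bin_width_cge, structure="target")
        return np.array([curve.dose_at_volume(v) for v in VOLUME_SAMPLES])

    nominal = dvh_points(None)
    d95_nom = nominal[np.searchsorted(VOLUME_SAMPLES, 0.95)]
    rows = []
    within = {q: 0 for q in BAND_LEVELS_PCT}
    total_points = 0
    band_min = nominal.copy()
    band_max = nominal.copy()
    for sc in scenarios:
        pts = dvh_points(sc)
        band_min = np.minimum(band_min, pts)
        band_max = np.maximum(band_max, pts)
        d95 = pts[np.searchsorted(VOLUME_SAMPLES, 0.95)]
        dev_pct = abs(d95 - d95_nom) / d95_nom * 100.0 if d95_nom > 0 else np.inf
        diffs = np.abs(pts - nominal)
        total_points += pts.size
        row = {"scenario": sc.tag, "category": sc.category, "d95_cge": d95,
               "d95_deviation_pct": dev_pct}
        for q in BAND_LEVELS_PCT:
            n_in = int((diffs <= q / 100.0 * presc + 1e-12).sum())
            within[q] += n_in
            row[f"within_{q:g}pct"] = n_in / pts.size
        rows.append(row)
    table = pd.DataFrame(rows)
    worst = float(table["d95_deviation_pct"].max()) if len(table) else 0.0
    f2 = within[2.0] / total_points if total_points else 1.0
    f5 = within[5.0] / total_points if total_points else 1.0
    return RobustReport(
        nominal_d95_cge=float(d95_nom),
        worst_d95_deviation_pct=worst,
        fraction_within_2pct=f2,
        fraction_within_5pct=f5,
        passes=worst <= D95_PASS_PCT,
        table=table,
        nominal_curve_cge=nominal,
        band_min_cge=band_min,
        band_max_cge=band_max,
    )


# --------------------------------------------------------------------------
# clinical goals
# --------------------------------------------------------------------------

MEAN_DOSE_OARS = ("parotid_l", "parotid_r", "oral_cavity", "larynx", "trachea", "esophagus")
MAX_DOSE_OARS = ("spinal_cord", "brainstem", "external")


def check_clinical_goals(
    dose_grid: np.ndarray,
    structures: StructureSet,
    prescription: Prescription,
    target_name: str = "CTV50",
    v95_goal_pct: float = 99.0,
) -> pd.DataFrame:
    """Evaluate the clinical goal table on a computed dose grid.

    The hard coverage goal is target V95% > 99%; OAR mean and maximum doses
    are reported (informational rows have no pass/fail flag).
    """
    rows = []
    ctv = structures[target_name]
    curve = compute_dvh(dose_grid, ctv, structure=target_name)
    v95 = curve.volume_at_dose(0.95 * prescription.dose_cge) * 100.0
    rows.append({"structure": target_name, "metric": "V95%", "value": v95,
                 "goal": f"> {v95_goal_pct}", "passed": bool(v95 > v95_goal_pct)})
    for name in MEAN_DOSE_OARS:
        if name in structures and structures[name].any():
            rows.append({"structure": name, "metric": "mean_cge",
                         "value": float(dose_grid[structures[name]].mean()),
                         "goal": "", "passed": None})
    for name in MAX_DOSE_OARS:
        if name in structures and structures[name].any():
            rows.append({"structure": name, "metric": "max_cge",
                         "value": float(dose_grid[structures[name]].max()),
                         "goal": "", "passed": None})
    return pd.DataFrame(rows)
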