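"""End-to-end orchestration: case -> structures -> prediction -> spots ->
robust optimization -> evaluation.

Each stage is an ordinary library call; :func:`autoplan` wires them together,
logs the intermediate quantities (structure volumes, spot counts per beam,
scenario counts, convergence), and returns everything the evaluation stage
produced. Outputs are written by :meth:`AutoplanResult.save` so a run is
resumable from its persisted intermediates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import beamspot, evaluate, oar_predict, robust_opt, structgen
from .config import RunConfig
from .core import (
    ImageGrid,
    Plan,
    Prescription,
    Spot,
    StructureSet,
    write_case,
    write_plan,
    write_volume,
)
from .dose_engine import DoseCalculator, compute_influence
from .evaluate import RobustReport

log = logging.getLogger(__name__)

__all__ = ["AutoplanResult", "autoplan", "falloff_allowed_dose"]


@dataclass
class AutoplanResult:
    plan: Plan
    dose_grid: np.ndarray
    goals: pd.DataFrame
    robust_report: RobustReport
    predicted: dict[str, dict[str, float]]
    automation: structgen.AutomationStructures
    convergence: list[dict]
    config: RunConfig
    pre_enforcement_weights: np.ndarray = field(repr=False, default=None)

    def save(self, out_dir: str | Path, grid: ImageGrid, structures: StructureSet) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_plan(self.plan, out / "plan.json")
        write_volume(out / "dose.nrrd", self.dose_grid, origin=grid.origin,
                     spacing=grid.spacing)
        self.goals.to_csv(out / "goals.csv", index=False)
        self.robust_report.table.to_csv(out / "robust_report.csv", index=False)
        band = pd.DataFrame({
            "volume_fraction": evaluate.VOLUME_SAMPLES,
            "nominal_cge": self.robust_report.nominal_curve_cge,
            "band_min_cge": self.robust_report.band_min_cge,
            "band_max_cge": self.robust_report.band_max_cge,
        })
        band.to_csv(out / "dvh_band.csv", index=False)
        pd.DataFrame(self.convergence).to_csv(out / "convergence.csv", index=False)
        pred_rows = [{"structure": k, **v} for k, v in self.predicted.items()]
        pd.DataFrame(pred_rows).to_csv(out / "prediction.csv", index=False)
        vv = grid.voxel_volume_cm3()
        vols = [{"structure": n, "volume_cm3": m.sum() * vv}
                for n, m in self.automation.as_dict().items()]
        pd.DataFrame(vols).to_csv(out / "automation_volumes.csv", index=False)
        for name, mask in self.automation.as_dict().items():
            write_volume(out / f"auto_{name}.nrrd", mask, origin=grid.origin,
                         spacing=grid.spacing)
        from .core import write_dvh_csv
        from .evaluate import compute_dvh

        curves = []
        for name in structures.names():
            mask = structures[name]
            if mask.any():
                curves.append(compute_dvh(self.dose_grid, mask, structure=name))
        write_dvh_csv(curves, out / "dvh.csv")
        self.config.dump_yaml(out / "config.resolved.yaml")
        return out


def falloff_allowed_dose(
    grid: ImageGrid,
    target: np.ndarray,
    prescription_cge: float,
    low_cge: float,
    distance_mm: float,
) -> np.ndarray:
    """Per-voxel allowed dose (flat array) for the dose fall-off objective:
    prescription at the target boundary, ramping linearly to ``low_cge`` at
    ``distance_mm``, constant beyond."""
    dist = oar_predict.target_distance_mm(target, grid)
    ramp = np.clip(dist / distance_mm, 0.0, 1.0)
    return (prescription_cge - (prescription_cge - low_cge) * ramp).ravel()


def autoplan(
    grid: ImageGrid,
    structures: StructureSet,
    apex_z_mm: float | None,
    prescription: Prescription,
    config: RunConfig | None = None,
    plan: Plan | None = None,
) -> AutoplanResult:
    """Run the full automated planning pipeline on a validated case.

    When ``plan`` is given, its beams and spots are reused (weights are
    re-optimized); otherwise the standard beams are set up and spots placed.
    """
    if apex_z_mm is None:
        raise ValueError(
            "shoulder apex z is required: identify the most superior point of the "
            "shoulders and pass it as apex_z_mm (CLI: --apex-z)"
        )
    config = config or RunConfig()
    machine = config.machine
    structures.validate()
    target = config.target_name

    # 1. automation structures
    autos = structgen.build_all(
        grid, structures, apex_z_mm,
        target_name=target,
        ant_avoid_margin_mm=config.ant_avoid_margin(),
        subtract_target_from_ant_avoid=config.structgen.subtract_target_from_ant_avoid,
        postneck_lateral_mm=config.structgen.postneck_lateral_mm,
        postneck_posterior_mm=config.structgen.postneck_posterior_mm,
        skin_rind_mm=config.structgen.skin_rind_mm,
    )

    # 2. predicted OAR doses from simulated isodose rings
    falloff = oar_predict.default_falloff()
    rings = oar_predict.simulate_rings(structures[target], falloff, grid)
    predicted = oar_predict.predict_all(structures, rings, prescription.dose_cge)
    log.info("predicted OAR mean doses: %s",
             {k: round(v["mean_cge"], 1) for k, v in predicted.items()})

    # 3. beams and spots (or reuse a supplied plan's)
    if plan is None:
        beams = beamspot.default_beams(
            grid, structures, machine, target_name=target,
            anterior_gap_cm=config.anterior_gap_cm, posterior_gap_cm=config.posterior_gap_cm,
            range_shifter_wet_cm=config.range_shifter_wet_cm,
        )
        spots = beamspot.place_spots(grid, structures, beams, machine,
                                     avoid_masks=autos.as_dict(), target_name=target)
        plan = Plan(beams=beams, spots=spots, prescription=prescription,
                    weight_ratio_cap=machine.max_min_mu_ratio,
                    provenance={"seed": config.seed, "config_hash": config.hash()})
    else:
        beams = plan.beams
        plan.prescription = prescription
        plan.provenance.update({"seed": config.seed, "config_hash": config.hash()})
    counts = np.bincount(plan.spot_beam_indices(), minlength=len(beams))
    log.info("placed spots per beam: %s", dict(enumerate(counts.tolist())))

    # 4. influence matrices
    ext_ids = np.flatnonzero(structures["external"].ravel())
    calc = DoseCalculator(grid, beams, machine)
    nominal = compute_influence(grid, plan, None, machine, voxel_ids=ext_ids, calculator=calc)

    ctv_ids = np.flatnonzero(structures[target].ravel())
    other = np.setdiff1d(ext_ids, ctv_ids)
    robust_ids = np.union1d(ctv_ids, other[:: config.robust_external_stride])
    family = config.optimization_family
    if family.n_beams != len(beams):
        family.n_beams = len(beams)
    scenarios = robust_opt.enumerate_scenarios(family)
    log.info("optimization scenarios: %d, evaluation scenarios: 24", len(scenarios))
    scen_mats = []
    for sc in scenarios:
        scen_mats.append(
            compute_influence(grid, plan, sc, machine, voxel_ids=robust_ids, calculator=calc)
        )
        calc.clear_cache()

    # 5. objectives and optimization
    ant_idx = tuple(i for i, b in enumerate(beams) if b.is_anterior)
    predicted_means = {k: v["mean_cge"] for k, v in predicted.items()}
    objectives = robust_opt.build_objectives(
        prescription, predicted_means, ant_idx, params=config.objective_params,
        target_name=target,
    )
    masks = dict(structures.masks)
    masks.update(autos.as_dict())
    falloff_allowed = {
        "external_minus_target": falloff_allowed_dose(
            grid, structures[target], prescription.dose_cge,
            config.objective_params.get("falloff_low", 0.5) * prescription.dose_cge,
            config.objective_params.get("falloff_distance_mm", 15.0),
        )
    }
    weights, history = robust_opt.optimize_weights(
        nominal, scen_mats, objectives, machine, masks, prescription,
        config=config.optimizer, falloff_allowed=falloff_allowed, target_name=target,
    )
    log.info("optimizer: %d accepted iterations, final objective %.4e",
             len(history) - 1, history[-1]["objective"])

    # 6. deliverable MU constraints, final dose
    final_w = robust_opt.enforce_mu_constraints(weights, machine)
    dose_rows = nominal.dose(final_w)
    dose_grid = np.zeros(int(np.prod(grid.shape)))
    dose_grid[ext_ids] = dose_rows
    dose_grid = dose_grid.reshape(grid.shape)

    plan.set_weights(final_w)
    final_plan = plan.drop_zero_weight_spots()
    final_plan.validate()

    # 7. evaluation
    goals = evaluate.check_clinical_goals(dose_grid, structures, prescription,
                                          target_name=target)
    eval_scen = evaluate.evaluation_scenarios(
        final_plan, shift_mm=config.evaluation.shift_mm,
        range_pct=config.evaluation.range_pct,
        rotation_deg=config.evaluation.rotation_deg,
    )
    report = evaluate.robust_evaluate(
        grid, final_plan, eval_scen, structures[target], machine,
        bin_width_cge=config.evaluation.dvh_bin_cge,
    )
    log.info("CTV V95%%=%.2f%%, worst D95 deviation %.2f%%, band2=%.1f%%, band5=%.1f%%",
             float(goals.loc[goals["metric"] == "V95%", "value"].iloc[0]),
             report.worst_d95_deviation_pct,
             100 * report.fraction_within_2pct, 100 * report.fraction_within_5pct)
    return AutoplanResult(
        plan=final_plan, dose_grid=dose_grid, goals=goals, robust_report=report,
        predicted=predicted, automation=autos, convergence=history, config=config,
        pre_enforcement_weights=weights,
    )
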