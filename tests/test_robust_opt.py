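"""Scenario combinatorics, objective construction, and minimax optimization."""

import numpy as np
import pytest
from scipy import sparse

from pbsautoplan.beamspot import MachineModel
from pbsautoplan.core import Prescription, Scenario
from pbsautoplan.dose_engine import InfluenceMatrix
from pbsautoplan.robust_opt import (
    ObjectiveSpec,
    OptimizerConfig,
    ScenarioFamily,
    build_objectives,
    enforce_mu_constraints,
    enumerate_scenarios,
    optimization_scenarios,
    optimize_weights,
)


# --------------------------------------------------------------------------
# scenario enumeration
# --------------------------------------------------------------------------


@pytest.mark.parametrize(
    "family,expected",
    [
        # all six directions, independent beams, three range levels
        (ScenarioFamily(shift_mm=3.0, directions=("R", "L", "A", "P", "S", "I"),
                        independent_beams=True, n_beams=4,
                        range_scales=(0.965, 1.0, 1.035)), 7203),
        # no anterior/posterior shifts, still independent beams
        (ScenarioFamily(shift_mm=3.0, directions=("R", "L", "S", "I"),
                        independent_beams=True, n_beams=4,
                        range_scales=(0.965, 1.0, 1.035)), 1875),
        # the clinical family: collective 2 mm RLSI with +/-1% range
        (ScenarioFamily(), 15),
        # degenerate: no shifts, single range level -> nominal only
        (ScenarioFamily(directions=(), range_scales=(1.0,)), 1),
    ],
)
def test_scenario_counts_match_formula_and_enumeration(family, expected):
    scenarios = enumerate_scenarios(family)
    assert family.count == expected
    assert len(scenarios) == expected


def test_clinical_family_contents():
    scen = optimization_scenarios()
    assert len(scen) == 15
    assert sum(1 for s in scen if s.is_identity) == 1
    scales = sorted({s.range_scale for s in scen})
    assert np.allclose(scales, [0.99, 1.0, 1.01])
    shifts = {tuple(s.translation_mm) for s in scen}
    assert (0.0, 0.0, 0.0) in shifts
    assert all(not s.per_beam_mm for s in scen)  # collective, no independent beams
    # R/L/S/I at 2 mm: no anterior-posterior shifts
    assert all(s.translation_mm[1] == 0.0 for s in scen)


def test_independent_family_shifts_beams_separately():
    fam = ScenarioFamily(shift_mm=2.0, directions=("R", "L"), independent_beams=True,
                         n_beams=2, range_scales=(1.0,))
    scen = enumerate_scenarios(fam)
    assert len(scen) == 9  # (2 + 1)^2
    assert any(len(s.per_beam_mm) == 2 for s in scen)
    assert all(not s.translation_mm.any() for s in scen)


# --------------------------------------------------------------------------
# objectives
# --------------------------------------------------------------------------


def test_build_objectives_structure():
    presc = Prescription()
    objs = build_objectives(presc, {"parotid_l": 12.0, "larynx": 20.0},
                            anterior_beam_indices=(0, 1))
    robust_target = [o for o in objs if o.robust and o.structure == "CTV50"]
    assert len(robust_target) == 2
    kinds = {o.kind for o in robust_target}
    assert kinds == {"min_dose", "min_dvh"}
    # external gets robust AND non-robust maximum dose objectives
    ext_max = [o for o in objs if o.kind == "max_dose" and o.structure == "external"]
    assert sorted(o.robust for o in ext_max) == [False, True]
    # per-beam caps reference exactly the anterior beams
    pbm = [o for o in objs if o.kind == "per_beam_max"]
    assert sorted(o.beam_index for o in pbm) == [0, 1]
    assert all(o.structure == "sfo_region" for o in pbm)
    # predicted mean-dose objectives carry the predicted values
    means = {o.structure: o.dose_cge for o in objs if o.kind == "mean_dose"}
    assert means == {"parotid_l": 12.0, "larynx": 20.0}


def test_esophagus_never_gets_predicted_objective():
    with pytest.raises(ValueError, match="esophagus"):
        build_objectives(Prescription(), {"esophagus": 9.0}, (0, 1))


def test_objective_spec_contracts():
    with pytest.raises(ValueError):
        ObjectiveSpec("min_dvh", "CTV50", 48.5)  # missing volume
    with pytest.raises(ValueError):
        ObjectiveSpec("per_beam_max", "sfo_region", 30.0)  # missing beam
    with pytest.raises(ValueError):
        ObjectiveSpec("banana", "CTV50", 50.0)
    with pytest.raises(ValueError):
        ObjectiveSpec("min_dose", "CTV50", 50.0, weight=0.0)


# --------------------------------------------------------------------------
# optimization
# --------------------------------------------------------------------------


def _matrix(entries, voxel_ids, scenario=None, spot_beams=None):
    mat = sparse.csr_matrix(np.asarray(entries, dtype=float))
    return InfluenceMatrix(matrix=mat, voxel_ids=np.asarray(voxel_ids),
                           scenario=scenario or Scenario(tag="nominal"),
                           spot_beams=np.asarray(spot_beams if spot_beams is not None
                                                 else np.zeros(mat.shape[1], int)))


def _mask(n_vox, idx):
    m = np.zeros(n_vox, dtype=bool)
    m[idx] = True
    return m.reshape(n_vox, 1, 1)


def test_single_spot_single_voxel_closed_form(machine):
    """One spot, one voxel, one min-dose objective: w* = level / influence."""
    infl = _matrix([[0.5]], [0])
    masks = {"CTV50": _mask(1, [0])}
    objs = [ObjectiveSpec("min_dose", "CTV50", 50.0, weight=1.0, robust=True)]
    w, hist = optimize_weights(infl, [infl], objs, machine, masks, Prescription(),
                               config=OptimizerConfig(max_iterations=400))
    assert abs(w[0] - 100.0) < 1.0  # 50 / 0.5
    assert hist[-1]["objective"] < 1e-6


def test_nominal_only_family_reduces_to_plain_objective(machine):
    """With only the nominal scenario, minimax equals a plain non-robust run."""
    rng = np.random.default_rng(3)
    A = rng.uniform(0.0, 1.0, size=(12, 6))
    nominal = _matrix(A, np.arange(12))
    masks = {"CTV50": _mask(12, np.arange(8)), "external": _mask(12, np.arange(12))}
    presc = Prescription()
    objs_robust = [ObjectiveSpec("min_dose", "CTV50", 50.0, weight=1.0, robust=True),
                   ObjectiveSpec("max_dose", "external", 55.0, weight=1.0)]
    objs_plain = [ObjectiveSpec("min_dose", "CTV50", 50.0, weight=1.0, robust=False),
                  ObjectiveSpec("max_dose", "external", 55.0, weight=1.0)]
    cfg = OptimizerConfig(max_iterations=300)
    w_minimax, h1 = optimize_weights(nominal, [nominal], objs_robust, machine, masks,
                                     presc, config=cfg)
    # plain run: evaluate the same robust objective non-robustly on nominal
    w_plain, h2 = optimize_weights(nominal, [nominal], objs_plain, machine, masks,
                                   presc, config=cfg)
    assert abs(h1[-1]["objective"] - h2[-1]["objective"]) < 1e-6


def test_subgradient_worst_case_monotone(machine):
    """Accepted subgradient iterations never increase the minimax objective."""
    rng = np.random.default_rng(5)
    A = rng.uniform(0.0, 0.8, size=(20, 10))
    nominal = _matrix(A, np.arange(20))
    scen = [_matrix(A * f, np.arange(20), Scenario(range_scale=1 + 0.01 * i, tag=f"s{i}"))
            for i, f in enumerate((1.0, 0.9, 1.1))]
    masks = {"CTV50": _mask(20, np.arange(14)), "external": _mask(20, np.arange(20))}
    objs = [ObjectiveSpec("min_dose", "CTV50", 50.0, weight=10.0, robust=True),
            ObjectiveSpec("max_dose", "external", 52.0, weight=1.0)]
    cfg = OptimizerConfig(method="subgradient", max_iterations=100)
    w, hist = optimize_weights(nominal, scen, objs, machine, masks, Prescription(),
                               config=cfg)
    f = [h["objective"] for h in hist if h["iteration"] >= 0]
    assert all(a >= b - 1e-12 for a, b in zip(f, f[1:]))
    assert np.all(w >= 0)


def test_robust_run_beats_nonrobust_on_worst_case(machine):
    """Post hoc worst-case objective of a robust run is no worse than that of a
    non-robust run on the same scenarios."""
    rng = np.random.default_rng(8)
    A = rng.uniform(0.0, 0.8, size=(16, 8))
    nominal = _matrix(A, np.arange(16))
    scens = [_matrix(A * f, np.arange(16), Scenario(tag=f"s{f}"))
             for f in (1.0, 0.8, 1.2)]
    masks = {"CTV50": _mask(16, np.arange(12))}
    objs = [ObjectiveSpec("min_dose", "CTV50", 50.0, weight=1.0, robust=True)]
    cfg = OptimizerConfig(max_iterations=300)
    w_rob, _ = optimize_weights(nominal, scens, objs, machine, masks, Prescription(),
                                config=cfg)
    w_non, _ = optimize_weights(nominal, [scens[0]], objs, machine, masks, Prescription(),
                                config=cfg)

    def worst(w):
        out = []
        for s in scens:
            d = s.dose(w)[:12]
            v = np.maximum(50.0 - d, 0.0)
            out.append(float(v @ v) / (12 * 50.0**2))
        return max(out)

    assert worst(w_rob) <= worst(w_non) + 1e-9


# --------------------------------------------------------------------------
# MU constraints
# --------------------------------------------------------------------------


def test_enforce_mu_basic_rules(machine):
    m = MachineModel(min_spot_mu=1.0, max_min_mu_ratio=150.0)
    w = np.array([2.0, 2.0, 2.0])
    assert np.array_equal(enforce_mu_constraints(w, m), w)  # already deliverable
    w = np.array([1000.0 * 1.0, 5.0])
    out = enforce_mu_constraints(w, m)
    assert out[0] == 150.0  # capped at 150 x min MU
    w = np.array([0.4, 0.6, 3.0])  # below min/2 deleted; others clipped up
    out = enforce_mu_constraints(w, m)
    assert out[0] == 0.0 and out[1] == 1.0 and out[2] == 3.0


def test_enforce_mu_ratio_bound_randomized(machine):
    rng = np.random.default_rng(123)
    m = MachineModel(min_spot_mu=0.2, max_min_mu_ratio=150.0)
    for _ in range(50):
        w = rng.lognormal(mean=0.0, sigma=2.0, size=200)
        out = enforce_mu_constraints(w, m)
        nz = out[out > 0]
        assert nz.size > 0
        assert nz.max() / nz.min() <= 150.0 + 1e-9
        assert nz.min() >= m.min_spot_mu - 1e-12


def test_enforce_mu_all_deleted_is_error(machine):
    m = MachineModel(min_spot_mu=1.0)
    with pytest.raises(ValueError, match="every spot"):
        enforce_mu_constraints(np.array([0.1, 0.2]), m)
    with pytest.raises(ValueError):
        enforce_mu_constraints(np.array([-1.0]), m)
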