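"""Analytic pencil-beam kernel, influence matrices, and scenario transforms."""

import numpy as np
import pytest

from pbsautoplan.beamspot import MachineModel
from pbsautoplan.core import Beam, ImageGrid, Plan, Prescription, Scenario, Spot
from pbsautoplan.dose_engine import DoseCalculator, compute_influence, spot_dose
from pbsautoplan.geometry import apply_scenario


@pytest.fixture(scope="module")
def water():
    n = (31, 51, 31)  # odd sizes put voxel centers exactly on the beam axis
    sp = 4.0
    origin = np.array([-(n[0] - 1) / 2 * sp, -(n[1] - 1) / 2 * sp, -(n[2] - 1) / 2 * sp])
    return ImageGrid(origin=origin, spacing=np.full(3, sp), values=np.ones(n))


def _beam():
    return Beam(0.0, np.zeros(3), range_shifter_wet_cm=7.5)  # anterior, travel -y


def _depth_of(grid, beam, pts):
    """Geometric depth (mm) past the entry surface along the -y beam."""
    y_entry = grid.origin[1] + (grid.shape[1] - 0.5) * grid.spacing[1]
    return y_entry - pts[:, 1]


def test_peak_at_range_in_water(water, machine):
    spot = Spot(0, 120.0, 0.0, 0.0, 1.0)
    vox, dose = spot_dose(water, _beam(), spot, machine=machine)
    assert dose.min() >= 0.0
    pts = water.voxel_centers(vox)
    on_axis = (np.abs(pts[:, 0]) < 2.0) & (np.abs(pts[:, 2]) < 2.0)
    depth = _depth_of(water, _beam(), pts[on_axis])
    peak_depth_mm = depth[np.argmax(dose[on_axis])]
    expected_mm = (machine.range_from_energy(120.0) - 7.5) * 10.0
    assert abs(peak_depth_mm - expected_mm) <= water.spacing[1]
    # normalization: 1 MU gives ~1 CGE at the Bragg peak in water
    assert abs(dose[on_axis].max() - 1.0) < 0.15


def test_linearity_in_weight(water, machine):
    s1 = Spot(0, 120.0, 0.0, 0.0, 1.0)
    s2 = Spot(0, 120.0, 0.0, 0.0, 2.0)
    v1, d1 = spot_dose(water, _beam(), s1, machine=machine)
    v2, d2 = spot_dose(water, _beam(), s2, machine=machine)
    assert np.array_equal(v1, v2)
    assert np.allclose(d2, 2.0 * d1, rtol=1e-12)


def test_off_axis_ratio_one_sigma(water, machine):
    """Dose ratio at one lateral sigma equals exp(-1/2)."""
    spot = Spot(0, 130.0, 0.0, 0.0, 1.0)
    beam = _beam()
    R = float(machine.range_from_energy(130.0))
    vox, dose = spot_dose(water, beam, spot, machine=machine)
    pts = water.voxel_centers(vox)
    depth_mm = _depth_of(water, beam, pts)
    # pick the voxel plane nearest half the in-patient range
    target_depth = (R - 7.5) * 10.0 / 2.0
    plane = np.abs(depth_mm - target_depth) < 1.0
    if not plane.any():
        plane = np.abs(depth_mm - depth_mm[np.argmin(np.abs(depth_mm - target_depth))]) < 0.1
    wet_depth_cm = depth_mm[plane][0] / 10.0
    sigma = float(machine.sigma_at_depth_mm(wet_depth_cm))
    x = pts[plane][:, 0]
    z = pts[plane][:, 2]
    on = (np.abs(x) < 0.1) & (np.abs(z) < 0.1)
    d_on = dose[plane][on][0]
    # interpolate the lateral profile at exactly one sigma
    row = (np.abs(z) < 0.1)
    xi = np.argsort(x[row])
    prof = np.interp(sigma, x[row][xi], dose[plane][row][xi])
    assert abs(prof / d_on - np.exp(-0.5)) < 0.05


def _toy_plan(machine):
    beams = [Beam(0.0, np.zeros(3), range_shifter_wet_cm=7.5),
             Beam(90.0, np.zeros(3), range_shifter_wet_cm=7.5)]
    spots = [Spot(0, 110.0, 0.0, 0.0, 1.5), Spot(0, 120.0, 9.0, 0.0, 0.7),
             Spot(1, 115.0, -9.0, 4.0, 2.2), Spot(1, 125.0, 0.0, -4.0, 1.0)]
    return Plan(beams=beams, spots=spots, prescription=Prescription())


def test_influence_equals_direct_spot_summation(water, machine):
    """Influence x weights reproduces the per-spot dose sum exactly."""
    plan = _toy_plan(machine)
    infl = compute_influence(water, plan, None, machine)
    total = infl.dose(plan.weights())
    direct = np.zeros(int(np.prod(water.shape)))
    for i, s in enumerate(plan.spots):
        vox, dose = spot_dose(water, plan.beams[s.beam], s, machine=machine,
                              beam_index=s.beam)
        direct[vox] += dose
    assert np.allclose(total, direct, atol=1e-6)
    assert infl.matrix.min() >= 0.0
    # per-beam decomposition sums to the total
    per_beam = sum(infl.beam_dose(plan.weights(), b) for b in range(2))
    assert np.allclose(per_beam, total, atol=1e-9)


def test_identity_scenario_matches_nominal(water, machine):
    plan = _toy_plan(machine)
    a = compute_influence(water, plan, None, machine)
    b = compute_influence(water, plan, Scenario(), machine)
    assert (a.matrix != b.matrix).nnz == 0


def test_scenario_validation_and_inverse(water, machine):
    with pytest.raises(ValueError, match="15"):
        apply_scenario(Scenario(roll_deg=20.0))
    plan = _toy_plan(machine)
    sc = Scenario(translation_mm=[3.0, -2.0, 1.0], range_scale=1.02)
    nominal = compute_influence(water, plan, None, machine).dose(plan.weights())
    net = sc.compose(sc.neg())
    back = compute_influence(water, plan, net, machine).dose(plan.weights())
    assert np.allclose(back, nominal, atol=1e-9)


def test_range_scale_moves_peak_proximal(water, machine):
    """Range scale 1.035 puts the water Bragg peak at R/1.035 of the patient
    depth, within one voxel."""
    spot = Spot(0, 140.0, 0.0, 0.0, 1.0)
    beam = _beam()
    vox, dose = spot_dose(water, beam, spot, Scenario(range_scale=1.035), machine)
    pts = water.voxel_centers(vox)
    on_axis = (np.abs(pts[:, 0]) < 2.0) & (np.abs(pts[:, 2]) < 2.0)
    depth = _depth_of(water, beam, pts[on_axis])
    peak_depth_mm = depth[np.argmax(dose[on_axis])]
    expected = (machine.range_from_energy(140.0) - 7.5) * 10.0 / 1.035
    assert abs(peak_depth_mm - expected) <= water.spacing[1]


def test_translation_equivariance_on_uniform_slab(water, machine):
    """A +x patient shift moves the dose by -x in the patient frame and leaves
    the maximum unchanged within 1%."""
    spot = Spot(0, 125.0, 0.0, 0.0, 1.0)
    beam = _beam()
    v0, d0 = spot_dose(water, beam, spot, machine=machine)
    sc = Scenario(translation_mm=[4.0, 0.0, 0.0])  # one voxel exactly
    v1, d1 = spot_dose(water, beam, spot, sc, machine)
    g0 = np.zeros(int(np.prod(water.shape)))
    g1 = np.zeros_like(g0)
    g0[v0] = d0
    g1[v1] = d1
    g0 = g0.reshape(water.shape)
    g1 = g1.reshape(water.shape)
    assert abs(g1.max() - g0.max()) / g0.max() < 0.01
    # the shifted distribution equals the nominal rolled by -1 voxel in x
    # (away from the boundary, where the roll wraps)
    interior = np.s_[2:-2, 2:-2, 2:-2]
    assert np.allclose(np.roll(g0, -1, axis=0)[interior], g1[interior], atol=1e-4)


def test_per_beam_shift_only_moves_that_beam(water, machine):
    plan = _toy_plan(machine)
    sc = Scenario(per_beam_mm={0: np.array([4.0, 0.0, 0.0])})
    nom = compute_influence(water, plan, None, machine)
    per = compute_influence(water, plan, sc, machine)
    w = plan.weights()
    # beam 1 columns identical, beam 0 columns changed
    assert np.allclose(nom.beam_dose(w, 1), per.beam_dose(w, 1), atol=1e-9)
    assert not np.allclose(nom.beam_dose(w, 0), per.beam_dose(w, 0), atol=1e-3)


def test_memory_guard(water, machine):
    plan = _toy_plan(machine)
    with pytest.raises(ValueError, match="coarser"):
        compute_influence(water, plan, None, machine, size_cap=10.0)
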