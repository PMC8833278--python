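"""Machine model, WET ray tracing, standard beams, and spot placement."""

import numpy as np
import pytest

from pbsautoplan.beamspot import (
    AvoidanceEliminatesBeamError,
    MachineModel,
    default_beams,
    place_spots,
    spot_peak_positions,
    trace_wet,
)
from pbsautoplan.core import Beam, ImageGrid, Scenario
from pbsautoplan.structgen import build_all


def test_range_energy_anchor(machine):
    assert np.isclose(machine.range_from_energy(97.5), 7.5, atol=1e-12)


def test_range_energy_inverse_roundtrip(machine):
    for e in (97.5, 120.0, 160.0, 226.0):
        assert abs(machine.energy_from_range(machine.range_from_energy(e)) - e) / e < 1e-9


def test_range_power_law(machine):
    p = machine.bragg_kleeman_p
    for e in (100.0, 150.0):
        assert np.isclose(machine.range_from_energy(2 * e) / machine.range_from_energy(e),
                          2.0**p)


def test_spot_spacing_80pct_overlap(machine):
    sigma = 16.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    assert np.isclose(machine.sigma_air_mm, sigma)
    expected = 2.0 * sigma * np.sqrt(2.0 * np.log(1.0 / 0.8))
    assert np.isclose(machine.spot_spacing_mm, expected)
    assert abs(machine.spot_spacing_mm - 9.08) < 0.01  # closed-form value


# --------------------------------------------------------------------------
# WET tracing
# --------------------------------------------------------------------------


def _water_box(n=30, sp=4.0):
    origin = np.full(3, -(n - 1) / 2.0 * sp)
    return ImageGrid(origin=origin, spacing=np.full(3, sp), values=np.ones((n, n, n)))


def test_trace_wet_water_identity_and_shifter():
    grid = _water_box()
    beam = Beam(0.0, np.zeros(3), range_shifter_wet_cm=0.0)
    ray = trace_wet(grid, beam, (0.0, 0.0))
    # 30 voxels x 4 mm = 120 mm of water -> 12 cm WET
    assert np.isclose(ray.wet_end_cm[-1], 12.0, atol=1e-9)
    beam2 = Beam(0.0, np.zeros(3), range_shifter_wet_cm=7.5)
    ray2 = trace_wet(grid, beam2, (0.0, 0.0))
    assert np.isclose(ray2.wet_end_cm[-1], 19.5, atol=1e-9)
    assert not ray.missed_external


def test_trace_wet_oblique_path_length():
    """A 45-degree ray through a single voxel of RSP 2 adds 2 x the in-voxel
    chord length to the WET."""
    grid = _water_box()
    grid.values[:] = 0.0
    # voxel centered at (-2, -2, +2); the 45-degree ray through lateral (0, +2)
    # runs in the z = +2 plane and crosses this voxel corner-to-corner
    grid.values[14, 14, 15] = 2.0
    beam = Beam(45.0, np.zeros(3), range_shifter_wet_cm=0.0)
    ray = trace_wet(grid, beam, (0.0, 2.0))
    expected_chord = 4.0 * np.sqrt(2.0)
    assert np.isclose(ray.wet_end_cm[-1], 2.0 * expected_chord / 10.0, atol=1e-6)


def test_trace_wet_miss_is_flagged():
    grid = _water_box()
    beam = Beam(0.0, np.zeros(3), range_shifter_wet_cm=7.5)
    ray = trace_wet(grid, beam, (1e4, 0.0))
    assert ray.missed_external
    assert ray.wet_end_cm.size == 0 or np.isclose(ray.wet_end_cm[-1], 7.5)


def test_trace_wet_range_scale_scales_patient_only():
    grid = _water_box()
    beam = Beam(0.0, np.zeros(3), range_shifter_wet_cm=7.5)
    ray = trace_wet(grid, beam, (0.0, 0.0), scenario=Scenario(range_scale=1.035))
    assert np.isclose(ray.wet_end_cm[-1], 7.5 + 1.035 * 12.0, atol=1e-9)


# --------------------------------------------------------------------------
# standard beams
# --------------------------------------------------------------------------


def test_default_beams_configuration(phantom_case, machine):
    grid, structures, _ = phantom_case
    beams = default_beams(grid, structures, machine)
    got = {b.gantry_deg: b for b in beams}
    assert set(got) == {30.0, 330.0, 135.0, 225.0}
    for g in (30.0, 330.0):
        assert got[g].classification == "anterior"
        assert got[g].air_gap_cm == 5.0
        assert got[g].avoidance == ("ant_avoid",)
    for g in (135.0, 225.0):
        assert got[g].classification == "posterior"
        assert got[g].air_gap_cm == 10.0
        assert got[g].avoidance == ("post_avoid",)
    for b in beams:
        assert b.range_shifter_wet_cm == 7.5
        # snout sits exactly the configured gap upstream of the external surface
        _, _, d = b.axes()
        ext_pts = grid.voxel_centers(np.flatnonzero(structures["external"]))
        t_entry = float(((ext_pts - b.isocenter_mm) @ d).min())
        assert np.isclose(t_entry - b.snout_t_mm, b.air_gap_cm * 10.0)


def test_default_beams_symmetric_gap_swap(machine):
    """On a y-symmetric phantom, flipping the external 180 degrees swaps which
    air gap applies along each beam axis."""
    n = 31
    grid = _water_box(n)
    grid.values[:] = 0.0
    ext = np.zeros((n, n, n), dtype=bool)
    ext[10:21, 6:25, 10:21] = True  # asymmetric in y
    grid.values[ext] = 1.0
    from pbsautoplan.core import StructureSet

    ss = StructureSet(grid=grid)
    ss.add("external", ext, role="external")
    ctv = np.zeros_like(ext)
    ctv[14:17, 14:17, 14:17] = True
    ss.add("CTV50", ctv, role="target")
    beams = default_beams(grid, ss, machine)
    flipped = StructureSet(grid=grid)
    flipped.add("external", ext[:, ::-1, :], role="external")
    flipped.add("CTV50", ctv[:, ::-1, :], role="target")
    beams_f = default_beams(grid, flipped, machine)
    by_g = {b.gantry_deg: b for b in beams}
    by_gf = {b.gantry_deg: b for b in beams_f}
    # the 0/180-degree-equivalent pair: anterior 30 vs flipped posterior 225
    # share mirrored geometry, so entry distances swap within a voxel
    for g, g_m in ((30.0, 225.0), (330.0, 135.0)):
        _, _, d = by_g[g].axes()
        t1 = by_g[g].snout_t_mm + by_g[g].air_gap_cm * 10
        t2 = by_gf[g_m].snout_t_mm + by_gf[g_m].air_gap_cm * 10
        assert abs(t1 - t2) <= 2 * 4.0  # mirrored entry distance


# --------------------------------------------------------------------------
# spot placement
# --------------------------------------------------------------------------


@pytest.fixture(scope="module")
def placed(phantom_case):
    grid, structures, apex = phantom_case
    machine = MachineModel()
    autos = build_all(grid, structures, apex)
    beams = default_beams(grid, structures, machine)
    spots = place_spots(grid, structures, beams, machine, avoid_masks=autos.as_dict())
    return grid, structures, apex, autos, beams, spots, machine


def test_spots_respect_min_depth_and_energy(placed):
    *_, beams, spots, machine = placed
    for s in spots:
        depth = machine.range_from_energy(s.energy_mev) - beams[s.beam].range_shifter_wet_cm
        assert depth >= machine.min_spot_depth_cm - 1e-9
        assert s.energy_mev >= machine.min_energy_mev - 1e-9


def test_no_posterior_spot_below_shoulder_apex(placed):
    grid, structures, apex, autos, beams, spots, machine = placed
    pos = spot_peak_positions(grid, beams, spots, machine)
    for s, p in zip(spots, pos):
        if not beams[s.beam].is_anterior:
            assert p[2] >= apex - 1e-6


def test_lattice_covers_projected_target(placed):
    """Without avoidance filtering, every projected target voxel lies within
    one lattice spacing of a placed spot, for every beam."""
    grid, structures, apex, autos, beams, spots, machine = placed
    from pbsautoplan.geometry import BeamFrame

    empty = {"ant_avoid": np.zeros(grid.shape, bool), "post_avoid": np.zeros(grid.shape, bool)}
    unfiltered = place_spots(grid, structures, beams, machine, avoid_masks=empty)
    ctv_pts = grid.voxel_centers(np.flatnonzero(structures["CTV50"]))
    s = machine.spot_spacing_mm
    for bi, beam in enumerate(beams):
        bf = BeamFrame(grid, beam, beam_index=bi)
        uv = bf.points_to_uvt(ctv_pts)[:, :2]
        nodes = np.array([[sp.x_mm, sp.y_mm] for sp in unfiltered if sp.beam == bi])
        from scipy.spatial import cKDTree

        dist, _ = cKDTree(nodes).query(uv, k=1)
        assert dist.max() <= s + 1e-6


def test_avoidance_monotone_spot_count(placed):
    grid, structures, apex, autos, beams, spots, machine = placed
    from pbsautoplan.structgen import expand

    bigger = dict(autos.as_dict())
    bigger["ant_avoid"] = expand(autos.ant_avoid, 8.0, grid.spacing)
    spots_big = place_spots(grid, structures, beams, machine, avoid_masks=bigger)
    assert len(spots_big) <= len(spots)


def test_avoidance_eliminating_a_beam_errors(toy_case, machine):
    grid, structures, apex = toy_case
    beams = default_beams(grid, structures, machine)
    # slab covering the whole target for anterior beams only
    avoid = {"ant_avoid": structures["external"].copy(), "post_avoid": np.zeros(grid.shape, bool)}
    with pytest.raises(AvoidanceEliminatesBeamError, match="gantry 30"):
        place_spots(grid, structures, beams, machine, avoid_masks=avoid)
    # posterior beams unaffected: placement without the blocking mask succeeds
    spots = place_spots(grid, structures, beams, machine,
                        avoid_masks={"ant_avoid": np.zeros(grid.shape, bool),
                                     "post_avoid": np.zeros(grid.shape, bool)})
    assert len(spots) > 0
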