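"""Catheter geometry, dwell stepping, free-hand and phantom implants."""

import math

import numpy as np
import pytest

from brachydose import (
    Catheter, FreehandTemplate, PhantomSetup, build_phantom_plan,
    dwell_positions, generate_freehand_implant,
)
from brachydose.implant import InfeasibleImplantError, catheter_count_1d, save_plan, load_plan


def brute_force_line_count(extent_mm, pitch_mm):
    """Oracle: smallest n so centred, pitched lines leave no point of the
    interval farther than pitch/2 from a line."""
    half = extent_mm / 2.0
    for n in range(1, 200):
        xs = (np.arange(n) - (n - 1) / 2.0) * pitch_mm
        probe = np.linspace(-half, half, 2001)
        if np.max(np.min(np.abs(probe[:, None] - xs[None, :]), axis=1)) <= pitch_mm / 2 + 1e-9:
            return n
    raise AssertionError("no covering found")


class TestDwellPositions:
    def test_count_straight_path(self, straight_catheter):
        pos, tan = dwell_positions(straight_catheter, 5.0, 0.0)
        assert pos.shape == (21, 3)
        np.testing.assert_allclose(tan, [[0, 1, 0]] * 21)

    def test_count_with_retraction(self, straight_catheter):
        pos, _ = dwell_positions(straight_catheter, 5.0, 10.0)
        assert pos.shape[0] == 17
        assert pos[0, 1] == pytest.approx(-40.0)

    def test_curved_polyline_uniform_arc_spacing(self):
        t = np.linspace(0, np.pi, 400)
        path = np.column_stack([30 * np.cos(t), 30 * np.sin(t), np.full_like(t, 8.0)])
        cath = Catheter(id="arc", path_mm=path, button_positions_mm=np.array(
            [[path[0, 0], path[0, 1], 0.0], [path[-1, 0], path[-1, 1], 0.0]]))
        pos, _ = dwell_positions(cath, 5.0, 0.0)
        # oracle: arc length of each dwell from a dense resampling of the path
        seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
        cum = np.concatenate([[0], np.cumsum(seg)])
        dense_s = np.linspace(0, cum[-1], 200_001)
        dense_x = np.column_stack([np.interp(dense_s, cum, path[:, k])
                                   for k in range(3)])
        arcs = [dense_s[np.argmin(np.linalg.norm(dense_x - p, axis=1))]
                for p in pos]
        np.testing.assert_allclose(np.diff(arcs), 5.0, atol=1e-2)

    def test_too_short_path_raises(self):
        c = Catheter(id="s", path_mm=np.array([[0, 0, 5], [0, 8, 5.0]]),
                     button_positions_mm=np.array([[0, 0, 0], [0, 8, 0.0]]))
        with pytest.raises(ValueError):
            dwell_positions(c, 5.0, 10.0)


class TestFreehand:
    def test_count_matches_covering_oracle(self):
        tpl = FreehandTemplate(n_planes=2, spacing_cm=2.0)
        caths = generate_freehand_implant((0, 0, 25.0), 15.0, tpl)
        per_plane = brute_force_line_count(2 * (15.0 + 20.0), 20.0)
        assert len(caths) == 2 * per_plane
        assert per_plane == catheter_count_1d(70.0, 20.0)

    def test_single_plane_is_coplanar(self):
        tpl = FreehandTemplate(n_planes=1, spacing_cm=1.5)
        caths = generate_freehand_implant((0, 0, 20.0), 10.0, tpl)
        zs = np.concatenate([c.path_mm[:, 2] for c in caths])
        assert np.ptp(zs) < 1e-6

    def test_min_skin_depth_respected(self):
        tpl = FreehandTemplate(n_planes=2, spacing_cm=1.5)
        caths = generate_freehand_implant((0, 0, 14.0), 6.0, tpl)
        depth = min(c.path_mm[:, 2].min() for c in caths)
        assert depth >= 5.0

    def test_adjacent_spacing_exact(self):
        tpl = FreehandTemplate(n_planes=2, spacing_cm=1.8)
        caths = generate_freehand_implant((0, 0, 25.0), 12.0, tpl)
        xs_by_z = {}
        for c in caths:
            xs_by_z.setdefault(round(c.path_mm[0, 2], 6), []).append(c.path_mm[0, 0])
        for xs in xs_by_z.values():
            gaps = np.diff(sorted(xs))
            np.testing.assert_allclose(gaps, 18.0, atol=1e-6)
        # triangular offset between the two planes
        (z1, xs1), (z2, xs2) = sorted(xs_by_z.items())
        assert abs((min(xs2) - min(xs1)) % 18.0 - 9.0) < 1e-6

    def test_shallow_cavity_is_infeasible(self):
        tpl = FreehandTemplate(n_planes=2, spacing_cm=1.5)
        with pytest.raises(InfeasibleImplantError, match="mm"):
            generate_freehand_implant((0, 0, 8.0), 6.0, tpl)

    def test_deterministic(self):
        tpl = FreehandTemplate(n_planes=2, spacing_cm=1.7)
        a = generate_freehand_implant((3, -2, 22.0), 9.0, tpl)
        b = generate_freehand_implant((3, -2, 22.0), 9.0, tpl)
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.path_mm, cb.path_mm)

    def test_count_monotone_in_spacing(self):
        counts = []
        for s in np.linspace(1.5, 2.0, 11):
            tpl = FreehandTemplate(n_planes=2, spacing_cm=float(s))
            counts.append(len(generate_freehand_implant((0, 0, 25.0), 12.0, tpl)))
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestPhantom:
    @pytest.mark.parametrize("depth", [5.0, 10.0, 15.0, 20.0])
    def test_dwells_at_requested_depth(self, depth):
        plan = build_phantom_plan(PhantomSetup(catheter_depth_mm=depth))
        pos, _ = plan.dwell_geometry
        np.testing.assert_allclose(pos[:, 2], depth)

    def test_two_catheters_twenty_mm_apart(self):
        plan = build_phantom_plan(PhantomSetup(catheter_depth_mm=10.0))
        assert len(plan.catheters) == 2
        x0 = plan.catheters[0].path_mm[0, 0]
        x1 = plan.catheters[1].path_mm[0, 0]
        assert abs(x1 - x0) == pytest.approx(20.0, abs=1e-9)

    def test_film_variant_uses_two_cm_depth(self):
        plan = build_phantom_plan(PhantomSetup(variant="perpendicular_film"))
        pos, _ = plan.dwell_geometry
        np.testing.assert_allclose(pos[:, 2], 20.0)


class TestCatheterType:
    def test_buttons_default_to_skin_projection(self, straight_catheter):
        b = straight_catheter.button_positions_mm
        np.testing.assert_allclose(b[:, 2], 0.0)
        np.testing.assert_allclose(b[:, :2], straight_catheter.path_mm[[0, -1], :2])

    def test_buttons_must_sit_over_endpoints(self):
        with pytest.raises(ValueError):
            Catheter(id="bad", path_mm=np.array([[0, 0, 10], [0, 50, 10.0]]),
                     button_positions_mm=np.array([[5, 0, 0], [0, 50, 0.0]]))

    def test_degenerate_path_rejected(self):
        with pytest.raises(ValueError):
            Catheter(id="dup", path_mm=np.array([[0, 0, 5], [0, 0, 5.0]]))


def test_plan_save_load_round_trip(tmp_path, two_dwell_plan):
    two_dwell_plan.dwell_times_s = np.arange(two_dwell_plan.n_dwells, dtype=float) + 1
    save_plan(two_dwell_plan, tmp_path / "plan.json", tmp_path / "dwells.csv")
    back = load_plan(tmp_path / "plan.json")
    np.testing.assert_allclose(back.dwell_times_s, two_dwell_plan.dwell_times_s)
    p0, a0 = two_dwell_plan.dwell_geometry
    p1, a1 = back.dwell_geometry
    np.testing.assert_allclose(p0, p1)
    np.testing.assert_allclose(a0, a1)
    assert back.prescription_cgy_per_fraction == 340.0
    assert back.total_dose_cgy == 3400.0
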