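"""Voxel geometry: margins, the skin region, involved ribs, scar point."""

import numpy as np
import pytest

from brachydose import (
    Catheter, SkinRegionSpec, StructureSet, VoxelGrid, build_skin_region,
    expand_margin, involved_ribs, skin_measurement_point,
)
from brachydose.anatomy import slab_mask, sphere_mask


def make_grid(shape=(40, 40, 40), spacing=(1.0, 1.0, 2.5), origin=None):
    if origin is None:
        origin = tuple(-s * (n - 1) / 2 for s, n in zip(spacing, shape))
    return VoxelGrid(origin_mm=origin, spacing_mm=spacing, shape=shape)


def parallel_catheters(xs, depth=10.0, half_len=40.0):
    return [
        Catheter(id=f"c{i}", path_mm=np.array([[x, -half_len, depth],
                                               [x, half_len, depth]]))
        for i, x in enumerate(xs)
    ]


class TestExpandMargin:
    def test_zero_margin_is_identity(self):
        grid = make_grid((20, 20, 20))
        mask = sphere_mask(grid, (0, 0, 0), 6.0)
        np.testing.assert_array_equal(expand_margin(mask, 0.0, grid), mask)

    def test_sphere_expansion_matches_analytic_volume(self):
        grid = make_grid((81, 81, 41), spacing=(1.0, 1.0, 2.5))
        mask = sphere_mask(grid, (0, 0, 0), 10.0)
        grown = expand_margin(mask, 20.0, grid)
        analytic = 4.0 / 3.0 * np.pi * 30.0**3 / 1000.0  # 113.10 cc
        # center-distance semantics bias the boundary inward by up to half a
        # voxel diagonal; 4% covers that voxelization error at 1x1x2.5 mm
        assert grid.mask_volume_cc(grown) == pytest.approx(analytic, rel=0.04)

    def test_matches_brute_force_all_pairs(self, rng):
        grid = make_grid((18, 18, 18), spacing=(2.0, 2.0, 2.0))
        mask = np.zeros(grid.shape, bool)
        idx = rng.integers(4, 14, size=(8, 3))
        mask[idx[:, 0], idx[:, 1], idx[:, 2]] = True
        grown = expand_margin(mask, 7.0, grid)
        centers = grid.voxel_centers()
        src = centers[mask.ravel()]
        d = np.linalg.norm(centers[:, None, :] - src[None, :, :], axis=2).min(axis=1)
        brute = (d <= 7.0 + 1e-9).reshape(grid.shape)
        np.testing.assert_array_equal(grown, brute)

    def test_monotone_in_margin(self):
        grid = make_grid((24, 24, 24), spacing=(1.5, 1.5, 1.5))
        mask = sphere_mask(grid, (2, -1, 0), 4.0)
        prev = mask
        for margin in (2.0, 5.0, 9.0):
            cur = expand_margin(mask, margin, grid)
            assert not np.any(prev & ~cur)
            prev = cur

    def test_empty_mask_raises(self):
        grid = make_grid((8, 8, 8))
        with pytest.raises(ValueError):
            expand_margin(np.zeros(grid.shape, bool), 3.0, grid)


class TestSkinRegion:
    def grid(self):
        return VoxelGrid(origin_mm=(-60.0, -60.0, 0.25), spacing_mm=(0.5, 0.5, 0.5),
                         shape=(240, 240, 20))

    def test_two_catheter_footprint_volume(self):
        # 2 cm apart, 8 cm button span: footprint 8 x (2+1+1) cm2, 3 mm deep
        caths = parallel_catheters([-10.0, 10.0], half_len=40.0)
        grid = self.grid()
        mask = build_skin_region(caths, grid)
        assert grid.mask_volume_cc(mask) == pytest.approx(9.6, rel=0.02)

    def test_region_confined_to_three_mm(self):
        caths = parallel_catheters([0.0, 15.0])
        grid = self.grid()
        mask = build_skin_region(caths, grid)
        z = grid.axes()[2]
        assert not np.any(mask[:, :, z > 3.0])

    def test_single_catheter_degenerates_to_2cm_strip(self):
        caths = parallel_catheters([0.0], half_len=30.0)
        grid = self.grid()
        mask = build_skin_region(caths, grid)
        x = grid.axes()[0]
        occupied = x[np.any(mask, axis=(1, 2))]
        assert occupied.min() == pytest.approx(-10.0, abs=0.5)
        assert occupied.max() == pytest.approx(10.0, abs=0.5)

    def test_volume_scales_linearly_with_button_span(self):
        grid = self.grid()
        vols = []
        for half_len in (20.0, 30.0, 40.0):
            caths = parallel_catheters([-10.0, 10.0], half_len=half_len)
            vols.append(grid.mask_volume_cc(build_skin_region(caths, grid)))
        ratios = np.diff(vols) / np.diff([40.0, 60.0, 80.0])
        assert ratios[0] == pytest.approx(ratios[1], rel=0.02)


class TestInvolvedRibs:
    def test_full_overlap_is_footprint_times_thickness(self):
        grid = VoxelGrid(origin_mm=(-50, -50, 0.5), spacing_mm=(1, 1, 1),
                         shape=(100, 100, 40))
        caths = parallel_catheters([-10.0, 10.0], half_len=30.0)
        ribs = slab_mask(grid, 30.0, 35.0)
        mask = involved_ribs(caths, ribs, grid)
        # footprint 40 x 60 mm, slab 5 mm
        assert grid.mask_volume_cc(mask) == pytest.approx(12.0, rel=0.05)

    def test_no_overlap_is_empty(self):
        grid = VoxelGrid(origin_mm=(-50, -50, 0.5), spacing_mm=(1, 1, 1),
                         shape=(100, 100, 20))
        caths = parallel_catheters([-10.0, 10.0])
        ribs = np.zeros(grid.shape, bool)  # no rib slab in this grid
        assert not involved_ribs(caths, ribs, grid).any()

    def test_partial_overlap_matches_counting_oracle(self):
        grid = VoxelGrid(origin_mm=(-50, -50, 0.5), spacing_mm=(2, 2, 2),
                         shape=(50, 50, 25))
        caths = parallel_catheters([-10.0, 10.0], half_len=30.0)
        ribs = slab_mask(grid, 30.0, 40.0)
        ribs[grid.axes()[0] > 0, :, :] = False  # half slab only
        got = involved_ribs(caths, ribs, grid)
        x_lo, x_hi = -20.0, 20.0
        y_lo, y_hi = -30.0, 30.0
        centers = grid.voxel_centers()
        inside = ((centers[:, 0] >= x_lo - 1e-9) & (centers[:, 0] <= x_hi + 1e-9)
                  & (centers[:, 1] >= y_lo - 1e-9) & (centers[:, 1] <= y_hi + 1e-9))
        brute = inside.reshape(grid.shape) & ribs
        np.testing.assert_array_equal(got, brute)


class TestScarPoint:
    def test_straight_scar_offsets_in_x(self):
        scar = np.array([[0.0, -20.0, 0.0], [0.0, 20.0, 0.0]])
        p = skin_measurement_point(scar, 20.0, side=-1.0)
        np.testing.assert_allclose(p, [20.0, 0.0, 0.0], atol=1e-9)

    def test_zero_offset_is_midpoint(self):
        scar = np.array([[0.0, -20.0, 0.0], [0.0, 30.0, 0.0]])
        np.testing.assert_allclose(skin_measurement_point(scar, 0.0),
                                   [0.0, 5.0, 0.0], atol=1e-9)

    def test_curved_scar_distance_exact(self):
        t = np.linspace(0, np.pi / 2, 200)
        scar = np.column_stack([25 * np.cos(t), 25 * np.sin(t), np.zeros_like(t)])
        p = skin_measurement_point(scar, 20.0)
        seg = np.linalg.norm(np.diff(scar, axis=0), axis=1)
        cum = np.concatenate([[0], np.cumsum(seg)])
        j = np.searchsorted(cum, cum[-1] / 2)
        mid = scar[j]
        assert np.linalg.norm(p - mid) == pytest.approx(20.0, abs=0.5)

    def test_zero_length_scar_raises(self):
        with pytest.raises(ValueError):
            skin_measurement_point(np.array([[1.0, 1.0, 0.0]]), 20.0)


def test_structure_nesting_enforced():
    grid = make_grid((20, 20, 20), spacing=(2, 2, 2), origin=(-19, -19, 1.0))
    ss = StructureSet(grid=grid)
    inner = sphere_mask(grid, (0, 0, 20), 8.0)
    outer = sphere_mask(grid, (0, 0, 20), 14.0)
    ss["tumor_bed"] = inner
    ss["ctv"] = outer
    ss["ptv"] = expand_margin(outer, 4.0, grid)
    ss.validate()
    ss["ctv"] = sphere_mask(grid, (10, 10, 30), 4.0)  # no longer contains bed
    with pytest.raises(ValueError, match="nesting"):
        ss.validate()
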