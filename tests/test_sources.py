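"""TG-43 source model: geometry factor, table interpolation, dose rate."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.spatial.transform import Rotation

from brachydose import (
    DwellSource, SourceSpec, anisotropy, dose_rate, geometry_factor,
    radial_dose, save_source, load_source, unit_test_source,
)
from brachydose.sources import SourceDataError


def quad_line_geometry(r_cm, theta_deg, L_cm):
    """Independent oracle: (1/L) * integral of |r - l|^-2 over the line."""
    th = np.deg2rad(theta_deg)
    d, z0 = r_cm * np.sin(th), r_cm * np.cos(th)
    val, _ = quad(lambda l: 1.0 / (d * d + (z0 - l) ** 2), -L_cm / 2, L_cm / 2,
                  epsabs=1e-13, epsrel=1e-12)
    return val / L_cm


class TestGeometryFactor:
    def test_point_mode_is_inverse_square(self):
        assert geometry_factor(2.0, 90.0, 0.36, "point") == 0.25

    @pytest.mark.parametrize("r,theta", [
        (1.0, 90.0), (0.3, 90.0), (1.7, 35.0), (2.5, 120.0),
        (0.5, 5.0), (5.0, 178.0), (0.25, 60.0),
    ])
    def test_line_mode_matches_quadrature(self, r, theta):
        g = geometry_factor(r, theta, 0.36, "line")
        assert g == pytest.approx(quad_line_geometry(r, theta, 0.36), rel=1e-6)

    def test_short_line_converges_to_point(self):
        g_line = geometry_factor(1.7, 35.0, 1e-6, "line")
        assert g_line == pytest.approx(1.0 / 1.7**2, rel=1e-5)

    def test_on_axis_limit_is_continuous(self):
        # analytic on-axis value 1/(r^2 - L^2/4) met continuously
        g0 = geometry_factor(2.0, 0.0, 0.36, "line")
        g_eps = geometry_factor(2.0, 1e-5, 0.36, "line")
        assert g0 == pytest.approx(1.0 / (4.0 - 0.36**2 / 4.0), rel=1e-12)
        assert g_eps == pytest.approx(g0, rel=1e-6)

    def test_singular_field_point_rejected(self):
        with pytest.raises(ValueError):
            geometry_factor(0.0, 90.0, 0.36, "line")


class TestTables:
    def test_radial_nodes_and_normalization(self, ir_source):
        for r, g in zip(ir_source.radial_r_cm, ir_source.radial_g):
            assert radial_dose(ir_source, r) == pytest.approx(g, rel=1e-12)
        assert radial_dose(ir_source, 1.0) == pytest.approx(1.0, abs=1e-12)

    def test_radial_midpoint_is_log_linear(self, ir_source):
        r1, r2 = ir_source.radial_r_cm[3:5]
        g1, g2 = ir_source.radial_g[3:5]
        rm = 0.5 * (r1 + r2)
        expect = np.exp(np.log(g1) + (np.log(g2) - np.log(g1)) * (rm - r1) / (r2 - r1))
        assert radial_dose(ir_source, rm) == pytest.approx(expect, rel=1e-12)

    def test_radial_extrapolation_policy(self, ir_source):
        rt, gt = ir_source.radial_r_cm, ir_source.radial_g
        # constant below r_min
        assert radial_dose(ir_source, rt[0] / 2) == pytest.approx(gt[0], rel=1e-12)
        # last-segment ln-slope continued above r_max
        slope = (np.log(gt[-1]) - np.log(gt[-2])) / (rt[-1] - rt[-2])
        expect = np.exp(np.log(gt[-1]) + slope * 2.0)
        assert radial_dose(ir_source, rt[-1] + 2.0) == pytest.approx(expect, rel=1e-12)
        with pytest.raises(ValueError):
            radial_dose(ir_source, -1.0)

    def test_anisotropy_normalized_at_90(self, ir_source):
        for r in ir_source.aniso_r_cm:
            assert anisotropy(ir_source, r, 90.0) == pytest.approx(1.0, abs=1e-12)

    def test_anisotropy_grid_nodes(self, ir_source):
        f = anisotropy(ir_source, ir_source.aniso_r_cm[2],
                       ir_source.aniso_theta_deg[1])
        assert f == pytest.approx(ir_source.aniso_f[2, 1], rel=1e-12)

    def test_anisotropy_off_grid_bilinear(self, ir_source):
        ra, ta, F = ir_source.aniso_r_cm, ir_source.aniso_theta_deg, ir_source.aniso_f
        r = 0.75 * ra[1] + 0.25 * ra[2]
        t = 0.4 * ta[2] + 0.6 * ta[3]
        wr = (r - ra[1]) / (ra[2] - ra[1])
        wt = (t - ta[2]) / (ta[3] - ta[2])
        expect = (F[1, 2] * (1 - wr) * (1 - wt) + F[2, 2] * wr * (1 - wt)
                  + F[1, 3] * (1 - wr) * wt + F[2, 3] * wr * wt)
        assert anisotropy(ir_source, r, t) == pytest.approx(expect, rel=1e-12)

    def test_anisotropy_clamps_to_table_bounds(self, ir_source):
        inner = anisotropy(ir_source, ir_source.aniso_r_cm[0], 30.0)
        assert anisotropy(ir_source, 0.05, 30.0) == pytest.approx(inner, rel=1e-12)


class TestSpecValidation:
    def _tables(self):
        r = np.array([0.5, 1.0, 5.0])
        return dict(radial_r_cm=r, radial_g=np.ones(3), aniso_r_cm=r,
                    aniso_theta_deg=np.array([0.0, 90.0, 180.0]),
                    aniso_f=np.ones((3, 3)))

    def test_radial_must_contain_unity_at_1cm(self):
        t = self._tables()
        t["radial_g"] = np.array([1.0, 1.01, 1.0])
        with pytest.raises(SourceDataError):
            SourceSpec(active_length_cm=0.36, dose_rate_constant=1.1, **t)

    def test_anisotropy_must_be_unity_at_90(self):
        t = self._tables()
        t["aniso_f"] = np.full((3, 3), 0.9)
        with pytest.raises(SourceDataError):
            SourceSpec(active_length_cm=0.36, dose_rate_constant=1.1, **t)

    def test_radii_strictly_increasing(self):
        t = self._tables()
        t["radial_r_cm"] = np.array([0.5, 1.0, 1.0])
        with pytest.raises(SourceDataError):
            SourceSpec(active_length_cm=0.36, dose_rate_constant=1.1, **t)


class TestDoseRate:
    def test_reference_point_equals_sk_lambda(self, unit_source, ir_source):
        for spec in (unit_source, ir_source):
            dw = DwellSource([0, 0, 0], [0, 0, 1], 123.0)
            got = dose_rate(spec, dw, [10.0, 0.0, 0.0])  # (1 cm, 90 deg)
            assert got == pytest.approx(123.0 * spec.dose_rate_constant, rel=1e-12)

    def test_unit_source_is_inverse_square(self, unit_source):
        dw = DwellSource([0, 0, 0], [0, 0, 1], 100.0)
        got = dose_rate(unit_source, dw, [0.0, 20.0, 0.0])
        assert got == pytest.approx(100.0 * unit_source.dose_rate_constant / 4.0,
                                    rel=1e-12)

    def test_term_by_term_composition(self, ir_source):
        dw = DwellSource([5.0, -3.0, 12.0], [0, 1, 0], 40800.0)
        p = np.array([21.0, 4.0, 2.0])
        rel = (p - dw.position_mm) / 10.0
        r = np.linalg.norm(rel)
        theta = np.degrees(np.arccos(rel @ dw.axis_direction / r))
        expect = (40800.0 * ir_source.dose_rate_constant
                  * geometry_factor(r, theta, ir_source.active_length_cm, "line")
                  / geometry_factor(1.0, 90.0, ir_source.active_length_cm, "line")
                  * radial_dose(ir_source, r) * anisotropy(ir_source, r, theta))
        assert dose_rate(ir_source, dw, p) == pytest.approx(expect, rel=1e-12)

    def test_coincident_point_raises(self, unit_source):
        dw = DwellSource([1.0, 2.0, 3.0], [0, 0, 1], 10.0)
        with pytest.raises(ValueError):
            dose_rate(unit_source, dw, [1.0, 2.0, 3.0])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_rotation_invariance(self, ir_source, seed):
        """Rigidly rotating dwell axis and field point leaves dose unchanged."""
        g = np.random.default_rng(seed)
        R = Rotation.random(random_state=np.random.RandomState(seed)).as_matrix()
        axis = np.array([0.0, 0.0, 1.0])
        point = g.uniform(-30, 30, 3) + np.array([0, 0, 40.0])
        dw = DwellSource([0, 0, 0], axis, 500.0)
        dw_rot = DwellSource([0, 0, 0], R @ axis, 500.0)
        d0 = dose_rate(ir_source, dw, point)
        d1 = dose_rate(ir_source, dw_rot, R @ point)
        assert d1 == pytest.approx(d0, rel=1e-9)

    def test_line_to_point_mode_convergence(self, unit_source):
        short = SourceSpec(
            active_length_cm=1e-5, dose_rate_constant=1.109,
            radial_r_cm=unit_source.radial_r_cm, radial_g=unit_source.radial_g,
            aniso_r_cm=unit_source.aniso_r_cm,
            aniso_theta_deg=unit_source.aniso_theta_deg,
            aniso_f=unit_source.aniso_f, mode="line")
        dw = DwellSource([0, 0, 0], [0, 0, 1], 77.0)
        for p in ([5.0, 0.0, 3.0], [0.0, 7.0, -9.0], [12.0, 5.0, 1.0]):
            assert dose_rate(short, dw, p) == pytest.approx(
                dose_rate(unit_source, dw, p), rel=1e-4)


def test_csv_round_trip(tmp_path, ir_source):
    save_source(ir_source, tmp_path)
    back = load_source(tmp_path)
    np.testing.assert_allclose(back.radial_g, ir_source.radial_g)
    np.testing.assert_allclose(back.aniso_f, ir_source.aniso_f)
    assert back.active_length_cm == ir_source.active_length_cm
    assert back.mode == ir_source.mode
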