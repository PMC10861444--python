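"""Unit and property tests for the per-ray polarization matrix chain."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from opmsim.config import SystemConfig
from opmsim.geometry import direction_grid
from opmsim.raytrace import (
    TransmissionCurve,
    _rz,
    fresnel_transmission,
    interface_power_transmission,
    microscope_matrix,
    quarter_wave_transmission,
    rotation_matrix,
    system_matrix,
    trace_system,
    transmission_mask,
)


class TestRotationMatrix:
    def test_zero_angle_is_identity(self):
        np.testing.assert_allclose(rotation_matrix("z", 0.0), np.eye(3), atol=1e-15)

    def test_quarter_turn_maps_x_to_y(self):
        v = rotation_matrix("z", math.pi / 2) @ np.array([1.0, 0.0, 0.0])
        np.testing.assert_allclose(v, [0.0, 1.0, 0.0], atol=1e-15)

    @given(
        axis=st.sampled_from(["x", "y", "z"]),
        angle=st.floats(-10.0, 10.0, allow_nan=False),
    )
    @settings(max_examples=50, deadline=None)
    def test_orthogonal_unit_determinant_and_inverse(self, axis, angle):
        r = rotation_matrix(axis, angle)
        np.testing.assert_allclose(r @ r.T, np.eye(3), atol=1e-12)
        assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(
            r @ rotation_matrix(axis, -angle), np.eye(3), atol=1e-12
        )


class TestFresnel:
    def test_index_matched_interface_is_transparent(self):
        t_s, t_p = fresnel_transmission(np.linspace(0, 1.4, 7), 1.33, 1.33)
        np.testing.assert_allclose(t_s, 1.0)
        np.testing.assert_allclose(t_p, 1.0)

    def test_normal_incidence_closed_form(self):
        t_s, t_p = fresnel_transmission(0.0, 1.0, 1.5)
        assert t_s == pytest.approx(2 * 1.0 / (1.0 + 1.5))
        assert t_p == pytest.approx(0.8)

    def test_brewster_angle_transmits_all_p_power(self):
        theta_b = math.atan(1.5 / 1.0)
        _, tp_power = interface_power_transmission(theta_b, 1.0, 1.5)
        assert tp_power == pytest.approx(1.0, abs=1e-9)

    def test_beyond_critical_angle_blocked(self):
        t_s, t_p = fresnel_transmission(math.radians(80.0), 1.5, 1.0)
        assert t_s == 0.0 and t_p == 0.0

    @given(theta=st.floats(0.0, 0.7, allow_nan=False))
    @settings(max_examples=30, deadline=None)
    def test_energy_balance_t_plus_r_is_one(self, theta):
        n1, n2 = 1.0, 1.52
        ts_pow, tp_pow = interface_power_transmission(theta, n1, n2)
        tt = math.asin(n1 * math.sin(theta) / n2)
        r_s = (n1 * math.cos(theta) - n2 * math.cos(tt)) / (
            n1 * math.cos(theta) + n2 * math.cos(tt)
        )
        r_p = (n2 * math.cos(theta) - n1 * math.cos(tt)) / (
            n2 * math.cos(theta) + n1 * math.cos(tt)
        )
        assert ts_pow + r_s**2 == pytest.approx(1.0, abs=1e-12)
        assert tp_pow + r_p**2 == pytest.approx(1.0, abs=1e-12)

    def test_monotone_non_increasing_in_theta(self):
        th = np.linspace(0.0, math.radians(85.0), 200)
        ts, tp = interface_power_transmission(th, 1.0, 1.5)
        assert np.all(np.diff(ts) <= 1e-12)
        assert np.all(ts >= 0) and np.all(ts <= 1) and np.all(tp <= 1 + 1e-12)


class TestQuarterWaveCoating:
    def test_perfect_at_normal_incidence(self):
        ts, tp = quarter_wave_transmission(0.0, 1.0, 1.52)
        assert ts == pytest.approx(1.0, abs=1e-12)
        assert tp == pytest.approx(1.0, abs=1e-12)

    def test_collapses_at_grazing(self):
        ts, tp = quarter_wave_transmission(math.radians(89.0), 1.0, 1.52)
        assert ts < 0.15 and tp < 0.2

    def test_beats_uncoated_interface(self):
        # near Brewster the uncoated p-transmittance touches 1, so allow the
        # coating a 1% shortfall there; s must always improve
        th = np.linspace(0, math.radians(80), 50)
        ts_c, tp_c = quarter_wave_transmission(th, 1.0, 1.52)
        ts_u, tp_u = interface_power_transmission(th, 1.0, 1.52)
        assert np.all(ts_c >= ts_u - 1e-9)
        assert np.all(tp_c >= tp_u - 0.01)


class TestTransmissionMask:
    def test_flat_curve_is_lossless(self):
        curve = TransmissionCurve.flat()
        np.testing.assert_allclose(
            transmission_mask(curve, np.linspace(0, 1.5, 9), "s"), 1.0
        )

    def test_amplitude_is_sqrt_of_power(self):
        th = np.linspace(0, math.radians(60), 30)
        curve = TransmissionCurve.fit(
            np.degrees(th), np.full_like(th, 0.81), np.full_like(th, 0.25)
        )
        # fit normalizes to the joint maximum (0.81 here)
        assert transmission_mask(curve, 0.3, "p") == pytest.approx(1.0, abs=1e-6)
        assert transmission_mask(curve, 0.3, "s") == pytest.approx(
            math.sqrt(0.25 / 0.81), abs=1e-6
        )

    def test_out_of_domain_clamps_with_warning(self):
        curve = TransmissionCurve.fit(
            np.linspace(0, 40, 20), np.linspace(1, 0.8, 20), np.linspace(1, 0.6, 20)
        )
        with pytest.warns(UserWarning, match="clamping"):
            edge = curve.power(math.radians(50.0), "s")
        assert edge == pytest.approx(curve.power(math.radians(40.0), "s"), abs=1e-9)

    def test_dry_like_fixture_s_falls_faster_than_p(self):
        from opmsim.fixtures import generate_fixture_transmission

        curve = generate_fixture_transmission("dry_like")
        high = curve.theta_max * 0.98
        assert curve.power(high, "s") < curve.power(high, "p")


class TestMicroscopeMatrix:
    def cfg(self, **kw):
        base = dict(na1=0.9, n1=1.0, na2=0.95, n2=1.0, na3=1.0, n3=1.0,
                    alpha=0.5, o3_coupling="matched",
                    grid_shape=(33, 33, 33), pupil_samples=33)
        base.update(kw)
        return SystemConfig(**base)

    def test_on_axis_ray_reduces_to_identity(self):
        m = microscope_matrix(0.0, self.cfg(tube_na_ratios=(1.0, 1.0, 1.0)), 1)
        np.testing.assert_allclose(m, np.eye(3), atol=1e-12)

    def test_energy_conserved_over_cone(self):
        cfg = self.cfg()
        theta, phi, w = direction_grid(cfg.theta1_max, 60, 120)
        m1 = microscope_matrix(theta, cfg, 1, order="objective_first")
        m2 = microscope_matrix(theta, cfg, 2, order="tube_first")
        full = _rz(phi) @ m2 @ m1 @ _rz(-phi)
        # transverse input field along the meridional unit vector
        e_in = np.stack(
            [np.cos(theta) * np.cos(phi), np.cos(theta) * np.sin(phi), -np.sin(theta)],
            -1,
        )
        e_out = np.einsum("...ij,...j->...i", full, e_in)
        p_in = (np.einsum("...i,...i->...", e_in, e_in) * w).sum()
        p_out = (np.einsum("...i,...i->...", e_out, e_out) * w).sum()
        assert p_out / p_in == pytest.approx(1.0, abs=1e-3)

    def test_matches_meridional_sagittal_decomposition_oracle(self):
        """Brute-force oracle: split the field into meridional/sagittal parts
        and rotate each explicitly through the sine-condition telescope."""
        cfg = self.cfg()
        theta, phi = 0.61, 2.3
        full = _rz(phi) @ microscope_matrix(theta, cfg, 1) @ _rz(-phi)
        ratio = cfg.tube_ratio(1)
        theta_t = math.asin(ratio * cfg.n1 * math.sin(theta))
        e_s = np.array([-math.sin(phi), math.cos(phi), 0.0])
        e_p_in = np.array(
            [math.cos(theta) * math.cos(phi), math.cos(theta) * math.sin(phi), -math.sin(theta)]
        )
        e_p_out = np.array(
            [math.cos(theta_t) * math.cos(phi), math.cos(theta_t) * math.sin(phi), -math.sin(theta_t)]
        )
        apod = math.sqrt(math.cos(theta_t) / math.cos(theta))
        for a, b in [(1.0, 0.0), (0.0, 1.0), (0.6, -0.8)]:
            e_in = a * e_p_in + b * e_s
            expected = apod * (a * e_p_out + b * e_s)
            np.testing.assert_allclose(full @ e_in, expected, atol=1e-12)

    def test_ray_outside_acceptance_is_vignetted(self):
        m = microscope_matrix(1.5, self.cfg(), 2)
        np.testing.assert_allclose(m, 0.0)


class TestSystemMatrix:
    def test_untilted_unity_relay_is_identity_on_transverse_components(self):
        cfg = SystemConfig(
            na1=0.5, na2=0.6, na3=0.7, n1=1.0, n2=1.0, n3=1.0,
            alpha=1e-9, o3_coupling="matched", tube_na_ratios=(1.0, 1.0, 1.0),
            grid_shape=(33, 33, 33),
        )
        t, alive = system_matrix(0.35, 1.2, cfg, sample_referred=True)
        assert alive
        np.testing.assert_allclose(t, np.eye(3), atol=1e-7)

    def test_passivity_sample_referred(self, small_config):
        rng = np.random.default_rng(5)
        theta = rng.uniform(0, small_config.theta1_max, 50)
        phi = rng.uniform(0, 2 * math.pi, 50)
        t, _ = system_matrix(theta, phi, small_config, sample_referred=True)
        e = rng.normal(size=(50, 3)) + 1j * rng.normal(size=(50, 3))
        out = np.einsum("...ij,...j->...i", t, e)
        assert np.all(
            np.linalg.norm(out, axis=-1) <= np.linalg.norm(e, axis=-1) * (1 + 1e-9)
        )

    def test_factor_by_factor_oracle(self, small_config):
        """The composed chain equals the sequential product of its eleven
        factor matrices built independently (scipy rotations, explicit
        diagonal masks) at a tilted configuration."""
        from scipy.spatial.transform import Rotation
        from opmsim.raytrace import _o3_interface_amplitudes

        cfg = small_config
        theta1, phi = 0.7, 1.1
        alpha = cfg.alpha

        def rot(axis, ang):
            return Rotation.from_euler(axis, ang).as_matrix()

        m1 = np.asarray(microscope_matrix(theta1, cfg, 1, "objective_first"))
        m2 = np.asarray(microscope_matrix(theta1, cfg, 2, "tube_first"))
        d = np.array(
            [math.sin(theta1) * math.cos(phi), math.sin(theta1) * math.sin(phi), math.cos(theta1)]
        )
        rt = rot("x", -alpha)  # lab -> tilted components
        dt = rt @ d
        theta_inc = math.acos(dt[2])
        phi_a = math.atan2(dt[1], dt[0])
        amp_p, amp_s, theta3, _ = _o3_interface_amplitudes(cfg, theta_inc)
        ft = np.diag([float(amp_p), float(amp_s), float(amp_p)])
        cfg3 = cfg.replace(transmission={**cfg.transmission, "o3": None})
        m3 = np.asarray(microscope_matrix(float(theta3), cfg3, 3, "objective_first"))
        expected = (
            rot("z", phi_a)
            @ m3
            @ rot("y", float(theta3))
            @ ft
            @ rot("y", -theta_inc)
            @ rot("z", -phi_a)
            @ rt
            @ rot("z", phi)
            @ m2
            @ m1
            @ rot("z", -phi)
        )
        t, alive = system_matrix(theta1, phi, cfg, sample_referred=False)
        assert alive
        np.testing.assert_allclose(t, expected, atol=1e-12)

    def test_lossless_chain_conserves_power_over_bundle(self, lossless_config):
        cfg = lossless_config
        theta, phi, w = direction_grid(min(cfg.theta1_max, cfg.theta2_max), 80, 160)
        g, alive = trace_system(cfg, theta, phi)
        r = np.stack(
            [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)], -1
        )
        for p in (np.array([1.0, 0, 0]), np.array([0, 0.6, 0.8])):
            p_in = 3 / (8 * np.pi) * (1 - (r @ p) ** 2)
            e_out = np.einsum("...ij,j->...i", g, p)
            p_out = np.einsum("...i,...i->...", e_out, e_out.conj()).real
            ratio = (p_out * w)[alive].sum() / (p_in * w)[alive].sum()
            assert ratio == pytest.approx(1.0, abs=1e-3)

    def test_mirror_symmetry_about_tilt_plane(self, small_config):
        """x -> -x mirror: the chain maps mirrored dipoles at mirrored rays to
        fields of identical intensity (the system is symmetric about the
        yz-plane containing the tilt)."""
        cfg = small_config
        rng = np.random.default_rng(11)
        theta = rng.uniform(0.05, cfg.theta1_max, 20)
        phi = rng.uniform(-math.pi, math.pi, 20)
        g1, a1 = trace_system(cfg, theta, phi)
        g2, a2 = trace_system(cfg, theta, math.pi - phi)
        mirror = np.diag([-1.0, 1.0, 1.0])
        for p in (np.array([1.0, 0, 0]), np.array([0, 1.0, 0]), np.array([0.5, -0.5, 0.707])):
            i1 = np.sum(np.abs(np.einsum("...ij,j->...i", g1, p)) ** 2, -1)
            i2 = np.sum(np.abs(np.einsum("...ij,j->...i", g2, mirror @ p)) ** 2, -1)
            both = a1 & a2
            np.testing.assert_allclose(i1[both], i2[both], rtol=1e-9, atol=1e-15)
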