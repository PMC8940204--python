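"""Anisotropic half-space forward model: kernel, impedance, closed forms."""

import cmath
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tonguevcp import (
    EPSILON_0,
    AnisotropicMedium,
    SurfacePoint,
    TetrapolarConfig,
    apparent_conductivity_closed_form,
    build_default_array,
    complex_conductivities,
    geometric_factor,
    point_source_kernel,
    transfer_impedance,
    transfer_impedance_complex,
)

TWO_PI = 2.0 * math.pi


def collinear_config(theta_deg, positions=(-0.007, 0.007, -0.004, 0.004)):
    """Build a collinear tetrapolar config at angle theta from scalar positions."""
    a, b, m, n = (SurfacePoint(p, 0.0).rotated(theta_deg) for p in positions)
    return TetrapolarConfig(theta_deg, A=a, B=b, M=m, N=n)


media = st.builds(
    AnisotropicMedium,
    sigma_L=st.floats(0.05, 2.0),
    sigma_T=st.floats(0.05, 2.0),
    eps_rL=st.floats(0.0, 1e5),
    eps_rT=st.floats(0.0, 1e5),
)
frequencies = st.sampled_from([8000.0, 16000.0, 32000.0, 64000.0, 128000.0, 256000.0])


class TestComplexConductivities:
    def test_zero_permittivity_is_purely_real(self):
        med = AnisotropicMedium(0.7, 0.5)
        s_l, s_t = complex_conductivities(med, 32000.0)
        assert s_t == 0.5 + 0j and s_l == 0.7 + 0j

    def test_imaginary_part_matches_omega_eps(self):
        med = AnisotropicMedium(0.7, 0.5, eps_rT=30000.0)
        _, s_t = complex_conductivities(med, 8000.0)
        assert s_t.imag == pytest.approx(TWO_PI * 8000.0 * EPSILON_0 * 30000.0,
                                         rel=1e-14)

    def test_imaginary_part_linear_in_frequency(self):
        med = AnisotropicMedium(0.7, 0.5, eps_rL=2e4, eps_rT=2e4)
        s1 = complex_conductivities(med, 16000.0)[0]
        s2 = complex_conductivities(med, 32000.0)[0]
        assert s2.imag == pytest.approx(2.0 * s1.imag, rel=1e-14)

    def test_nonpositive_frequency_rejected(self):
        with pytest.raises(ValueError):
            complex_conductivities(AnisotropicMedium(1.0, 1.0), 0.0)


class TestPointSourceKernel:
    def test_isotropic_closed_form(self):
        sigma = 0.5 + 0j
        d = math.hypot(0.003, 0.004)
        k = point_source_kernel(0.003, 0.004, sigma, sigma)
        assert k == pytest.approx(1.0 / (TWO_PI * 0.5 * d), rel=1e-14)

    def test_even_symmetry(self):
        k1 = point_source_kernel(0.002, -0.005, 1.0 + 0.1j, 0.3 + 0.02j)
        k2 = point_source_kernel(-0.002, 0.005, 1.0 + 0.1j, 0.3 + 0.02j)
        assert k1 == k2

    def test_hand_computed_anisotropic_value(self):
        # f = sqrt(0.25 * (0.25 * 1e-4)) = 0.0025 at (dx, dy) = (0.01, 0)
        k = point_source_kernel(0.01, 0.0, 1.0 + 0j, 0.25 + 0j)
        assert k == pytest.approx(1.0 / (TWO_PI * 0.0025), rel=1e-14)

    def test_coincident_point_rejected(self):
        with pytest.raises(ValueError):
            point_source_kernel(0.0, 0.0, 1.0, 1.0)


class TestGeometricFactor:
    def test_default_array_value(self, default_array):
        k = geometric_factor(default_array.config_for(0.0))
        assert k == pytest.approx((2 / 0.003 - 2 / 0.011) / TWO_PI, rel=1e-14)

    def test_wenner_closed_form(self):
        a = 0.005
        cfg = TetrapolarConfig(
            0.0,
            A=SurfacePoint(-1.5 * a, 0.0), B=SurfacePoint(1.5 * a, 0.0),
            M=SurfacePoint(-0.5 * a, 0.0), N=SurfacePoint(0.5 * a, 0.0),
        )
        assert geometric_factor(cfg) == pytest.approx(1.0 / (TWO_PI * a), rel=1e-14)

    def test_scaling(self):
        cfg1 = collinear_config(0.0)
        s = 2.5
        cfg2 = collinear_config(0.0, tuple(p * s for p in (-0.007, 0.007, -0.004, 0.004)))
        assert geometric_factor(cfg2) == pytest.approx(geometric_factor(cfg1) / s,
                                                       rel=1e-14)


class TestTransferImpedance:
    def test_isotropic_equals_k_over_sigma(self, default_array):
        cfg = default_array.config_for(0.0)
        z = transfer_impedance(cfg, AnisotropicMedium(0.5, 0.5), 8000.0)
        assert z == pytest.approx(geometric_factor(cfg) / 0.5, rel=1e-12)
        # the isotropic 0.5 S/m check lands inside the in vivo impedance band
        assert 100.0 < abs(z) < 300.0

    def test_reciprocity(self, default_array):
        cfg = default_array.config_for(45.0)
        swapped = TetrapolarConfig(45.0, A=cfg.M, B=cfg.N, M=cfg.A, N=cfg.B)
        med = AnisotropicMedium(0.9, 0.3, 2e4, 3e4)
        z1 = transfer_impedance(cfg, med, 64000.0)
        z2 = transfer_impedance(swapped, med, 64000.0)
        assert abs(z1 - z2) / abs(z1) < 1e-12

    def test_conductivity_scaling(self, default_array):
        cfg = default_array.config_for(150.0)
        z1 = transfer_impedance(cfg, AnisotropicMedium(0.8, 0.2), 8000.0)
        z2 = transfer_impedance(cfg, AnisotropicMedium(2.4, 0.6), 8000.0)
        assert z2 == pytest.approx(z1 / 3.0, rel=1e-12)

    def test_geometry_scaling(self):
        med = AnisotropicMedium(0.9, 0.3, 1e4, 1e4)
        s = 3.0
        z1 = transfer_impedance(collinear_config(45.0), med, 32000.0)
        z2 = transfer_impedance(
            collinear_config(45.0, (-0.007 * s, 0.007 * s, -0.004 * s, 0.004 * s)),
            med, 32000.0)
        assert z2 == pytest.approx(z1 / s, rel=1e-12)


class TestApparentConductivity:
    def test_paradox_at_zero_degrees(self):
        s_l, s_t = 0.9 + 0.01j, 0.3 + 0.003j
        assert apparent_conductivity_closed_form(0.0, s_l, s_t) == pytest.approx(s_t,
                                                                                 rel=1e-14)

    def test_geometric_mean_at_ninety(self):
        s_l, s_t = 0.9 + 0.01j, 0.3 + 0.003j
        expected = cmath.sqrt(s_l * s_t)
        assert apparent_conductivity_closed_form(90.0, s_l, s_t) == pytest.approx(
            expected, rel=1e-14)

    def test_hand_computed_45_degrees(self):
        # sqrt(0.2 * (0.2*0.5 + 0.8*0.5)) = sqrt(0.1)
        val = apparent_conductivity_closed_form(45.0, 0.8 + 0j, 0.2 + 0j)
        assert val.real == pytest.approx(math.sqrt(0.1), rel=1e-14)
        assert val.imag == pytest.approx(0.0, abs=1e-16)

    def test_monotonic_in_angle_when_longitudinal_dominates(self):
        s_l, s_t = 1.2 + 0j, 0.2 + 0j
        values = [apparent_conductivity_closed_form(t, s_l, s_t).real
                  for t in range(0, 91, 5)]
        assert all(b > a for a, b in zip(values, values[1:]))


class TestOracleEquivalence:
    """k / Z must equal the closed-form apparent conductivity for any
    collinear configuration at any angle from the fiber axis."""

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(medium=media, frequency=frequencies,
           theta=st.floats(0.0, 180.0),
           fiber=st.sampled_from([0.0, 10.0, -30.0]))
    def test_k_over_z_matches_closed_form(self, medium, frequency, theta, fiber):
        cfg = collinear_config(theta)
        med = AnisotropicMedium(medium.sigma_L, medium.sigma_T,
                                medium.eps_rL, medium.eps_rT, fiber_angle_deg=fiber)
        z = transfer_impedance(cfg, med, frequency)
        s_l, s_t = complex_conductivities(med, frequency)
        expected = apparent_conductivity_closed_form(theta - fiber, s_l, s_t)
        assert abs(geometric_factor(cfg) / z - expected) / abs(expected) < 1e-10

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(medium=media, frequency=frequencies)
    def test_isotropic_limit_direction_independent(self, medium, frequency):
        sigma, eps = medium.sigma_T, medium.eps_rT
        med = AnisotropicMedium(sigma, sigma, eps, eps)
        s_iso = complex_conductivities(med, frequency)[0]
        arr = build_default_array()
        for d in arr.directions:
            cfg = arr.config_for(d)
            sapp = geometric_factor(cfg) / transfer_impedance(cfg, med, frequency)
            assert abs(sapp - s_iso) / abs(s_iso) < 1e-12
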