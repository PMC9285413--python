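"""Shell geometry and wall-stress primitives."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gravicor import geometry
from gravicor.errors import ConfigError
from gravicor.geometry import (
    SHAPE_COEFFICIENTS,
    chamber_geometry,
    laplace_sphere_stress,
    lumen_radius,
    meridional_stress,
    wall_thickness,
)


class TestLumenRadius:
    def test_unit_sphere(self):
        assert lumen_radius("sphere", 4 * np.pi / 3) == pytest.approx(1.0)

    def test_half_ellipsoid_inversion(self):
        # V = 2*pi*r^3 with r = 2
        assert lumen_radius("half_ellipsoid", 2 * np.pi * 8) == pytest.approx(2.0)

    def test_unknown_shape(self):
        with pytest.raises(ConfigError):
            lumen_radius("cube", 1.0)

    @given(
        st.floats(1.0, 300.0),
        st.sampled_from(sorted(SHAPE_COEFFICIENTS)),
    )
    def test_round_trip(self, volume, shape):
        r = lumen_radius(shape, volume)
        back = SHAPE_COEFFICIENTS[shape] * r**3
        assert back == pytest.approx(volume, rel=1e-12)


class TestWallThickness:
    def test_vanishing_wall(self):
        assert wall_thickness("sphere", 1.0, 1e-12) == pytest.approx(0.0, abs=1e-9)

    def test_constructed_shell(self):
        vwall = (4 * np.pi / 3) * (2**3 - 1**3)
        assert wall_thickness("sphere", 1.0, vwall) == pytest.approx(1.0)

    @given(st.floats(0.5, 5.0), st.floats(0.5, 200.0))
    def test_against_bisection(self, r, vwall):
        """Closed-form root matches an independent bisection solve."""
        k = SHAPE_COEFFICIENTS["quarter_ellipsoid"]
        h = wall_thickness("quarter_ellipsoid", r, vwall)
        lo, hi = 0.0, 10.0 + vwall
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if k * ((r + mid) ** 3 - r**3) < vwall:
                lo = mid
            else:
                hi = mid
        assert h == pytest.approx(0.5 * (lo + hi), abs=1e-9)

    def test_geometry_consistency_check(self):
        g = chamber_geometry("sphere", 50.0, 5.0)
        shell = g.k_shape * ((g.r + g.h) ** 3 - g.r**3)
        assert shell == pytest.approx(g.vwall, rel=1e-12)


class TestVentricularStress:
    def test_clinical_formula_arithmetic(self):
        # P = 100 mmHg, r = 2.5 cm, h = 1 cm -> 250/2.4
        assert meridional_stress(100.0, 2.5, 1.0) == pytest.approx(104.1667, rel=1e-4)

    @given(st.floats(5.0, 200.0), st.floats(0.5, 5.0), st.floats(0.05, 3.0))
    def test_equivalent_to_force_balance(self, p, r, h):
        """Clinical form == meridional force balance sigma*(Ro^2-Ri^2)=P*Ri^2."""
        ro = r + h
        balance = p * r**2 / (ro**2 - r**2)
        assert meridional_stress(p, r, h) == pytest.approx(balance, rel=1e-12)

    def test_thin_wall_limit_matches_laplace(self):
        p, r, h = 80.0, 2.0, 1e-5
        assert meridional_stress(p, r, h) == pytest.approx(
            laplace_sphere_stress(p, r, h), rel=1e-4
        )

    @given(st.floats(0.1, 1.5))
    def test_decreasing_in_thickness(self, h):
        """Thicker wall always carries less stress (growth feedback
        stability)."""
        s1 = meridional_stress(100.0, 2.5, h)
        s2 = meridional_stress(100.0, 2.5, h * 1.1)
        assert s2 < s1


class TestAtrialStress:
    def test_laplace_arithmetic(self):
        assert laplace_sphere_stress(10.0, 2.0, 0.2) == pytest.approx(50.0)

    def test_halves_when_thickness_doubles(self):
        assert laplace_sphere_stress(10.0, 2.0, 0.4) == pytest.approx(25.0)

    def test_sinusoidal_pressure_quadrature(self):
        """For fixed geometry the beat average equals mean(P)*r/(2h)."""
        from gravicor.hemo import BeatRecord

        class FakeBeat:
            time = np.linspace(0.0, 1.0, 2001)
            acc = None

            def chamber_shape(self, c):
                return "sphere"

            def chamber_vwall(self, c):
                # shell for r=2, h=0.1
                return SHAPE_COEFFICIENTS["sphere"] * (2.1**3 - 2.0**3)

            def chamber_volume(self, c):
                return np.full(2001, SHAPE_COEFFICIENTS["sphere"] * 8.0)

            def chamber_pressure(self, c):
                return 8.0 + 3.0 * np.sin(2 * np.pi * FakeBeat.time)

            def mean_laplace_stress(self, c):
                return None

        got = geometry.atrial_mean_stress(FakeBeat(), "LA")
        want = 8.0 * 2.0 / (2 * 0.1)
        assert got == pytest.approx(want, rel=1e-3)


class TestWallShearStress:
    def test_poiseuille_arithmetic(self):
        # 4*mu*q/(pi*r^3) with mu=0.035 P, q=80 ml/s, r=2 cm
        sigma = 4 * 0.035 * 80 / (np.pi * 8.0)
        assert sigma == pytest.approx(0.4456, rel=1e-3)

    def test_linear_in_viscosity_and_positive(self, baseline):
        beat = baseline.beat
        s1 = geometry.chamber_wall_shear_stress(beat, "LV", 0.035)
        s2 = geometry.chamber_wall_shear_stress(beat, "LV", 0.070)
        assert s2 == pytest.approx(2 * s1, rel=1e-12)
        assert s1 > 0

    @given(st.floats(20.0, 200.0))
    def test_cubic_decay_with_radius(self, volume):
        """Doubling the chamber radius at fixed flow divides the shear by
        eight (synthetic single-chamber beat)."""

        class FakeBeat:
            acc = None
            time = np.linspace(0, 1, 11)

            def __init__(self, v):
                self._v = v

            def mean_inlet_flow(self, c):
                return 80.0

            def mean_abs_outlet_flow(self, c):
                return 80.0

            def mean_radius(self, c):
                return None

            def chamber_shape(self, c):
                return "sphere"

            def chamber_volume(self, c):
                return np.full(11, self._v)

        s1 = geometry.chamber_wall_shear_stress(FakeBeat(volume), "LA", 0.035)
        s8 = geometry.chamber_wall_shear_stress(FakeBeat(8 * volume), "LA", 0.035)
        assert s8 == pytest.approx(s1 / 8, rel=1e-9)
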