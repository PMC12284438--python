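"""Wall-model properties: deviatoric structure, symmetry limits, tube law."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pulmo1d import wall
from pulmo1d.wall import (
    ConstitutiveParams,
    StretchState,
    WallGeometry,
    apply_stiffness_scaling,
    area_from_pressure,
    cauchy_to_second_pk,
    fiber_invariant,
    isochoric_stress,
    linear_tube_law,
    tangent_stiffness,
    transmural_pressure,
    uniaxial_curve,
    uniaxial_response,
)


class TestTypes:
    def test_stretch_state_enforces_incompressibility(self):
        with pytest.raises(ValueError, match="incompressibility"):
            StretchState(1.0, 1.2, 1.2)
        st_ = StretchState.from_theta_z(1.2, 1.3)
        assert st_.lambda_r * st_.lambda_theta * st_.lambda_z == pytest.approx(1.0)

    @pytest.mark.parametrize("kwargs", [
        dict(c=-1, k1=1, k2=1, beta=45),
        dict(c=1, k1=-1, k2=1, beta=45),
        dict(c=1, k1=1, k2=0, beta=45),
        dict(c=1, k1=1, k2=1, beta=95),
    ])
    def test_invalid_constitutive_params(self, kwargs):
        with pytest.raises(ValueError):
            ConstitutiveParams(**kwargs)

    def test_wall_geometry_requires_moderate_thickness(self):
        with pytest.raises(ValueError):
            WallGeometry(0.1, 0.2)


class TestFiberInvariant:
    def test_identity_stretch_gives_zero(self):
        for beta in (0.0, 30.0, 90.0):
            assert fiber_invariant(StretchState(1, 1, 1), beta) == pytest.approx(0.0)

    def test_axial_fibers_only_see_axial_stretch(self):
        st_ = StretchState.from_theta_z(1.1, 1.3)
        assert fiber_invariant(st_, 90.0) == pytest.approx(1.3**2 - 1, abs=1e-12)

    @given(lt=st.floats(0.8, 1.5), lz=st.floats(0.8, 1.5))
    @settings(max_examples=30, deadline=None)
    def test_45_degrees_symmetric_under_inplane_swap(self, lt, lz):
        a = fiber_invariant(StretchState.from_theta_z(lt, lz), 45.0)
        b = fiber_invariant(StretchState.from_theta_z(lz, lt), 45.0)
        assert a == pytest.approx(b, abs=1e-12)


class TestIsochoricStress:
    def test_identity_stretch_is_stress_free(self, control_params):
        assert isochoric_stress(StretchState(1, 1, 1), control_params) == \
            pytest.approx((0.0, 0.0, 0.0), abs=1e-12)

    def test_trace_free_for_random_states(self, control_params, rng):
        for _ in range(1000):
            lt, lz = rng.uniform(0.7, 1.6, size=2)
            s = isochoric_stress(StretchState.from_theta_z(lt, lz), control_params)
            # trace-free to numerical precision, relative to the stress scale
            assert abs(sum(s)) < 1e-10 * max(1.0, max(abs(x) for x in s))

    def test_neo_hookean_axial_minus_radial(self):
        p = ConstitutiveParams(10.0, 0.0, 1.0, 45.0)
        st_ = StretchState.from_theta_z(1.5**-0.5, 1.5)
        s_rr, _, s_zz = isochoric_stress(st_, p)
        assert s_zz - s_rr == pytest.approx(10.0 * (1.5**2 - 1 / 1.5), rel=1e-12)

    def test_overflow_guard_names_the_stretch(self):
        p = ConstitutiveParams(10.0, 100.0, 50.0, 90.0)
        with pytest.raises(OverflowError, match="alpha"):
            isochoric_stress(StretchState.from_theta_z(1.0, 4.0), p)

    def test_compressed_fibers_drop_out_under_tension_only_switch(self):
        p = ConstitutiveParams(10.0, 100.0, 5.0, 90.0)  # purely axial fibers
        st_ = StretchState.from_theta_z(1.2, 0.9)       # axially shortened
        with_fibers = isochoric_stress(st_, p, tension_only=False)
        without = isochoric_stress(st_, p, tension_only=True)
        nh = isochoric_stress(st_, ConstitutiveParams(10.0, 0.0, 5.0, 90.0))
        assert without == pytest.approx(nh, abs=1e-12)
        assert with_fibers != pytest.approx(without)


class TestUniaxialResponse:
    def test_reference_stretch_is_stress_free(self, control_params):
        for d in ("circumferential", "longitudinal"):
            stress, _ = uniaxial_response(d, 1.0, control_params)
            assert stress == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("direction", ["circumferential", "longitudinal"])
    def test_neo_hookean_closed_form(self, direction):
        p = ConstitutiveParams(10.0, 0.0, 1.0, 45.0)
        lams = np.linspace(1.01, 1.6, 9)
        got = uniaxial_curve(direction, lams, p)
        want = 10.0 * (lams**2 - 1.0 / lams)
        np.testing.assert_allclose(got, want, rtol=1e-8)

    def test_beta_45_makes_directions_identical(self):
        p = ConstitutiveParams(8.0, 120.0, 4.0, 45.0)
        lams = np.linspace(1.0, 1.5, 11)
        circ = uniaxial_curve("circumferential", lams, p)
        long = uniaxial_curve("longitudinal", lams, p)
        np.testing.assert_allclose(circ, long, rtol=1e-9, atol=1e-9)

    def test_lateral_stresses_vanish_at_solution(self, control_params):
        stress, state = uniaxial_response("longitudinal", 1.4, control_params)
        s = isochoric_stress(state, control_params)
        assert s[0] + state.p == pytest.approx(0.0, abs=1e-8)  # radial
        assert s[1] + state.p == pytest.approx(0.0, abs=1e-8)  # circumferential
        assert s[2] + state.p == pytest.approx(stress, rel=1e-10)

    def test_compression_rejected(self, control_params):
        with pytest.raises(ValueError, match="tension"):
            uniaxial_response("longitudinal", 0.9, control_params)


class TestStressConversions:
    def test_second_pk_from_cauchy(self):
        assert cauchy_to_second_pk(15.833333, 1.5) == pytest.approx(7.037037, rel=1e-6)
        assert cauchy_to_second_pk(0.0, 1.2) == 0.0
        with pytest.raises(ValueError):
            cauchy_to_second_pk(1.0, -1.0)

    def test_fifty_percent_stretch_is_625_green_strain(self):
        assert wall.green_strain(1.5) == pytest.approx(0.625)
        assert wall.stretch_from_green(0.625) == pytest.approx(1.5)


class TestTubeLaw:
    def test_zero_pressure_at_reference_area(self, mpa_geom, control_params):
        a0 = math.pi * mpa_geom.r0**2
        assert transmural_pressure(a0, mpa_geom, control_params) == pytest.approx(0.0, abs=1e-12)

    def test_monotone_increasing_in_area(self, mpa_geom, control_params):
        a0 = math.pi * mpa_geom.r0**2
        areas = np.linspace(0.5 * a0, 2.0 * a0, 40)
        p = [transmural_pressure(a, mpa_geom, control_params) for a in areas]
        assert np.all(np.diff(p) > 0)

    def test_inverse_round_trips(self, mpa_geom, control_params):
        a0 = math.pi * mpa_geom.r0**2
        for a in (0.7 * a0, a0, 1.3 * a0, 1.8 * a0):
            p = transmural_pressure(a, mpa_geom, control_params)
            back = area_from_pressure(p, mpa_geom, control_params)
            assert abs(back - a) / a < 1e-8

    def test_thin_wall_matches_laplace(self, control_params):
        geom = WallGeometry.from_ratio(0.2, 0.01)
        a = 1.3 * math.pi * geom.r0**2
        p = transmural_pressure(a, geom, control_params)
        # Laplace estimate: mid-wall (sigma_theta - sigma_r) * h / r
        ri = math.sqrt(a / math.pi)
        ro = math.sqrt(ri**2 + (geom.r0 + geom.h0) ** 2 - geom.r0**2)
        rm = 0.5 * (ri + ro)
        lt = rm / math.sqrt(geom.r0**2 + rm**2 - ri**2)
        laplace = float(wall._delta_theta_r(lt, 1.0, control_params, True)) \
            * (ro - ri) / rm * wall.KPA_TO_MMHG
        assert p == pytest.approx(laplace, rel=0.03)

    def test_axial_prestretch_shifts_reference(self, mpa_geom, control_params):
        a_ref = wall.reference_area(mpa_geom, control_params, lambda_z=1.2)
        p = transmural_pressure(a_ref, mpa_geom, control_params, lambda_z=1.2)
        assert p == pytest.approx(0.0, abs=1e-9)


class TestStiffnessScaling:
    def test_identity_and_arithmetic(self, control_params):
        assert apply_stiffness_scaling(control_params, 1.0) == control_params
        doubled = apply_stiffness_scaling(control_params, 2.0)
        assert (doubled.c, doubled.k1) == (20.0, 200.4)
        assert (doubled.k2, doubled.beta) == (control_params.k2, control_params.beta)
        with pytest.raises(ValueError):
            apply_stiffness_scaling(control_params, 0.0)

    def test_pressure_is_homogeneous_in_wall_constants(self, mpa_geom, control_params):
        a = 1.4 * math.pi * mpa_geom.r0**2
        p1 = transmural_pressure(a, mpa_geom, control_params)
        p2 = transmural_pressure(a, mpa_geom, apply_stiffness_scaling(control_params, 2.0))
        assert p2 == pytest.approx(2.0 * p1, rel=1e-12)

    def test_stiffer_wall_has_smaller_area_at_fixed_pressure(self, mpa_geom, control_params):
        p_star = 15.0  # mmHg
        a1 = area_from_pressure(p_star, mpa_geom, control_params)
        a2 = area_from_pressure(p_star, mpa_geom, apply_stiffness_scaling(control_params, 2.0))
        assert a2 < a1


class TestLinearTubeLaw:
    def test_zero_at_reference(self, mpa_geom, control_params):
        a0 = math.pi * mpa_geom.r0**2
        k = tangent_stiffness(mpa_geom, control_params)
        assert linear_tube_law(a0, mpa_geom, k) == 0.0

    def test_tangent_matched_at_small_deformation(self, mpa_geom, control_params):
        a0 = math.pi * mpa_geom.r0**2
        k = tangent_stiffness(mpa_geom, control_params)
        p_lin = linear_tube_law(1.01 * a0, mpa_geom, k)
        p_nl = transmural_pressure(1.01 * a0, mpa_geom, control_params)
        assert p_lin == pytest.approx(p_nl, rel=0.02)

    def test_nonlinear_exceeds_linear_at_large_deformation(self, mpa_geom, control_params):
        a0 = math.pi * mpa_geom.r0**2
        k = tangent_stiffness(mpa_geom, control_params)
        assert transmural_pressure(1.5 * a0, mpa_geom, control_params) > \
            linear_tube_law(1.5 * a0, mpa_geom, k)
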