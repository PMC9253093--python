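"""Neutral-buoyancy solution, hydrostatic centres, stability, and
orientation angles."""

import dataclasses
import math

import numpy as np
import pytest

from ectoswim.hydro import (
    DensityTable,
    apertural_orientation,
    chamber_fill_fraction,
    compute_hydrostatics,
    fit_body_chamber,
    model_from_conch,
    scale_to_displaced_mass,
    stability_index,
    thrust_angle,
    total_center_of_mass,
)


@pytest.fixture
def densities():
    return DensityTable()


class TestChamberFill:
    def test_phi_zero_when_residual_density_is_liquid(self, densities):
        # choose V_wd so that R == rho_cl exactly
        v_sb, v_sh, v_ct = 700.0, 100.0, 200.0
        v_wd = (v_ct * densities.cameral_liquid + v_sb * densities.soft_body
                + v_sh * densities.shell) / densities.water_displaced
        fill = chamber_fill_fraction(v_wd, v_sb, v_sh, v_ct, densities)
        assert fill.phi == pytest.approx(0.0, abs=1e-12)
        assert fill.liquid_fraction == pytest.approx(1.0, abs=1e-12)

    def test_phi_one_when_residual_density_is_gas(self, densities):
        v_sb, v_sh, v_ct = 700.0, 100.0, 200.0
        v_wd = (v_ct * densities.cameral_gas + v_sb * densities.soft_body
                + v_sh * densities.shell) / densities.water_displaced
        fill = chamber_fill_fraction(v_wd, v_sb, v_sh, v_ct, densities)
        assert fill.phi == pytest.approx(1.0, abs=1e-12)

    def test_worked_example_mass_balance(self, densities):
        # plugging the solved fill back must balance organismal and
        # displaced mass identically
        fill = chamber_fill_fraction(1000.0, 700.0, 100.0, 200.0, densities)
        organismal = (
            700.0 * densities.soft_body + 100.0 * densities.shell
            + 200.0 * (fill.phi * densities.cameral_gas
                       + (1 - fill.phi) * densities.cameral_liquid)
        )
        displaced = 1000.0 * densities.water_displaced
        assert abs(organismal - displaced) / displaced < 1e-9
        assert abs(fill.residual) / displaced < 1e-9

    def test_complement_identity_exact(self, densities):
        fill = chamber_fill_fraction(1000.0, 650.0, 120.0, 230.0, densities)
        assert fill.phi + fill.liquid_fraction == 1.0

    def test_out_of_range_flagged_not_raised(self, densities):
        # hugely heavy shell: no gas fill can save it
        fill = chamber_fill_fraction(1000.0, 900.0, 500.0, 100.0, densities)
        assert not fill.attainable
        assert fill.phi > 1.0 or fill.phi < 0.0

    def test_zero_chamber_volume_rejected(self, densities):
        with pytest.raises(ValueError):
            chamber_fill_fraction(1000.0, 700.0, 100.0, 0.0, densities)


class TestCenterOfMass:
    def test_single_component_identity(self):
        c = total_center_of_mass([(5.0, (1.0, 2.0, 3.0))])
        assert c == pytest.approx([1.0, 2.0, 3.0])

    def test_weighted_mean(self):
        c = total_center_of_mass([(2.0, (0, 0, 0)), (1.0, (3.0, 0, 0))])
        assert c[0] == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_density_field(self):
        # 5 random point components vs direct weighted sum
        rng = np.random.default_rng(7)
        comps = [(float(rng.uniform(0.5, 5)), rng.normal(size=3))
                 for _ in range(5)]
        expect = sum(m * c for m, c in comps) / sum(m for m, _ in comps)
        assert total_center_of_mass(comps) == pytest.approx(expect, rel=1e-12)

    def test_zero_mass_rejected(self):
        with pytest.raises(ValueError):
            total_center_of_mass([(0.0, (0, 0, 0))])


class TestStabilityIndex:
    def test_zero_when_centers_coincide(self):
        assert stability_index((1, 2, 3), (1, 2, 3), 10.0) == 0.0

    def test_unit_case(self):
        assert stability_index((0, 0, 1), (0, 0, 0), 1.0) == pytest.approx(1.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            B, M = rng.normal(size=3), rng.normal(size=3)
            v = float(rng.uniform(0.1, 1000))
            k = float(rng.uniform(0.01, 100))
            st0 = stability_index(B, M, v)
            st1 = stability_index(k * B, k * M, k ** 3 * v)
            assert abs(st1 - st0) < 1e-12 * max(st0, 1.0)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(4)
        B, M, v = rng.normal(size=3), rng.normal(size=3), 42.0
        q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        assert stability_index(q @ B, q @ M, v) == pytest.approx(
            stability_index(B, M, v), abs=1e-12)


class TestOrientationAngles:
    def test_horizontal_aperture_is_zero(self):
        # B above M, aperture facing +x
        assert apertural_orientation((1, 0, 0), (0, 0, 1), (0, 0, 0)) \
            == pytest.approx(0.0, abs=1e-9)

    def test_upward_aperture_is_plus_ninety(self):
        assert apertural_orientation((0, 0, 1), (0, 0, 1), (0, 0, 0)) \
            == pytest.approx(90.0, abs=1e-9)

    def test_equilibration_invariance_under_prerotation(self):
        rng = np.random.default_rng(11)
        B = np.array([0.2, -0.1, 0.7])
        M = np.array([0.0, 0.05, -0.3])
        a = np.array([1.0, 0.4, -0.2])
        a /= np.linalg.norm(a)
        base = apertural_orientation(a, B, M)
        for _ in range(10):
            q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
            if np.linalg.det(q) < 0:
                q[:, 0] *= -1
            assert apertural_orientation(q @ a, q @ B, q @ M) \
                == pytest.approx(base, abs=1e-6)

    def test_coincident_centers_rejected(self):
        with pytest.raises(ValueError):
            apertural_orientation((1, 0, 0), (0, 0, 0), (0, 0, 0))

    def test_thrust_angle_zero_at_same_height(self):
        # hyponome level with the midpoint of B and M
        B, M = np.array([0, 0, 1.0]), np.array([0, 0, -1.0])
        hyp = np.array([3.0, 0, 0.0])  # midpoint at origin, same z
        assert thrust_angle(hyp, B, M) == pytest.approx(0.0, abs=1e-9)

    def test_thrust_angle_45_magnitude(self):
        B, M = np.array([0, 0, 1.0]), np.array([0, 0, -1.0])
        hyp = np.array([1.0, 0, 1.0])
        assert abs(thrust_angle(hyp, B, M)) == pytest.approx(45.0, abs=1e-9)

    def test_thrust_sign_convention_downward_positive(self):
        # hyponome directly above the midpoint: jet reaction drives the
        # animal downward -> +90
        B, M = np.array([0, 0, 1.0]), np.array([0, 0, -1.0])
        hyp = np.array([0.0, 0, 2.0])
        assert thrust_angle(hyp, B, M) == pytest.approx(90.0, abs=1e-9)

    def test_hyponome_at_midpoint_rejected(self):
        B, M = np.array([0, 0, 1.0]), np.array([0, 0, -1.0])
        with pytest.raises(ValueError):
            thrust_angle(np.zeros(3), B, M)


class TestScaling:
    def test_sphere_to_one_kilogram(self, coarse_model, densities):
        scaled, factor = scale_to_displaced_mass(coarse_model, 1000.0,
                                                 densities)
        from ectoswim.mesh import signed_volume

        v = signed_volume(scaled.water_displaced)
        assert v * densities.water_displaced == pytest.approx(1000.0,
                                                              rel=1e-9)

    def test_doubled_target_scales_by_cbrt2(self, coarse_model, densities):
        _, f1 = scale_to_displaced_mass(coarse_model, 500.0, densities)
        _, f2 = scale_to_displaced_mass(coarse_model, 1000.0, densities)
        assert f2 / f1 == pytest.approx(2.0 ** (1 / 3), rel=1e-12)

    def test_stability_index_unchanged(self, coarse_model, densities):
        res0 = compute_hydrostatics(model_from_conch(coarse_model, densities),
                                    densities)
        scaled, _ = scale_to_displaced_mass(coarse_model, 2500.0, densities)
        res1 = compute_hydrostatics(model_from_conch(scaled, densities),
                                    densities)
        assert res1.St == pytest.approx(res0.St, abs=1e-12)


class TestFullModel:
    def test_neutral_buoyancy_conservation(self, coarse_model, densities):
        res = compute_hydrostatics(model_from_conch(coarse_model, densities),
                                   densities)
        assert abs(res.total_mass - res.displaced_mass) / res.displaced_mass \
            < 1e-9

    def test_result_serialises(self, coarse_model, densities):
        import json

        res = compute_hydrostatics(model_from_conch(coarse_model, densities),
                                   densities)
        d = json.loads(res.to_json())
        assert "phi_gas_fraction" in d and "liquid_fraction" in d


class TestBodyChamberFit:
    def test_target_achieved_within_tolerance(self, coarse_spec, densities):
        angle, achieved = fit_body_chamber(coarse_spec, 0.12, tol=0.005,
                                           densities=densities)
        assert abs(achieved - 0.12) <= 0.005

    def test_liquid_fraction_monotone_in_angle(self, coarse_spec, densities):
        from ectoswim.hydro import _mesh_liquid_fraction

        angles = [200.0, 300.0, 420.0]
        fracs = [_mesh_liquid_fraction(coarse_spec, a, densities)
                 for a in angles]
        assert fracs[0] > fracs[1] > fracs[2]

    def test_idempotence(self, coarse_spec, densities):
        angle, achieved = fit_body_chamber(coarse_spec, 0.12, tol=0.005,
                                           densities=densities)
        spec2 = dataclasses.replace(coarse_spec, body_chamber_angle=angle)
        angle2, achieved2 = fit_body_chamber(spec2, achieved, tol=0.005,
                                             densities=densities)
        assert angle2 == pytest.approx(angle, abs=5.0)

    def test_unattainable_target_raises_with_bracket(self, coarse_spec,
                                                     densities):
        with pytest.raises(ValueError, match="bracket"):
            fit_body_chamber(coarse_spec, 5.0, densities=densities)


class TestDensityTable:
    def test_defaults_are_physical(self, densities):
        assert densities.cameral_gas < densities.cameral_liquid

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            DensityTable(shell=-1.0)
        with pytest.raises(ValueError):
            DensityTable(cameral_gas=2.0)
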