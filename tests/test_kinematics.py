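"""Velocity identities, acceleration fits, rocking, yaw unwrapping, and the
Welch/Games-Howell statistics."""

import math

import numpy as np
import pytest

from ectoswim.kinematics import (
    fit_acceleration,
    games_howell,
    rocking_angle,
    summarize_trial,
    velocity_series,
    welch_anova,
    welch_anova_games_howell,
    yaw_series,
)
from ectoswim.simulate import (
    MORPHOTYPE_BODIES,
    BodyParams,
    JetProfile,
    TrackedTrial,
    simulate_linear_trial,
    simulate_yaw_trial,
)


def _trial_from_midpoints(times, mids, motor=None):
    mids = np.asarray(mids, dtype=float)
    off = np.array([0.05, 0.0, 0.0])
    motor = np.zeros(len(times), bool) if motor is None else motor
    return TrackedTrial(times, mids + off, mids - off, motor)


class TestVelocitySeries:
    def test_3_4_5_horizontal(self):
        tr = _trial_from_midpoints([0.0, 1.0],
                                   [[0, 0, 0], [0.03, 0.04, 0.0]])
        for mode in ("2d", "3d"):
            _, v = velocity_series(tr, mode)
            assert v[0] == pytest.approx(0.05, abs=1e-12)

    def test_5_12_13_with_vertical(self):
        tr = _trial_from_midpoints([0.0, 1.0],
                                   [[0, 0, 0], [0.03, 0.04, 0.12]])
        _, v3 = velocity_series(tr, "3d")
        _, v2 = velocity_series(tr, "2d")
        assert v3[0] == pytest.approx(0.13, abs=1e-12)
        assert v2[0] == pytest.approx(0.05, abs=1e-12)

    def test_pure_vertical_motion_has_zero_2d_speed(self):
        tr = _trial_from_midpoints([0, 1, 2],
                                   [[0, 0, 0], [0, 0, 0.1], [0, 0, 0.3]])
        _, v2 = velocity_series(tr, "2d")
        assert np.all(v2 == 0.0)

    def test_v2d_never_exceeds_v3d(self):
        tr = simulate_linear_trial(MORPHOTYPE_BODIES["center"], JetProfile(),
                                   noise_sd=0.003, seed=3, duration=6.0)
        _, v2 = velocity_series(tr, "2d")
        _, v3 = velocity_series(tr, "3d")
        assert np.all(v2 <= v3 + 1e-15)

    def test_non_monotone_timestamps_rejected(self):
        tr = _trial_from_midpoints([0.0, 1.0, 0.5],
                                   [[0, 0, 0]] * 3)
        with pytest.raises(ValueError, match="increasing"):
            velocity_series(tr)


class TestAccelerationFit:
    def test_exact_linear_ramp(self):
        t = np.arange(0, 2.0, 1 / 24)
        # midpoint positions for v = 0.15 t -> x = 0.075 t^2
        mids = np.column_stack([0.075 * t ** 2, 0 * t, 0 * t])
        motor = t < 1.0
        tr = _trial_from_midpoints(t, mids, motor)
        fit = fit_acceleration(tr)
        assert fit.slope_mps2 == pytest.approx(0.15, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_constant_velocity_zero_slope(self):
        t = np.arange(0, 2.0, 1 / 24)
        mids = np.column_stack([0.2 * t, 0 * t, 0 * t])
        tr = _trial_from_midpoints(t, mids, t < 1.0)
        fit = fit_acceleration(tr)
        assert fit.slope_mps2 == pytest.approx(0.0, abs=1e-9)

    def test_low_drag_morph_accelerates_faster(self):
        jet = JetProfile()
        fits = {}
        for morph in ("oxycone", "sphaerocone"):
            tr = simulate_linear_trial(MORPHOTYPE_BODIES[morph], jet,
                                       duration=3.0)
            fits[morph] = fit_acceleration(tr).slope_cms2
        assert fits["oxycone"] > fits["sphaerocone"]

    def test_initial_acceleration_matches_thrust_over_mass(self):
        body = BodyParams(mass_g=1000.0, added_mass_coefficient=0.3,
                          drag_coefficient=0.2)
        jet = JetProfile(rise_tau=0.0, decay_tau=0.0)
        tr = simulate_linear_trial(body, jet, duration=2.0)
        t, v = velocity_series(tr, "2d")
        # earliest interval: v/t_mid ~ T/(m+ma) within 2%
        a0 = v[0] / (0.5 * (tr.time[0] + tr.time[1]))
        assert a0 == pytest.approx(0.3 / body.effective_mass_kg, rel=0.02)

    def test_short_window_rejected(self):
        t = np.array([0.0, 0.05, 0.1])
        tr = _trial_from_midpoints(t, np.zeros((3, 3)), t < 0.04)
        with pytest.raises(ValueError, match="3 frames"):
            fit_acceleration(tr)


class TestRocking:
    def test_posterior_above_anterior_zero_case(self):
        # p2 directly above p1, static angle 0 -> deviation 0
        tr = TrackedTrial([0.0], [[0, 0, 0]], [[0, 0, 1.0]], [False])
        assert rocking_angle(tr, theta_tp=0.0)[0] == pytest.approx(0.0)

    def test_horizontal_axis_with_90_static_angle(self):
        tr = TrackedTrial([0.0], [[0, 0, 0]], [[1.0, 0, 0]], [False])
        assert rocking_angle(tr, theta_tp=90.0)[0] == pytest.approx(0.0)

    def test_recovers_simulated_rocking_amplitude(self):
        # tracking axis tilted 45 deg from vertical in the pitch plane, as
        # on the physical robots; pitch rocking of +-5 deg then shows up as
        # a two-sided +-5 deg oscillation about the static angle
        a = 5.0 / math.sqrt(2.0)
        body = BodyParams(rocking_amplitude_deg=5.0,
                          rocking_frequency_hz=0.8,
                          tracking_point_offsets_cm=((-a, 0, -a), (a, 0, a)))
        tr = simulate_linear_trial(body, JetProfile(), duration=6.0)
        theta = rocking_angle(tr, theta_tp=45.0)
        amplitude = 0.5 * (theta.max() - theta.min())
        assert amplitude == pytest.approx(5.0, rel=0.05)
        assert abs(theta.max() + theta.min()) < 0.5  # centred on zero

    def test_coincident_points_rejected(self):
        tr = TrackedTrial([0.0], [[0, 0, 0]], [[0, 0, 0]], [False])
        with pytest.raises(ValueError, match="coincident"):
            rocking_angle(tr)


class TestYawSeries:
    @staticmethod
    def _rotating_trial(total_deg, n=200, duration=5.0):
        t = np.linspace(0.0, duration, n)
        psi = np.radians(total_deg) * t / duration
        r = 0.07
        p1 = np.column_stack([r * np.cos(psi), r * np.sin(psi), 0 * t])
        p2 = -p1
        return TrackedTrial(t, p1, p2, np.zeros(n, bool))

    def test_quarter_turn_counterclockwise(self):
        y = yaw_series(self._rotating_trial(90.0))
        assert y.net_angle_deg[-1] == pytest.approx(90.0, abs=1e-9)

    def test_multi_revolution_unwrap(self):
        y = yaw_series(self._rotating_trial(1170.0))
        assert y.net_angle_deg[-1] == pytest.approx(1170.0, abs=1e-6)
        assert y.revolutions == pytest.approx(3.25, abs=1e-9)

    def test_static_body_zero_series(self):
        t = np.linspace(0, 2, 40)
        p1 = np.tile([0.07, 0.0, 0.0], (40, 1))
        tr = TrackedTrial(t, p1, -p1, np.zeros(40, bool))
        y = yaw_series(tr)
        assert np.all(y.net_angle_deg == 0.0)
        assert np.all(y.omega_deg_s == 0.0)

    def test_frame_reversal_negates_net_angle(self):
        tr = self._rotating_trial(517.0)
        rev = TrackedTrial(tr.time, tr.p1[::-1], tr.p2[::-1], tr.motor_on)
        a = yaw_series(tr).net_angle_deg[-1]
        b = yaw_series(rev).net_angle_deg[-1]
        assert b == pytest.approx(-a, abs=1e-9)

    def test_vertically_stacked_points_rejected(self):
        tr = TrackedTrial([0.0], [[0, 0, 0.1]], [[0, 0, -0.1]], [False])
        with pytest.raises(ValueError, match="bearing"):
            yaw_series(tr)


class TestTrialSummary:
    def test_constant_velocity_peak(self):
        t = np.arange(0, 3.0, 1 / 24)
        mids = np.column_stack([0.21 * t, 0 * t, 0 * t])
        tr = _trial_from_midpoints(t, mids)
        s = summarize_trial(tr)
        assert s.peak_velocity_mps == pytest.approx(0.21, rel=1e-9)

    def test_zero_motion_zero_coasting(self):
        t = np.arange(0, 3.0, 1 / 24)
        tr = _trial_from_midpoints(t, np.zeros((len(t), 3)), t < 1.0)
        s = summarize_trial(tr)
        assert s.coasting_distance_m == 0.0
        assert s.duration_s == pytest.approx(0.0, abs=0.1)

    def test_low_drag_group_coasts_farther(self):
        jet = JetProfile()
        dist = {}
        for morph in ("oxycone", "sphaerocone"):
            body = MORPHOTYPE_BODIES[morph]
            ds = []
            for seed in range(15):
                tr = simulate_linear_trial(body, jet, noise_sd=0.001,
                                           seed=seed, duration=8.0)
                ds.append(summarize_trial(tr).coasting_distance_m)
            dist[morph] = np.array(ds)
        assert dist["oxycone"].min() > dist["sphaerocone"].max()


class TestWelchGamesHowell:
    def test_matches_pingouin_on_fixed_data(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(12)
        groups = {
            "a": rng.normal(0.0, 1.0, 12),
            "b": rng.normal(0.8, 2.0, 17),
            "c": rng.normal(-0.3, 0.5, 9),
        }
        mine = welch_anova_games_howell(groups)
        df = pd.DataFrame(
            [(g, v) for g, vals in groups.items() for v in vals],
            columns=["g", "y"])
        ref_anova = pg.welch_anova(data=df, dv="y", between="g")
        assert mine["anova"]["F"] == pytest.approx(
            float(ref_anova["F"].iloc[0]), rel=1e-9)
        assert mine["anova"]["p"] == pytest.approx(
            float(ref_anova["p_unc"].iloc[0]), rel=1e-6)
        ref_gh = pg.pairwise_gameshowell(data=df, dv="y", between="g")
        for row in mine["pairwise"]:
            match = ref_gh[(ref_gh.A == row["a"]) & (ref_gh.B == row["b"])]
            if match.empty:
                match = ref_gh[(ref_gh.A == row["b"]) & (ref_gh.B == row["a"])]
            assert abs(row["t"]) == pytest.approx(
                abs(float(match["T"].iloc[0])), rel=1e-9)
            assert row["p"] == pytest.approx(
                float(match["pval"].iloc[0]), rel=1e-6, abs=1e-12)

    def test_power_sanity_large_shift(self):
        rng = np.random.default_rng(5)
        groups = {"a": rng.normal(0, 1, 15), "b": rng.normal(10, 1, 15)}
        res = welch_anova_games_howell(groups)
        assert res["anova"]["p"] < 1e-3
        assert res["pairwise"][0]["p"] < 1e-3

    def test_pairwise_symmetry(self):
        rng = np.random.default_rng(6)
        groups = {"a": rng.normal(0, 1, 10), "b": rng.normal(1, 2, 12)}
        swapped = {"b": groups["b"], "a": groups["a"]}
        p1 = games_howell(groups)[0]["p"]
        p2 = games_howell(swapped)[0]["p"]
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            welch_anova({"a": [1.0, 1.0, 1.0], "b": [2.0, 2.0, 2.0]})

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            welch_anova({"a": [1.0, 2.0]})
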