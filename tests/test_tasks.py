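"""Task library: placement, mappings, physics, and classifier behaviour."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import goaltasks as gt
from goaltasks.core import GrossMiss, InputError
from goaltasks.tasks import (
    FIRE_THRESHOLD,
    MISFIRE_THRESHOLD,
    BAEnvironment,
    ba_bow_angle,
    ba_execution_mapping,
    ba_flight,
    ba_release_classifier,
    calibrate_ba_bullseye,
    pb_axis,
    pb_error,
    pb_error_decomposition,
    pb_execution_mapping,
    pb_peak_amplitude,
    pb_required_omega,
    pb_swing_time_course,
    pb_zero_error_velocity,
    place_objects,
    rs_error,
    rs_execution_mapping,
    rs_zero_error_velocity,
)

from .oracles import rk4_plane_hit, rotation_angle_between_axes


class TestPlacement:
    def test_ba_bow_position_from_star_limits(self):
        anthro = gt.Anthropometrics(height=1.75, upper_limb_length=0.7)
        limits = gt.WorkspaceLimits(
            chest_limit={d: 0.20 for d in ("R", "FR", "F", "FL", "L")},
            hand_limit={d: 0.80 for d in ("R", "FR", "F", "FL", "L")},
            neutral_hmd_height=1.6,
        )
        env = place_objects(limits, anthro, "BA", "far")
        assert env.bow_center[2] == pytest.approx(-0.63)  # 90 % limb forward
        assert env.bow_center[0] == pytest.approx(0.19)  # 95 % lateral limit
        rs = place_objects(limits, anthro, "RS", "near")
        assert rs.ball_center[2] == pytest.approx(-0.40)  # 50 % fwd reach

    @pytest.mark.parametrize("cond,frac", [("near", 0.65), ("mid", 0.80),
                                           ("far", 0.95)])
    def test_condition_fractions(self, subject, cond, frac):
        anthro, limits = subject
        env = place_objects(limits, anthro, "PB", cond)
        lat = limits.lateral_hand(anthro.handedness, "non-dominant")
        assert env.bag_center[0] == pytest.approx(-frac * lat)

    def test_unknown_condition_rejected(self, subject):
        anthro, limits = subject
        with pytest.raises(InputError):
            place_objects(limits, anthro, "BA", "extreme")


class TestBowAngle:
    @pytest.mark.parametrize(
        "x_chest_frac,expected_deg", [(1.0, 15.0), (0.0, 0.0), (0.5, 7.5)]
    )
    def test_linear_mapping(self, x_chest_frac, expected_deg):
        theta = ba_bow_angle(x_chest_frac * 0.25, 0.25)
        assert math.degrees(theta) == pytest.approx(expected_deg)

    def test_clamping_beyond_baseline(self):
        assert ba_bow_angle(0.30, 0.25) == pytest.approx(math.radians(15.0))
        assert ba_bow_angle(0.30, 0.25, clamp=False) == pytest.approx(
            math.radians(18.0)
        )

    def test_degenerate_baseline_rejected(self):
        with pytest.raises(InputError):
            ba_bow_angle(0.1, 0.0)


class TestBAExecution:
    def test_zero_pull_zero_velocity(self, ba_env):
        state = ba_execution_mapping(np.array([0.8, 0.0]), ba_env)
        assert np.allclose(state.velocity, 0.0)

    def test_speed_and_direction(self, ba_env):
        # full lean: 15 deg yaw; speed = k * pull
        state = ba_execution_mapping(np.array([1.0, 0.65]), ba_env)
        speed = np.linalg.norm(state.velocity)
        assert speed == pytest.approx(ba_env.k * 0.65)
        assert state.velocity[0] == pytest.approx(
            speed * math.sin(math.radians(15.0))
        )
        assert state.velocity[2] == pytest.approx(
            -speed * math.cos(math.radians(15.0))
        )

    def test_hand_evaluated_speed(self):
        # k = 20 /s per unit draw, pull 0.65 -> 13 m/s at 15 degrees
        anthro, limits = gt.default_subject()
        env = place_objects(limits, anthro, "BA", "near", k=20.0)
        state = ba_execution_mapping(np.array([1.0, 0.65]), env)
        assert np.linalg.norm(state.velocity) == pytest.approx(13.0)


class TestBAFlight:
    def test_optimal_angle_flight_time(self, ba_env):
        state = ba_execution_mapping(
            np.array([ba_env.theta_bow_opt / ba_env.theta_bow_max, 0.5]),
            ba_env,
        )
        sol = ba_flight(state, ba_env)
        assert sol.tflight == pytest.approx(
            ba_env.d_target / np.linalg.norm(state.velocity)
        )

    def test_perfect_shot_zero_error(self, ba_gf):
        opt_chest = ba_gf.env.theta_bow_opt / ba_gf.env.theta_bow_max
        assert ba_gf.error([opt_chest, 0.65]) <= 1e-9

    def test_zero_speed_is_gross_miss(self, ba_env):
        state = ba_execution_mapping(np.array([0.5, 0.0]), ba_env)
        with pytest.raises(GrossMiss):
            ba_flight(state, ba_env)

    def test_flight_matches_rk4_oracle(self, ba_env, rng):
        for _ in range(20):
            u = rng.uniform([0.1, 0.2], [1.1, 1.4])
            state = ba_execution_mapping(u, ba_env)
            sol = ba_flight(state, ba_env)
            hit, _ = rk4_plane_hit(
                state.position, state.velocity,
                ba_env.bullseye, ba_env.aim_direction,
            )
            rel = hit - ba_env.bullseye
            lateral = float(rel @ ba_env.lateral_axis)
            np.testing.assert_allclose(
                sol.hit, [lateral, rel[1]], atol=1e-6
            )


class TestReleaseClassifier:
    def test_offhand_drift_misfires(self):
        n = 50
        off_hand = np.linspace(0, 0.09, n)  # drifts past 0.08
        off_plane = np.zeros(n)
        outcome, idx = ba_release_classifier(off_hand, off_plane)
        assert outcome == "misfired"
        assert off_hand[idx] > MISFIRE_THRESHOLD

    def test_low_offplane_holds(self):
        n = 50
        outcome, _ = ba_release_classifier(np.zeros(n),
                                           np.linspace(0, 0.10, n))
        assert outcome == "held"

    def test_ramp_fires_at_first_crossing(self):
        ramp = np.linspace(0.0, 0.2, 101)
        outcome, idx = ba_release_classifier(np.zeros(101), ramp)
        assert outcome == "fired"
        assert ramp[idx] > FIRE_THRESHOLD and ramp[idx - 1] <= FIRE_THRESHOLD

    def test_bisection_recovers_fire_threshold(self):
        def fired(peak):
            out, _ = ba_release_classifier(
                np.zeros(64), np.linspace(0.0, peak, 64)
            )
            return out == "fired"

        lo, hi = 0.0, 0.5
        while hi - lo > 1e-7:
            mid = 0.5 * (lo + hi)
            lo, hi = (lo, mid) if fired(mid) else (mid, hi)
        assert 0.5 * (lo + hi) == pytest.approx(FIRE_THRESHOLD, abs=1e-6)

    def test_empty_trajectory_rejected(self):
        with pytest.raises(InputError):
            ba_release_classifier([], [])


class TestRS:
    def test_execution_mapping_linear(self, rs_env):
        from dataclasses import replace

        env2 = replace(rs_env, k=2.0)
        state = rs_execution_mapping(np.array([0.0, 1.0, -3.0]), env2)
        np.testing.assert_allclose(state.velocity, [0.0, 2.0, -6.0])

    def test_ballistic_solve_hits_bullseye(self, rs_gf):
        u = rs_zero_error_velocity(rs_gf.env, vz=-6.0)
        assert rs_gf.error(u) <= 1e-9

    def test_zero_forward_velocity_gross_miss(self, rs_gf):
        assert np.isinf(rs_gf.error([1.0, 2.0, 0.0]))
        assert np.isinf(rs_gf.error([0.0, 0.0, 0.0]))

    def test_error_matches_rk4_oracle(self, rs_env, rng):
        gf = gt.RSGoalFunction(rs_env)
        for _ in range(20):
            u = rng.uniform([-1.5, 0.0, -10.0], [1.5, 6.0, -1.5])
            state = rs_execution_mapping(u, rs_env)
            sol = rs_error(state, rs_env)
            hit, _ = rk4_plane_hit(
                state.position, state.velocity,
                rs_env.bullseye, np.array([0.0, 0.0, -1.0]),
            )
            rel = hit - rs_env.bullseye
            np.testing.assert_allclose(sol.hit, [rel[0], rel[1]], atol=1e-6)
            assert gf.error(u) == pytest.approx(np.linalg.norm(sol.hit))


class TestPendulum:
    def test_execution_mapping_quadrants(self, pb_env):
        d = float(pb_env.bag_center[1])
        s = pb_execution_mapping(np.array([2.0, 0.0, d]), pb_env)
        assert s.phi == pytest.approx(0.0)
        s = pb_execution_mapping(np.array([0.0, 2.0, d]), pb_env)
        assert math.degrees(s.phi) == pytest.approx(90.0)

    def test_omega_product(self, pb_env):
        from dataclasses import replace

        # k = 0.5 /m, |v| = 4 m/s, d = 3.0 m -> omega = 6 rad/s
        env = replace(pb_env, bag_center=np.array([0.0, 3.1, 0.0]))
        env = replace(env, k=0.5)
        s = pb_execution_mapping(np.array([4.0, 0.0, 3.0]), env)
        assert s.omega == pytest.approx(6.0)

    def test_hit_outside_bag_rejected(self, pb_env):
        with pytest.raises(InputError):
            pb_execution_mapping(
                np.array([1.0, 1.0, pb_env.bag_top + 0.1]), pb_env
            )

    def test_peak_amplitude_energy_balance(self, rng):
        L, g = 1.118, 9.81
        for omega in rng.uniform(0.1, 5.0, size=25):
            theta = pb_peak_amplitude(omega, L, g)
            # both sides of the mass-free energy balance:
            # (1/2) L^2 w^2  =  g L (1 - cos theta_max)
            kinetic = 0.5 * L**2 * omega**2
            potential = g * L * (1.0 - math.cos(theta))
            assert abs(kinetic - potential) / max(kinetic, 1e-12) < 1e-12

    def test_small_angle_limit(self):
        L, g = 1.118, 9.81
        omega = 0.05
        theta = pb_peak_amplitude(omega, L, g)
        approx = omega * math.sqrt(L / g)
        assert theta < 0.1
        assert abs(theta - approx) / approx < 0.01

    def test_over_energy_gross_miss(self):
        with pytest.raises(GrossMiss):
            pb_peak_amplitude(20.0, 1.118, 9.81)

    def test_swing_period_closed_form(self, pb_env):
        L, g = pb_env.hang_length, pb_env.gravity
        wn = pb_env.natural_frequency
        period = 2 * math.pi * math.sqrt(L / g)
        t = np.array([0.3, 0.3 + period])
        th = pb_swing_time_course(0.4, wn, 0.0, t)
        assert abs(th[0] - th[1]) < 1e-9
        # peak value attained at the cosine peak
        t_peak = (math.pi / 2) / wn  # phase -pi/2 peaks here
        assert pb_swing_time_course(0.4, wn, 0.0, np.array([t_peak]))[0] == (
            pytest.approx(0.4)
        )
        assert np.allclose(pb_swing_time_course(0.0, wn, 0.0, t), 0.0)


class TestPBError:
    def test_zero_when_matching(self):
        assert pb_error((0.5, 0.3), (0.5, 0.3)) == pytest.approx(0.0)

    def test_coaxial_amplitudes_subtract(self):
        e = pb_error((0.5, 0.3), (0.2, 0.3))
        assert e == pytest.approx(math.degrees(0.3))

    @given(
        theta=st.floats(0.05, 1.2),
        phi1=st.floats(-math.pi, math.pi),
        dphi=st.floats(-1.5, 1.5),
    )
    def test_matches_quaternion_oracle(self, theta, phi1, dphi):
        e = pb_error((theta, phi1), (theta, phi1 + dphi))
        oracle = rotation_angle_between_axes(
            pb_axis(theta, phi1), pb_axis(theta, phi1 + dphi)
        )
        assert abs(e - oracle) < 1e-9

    def test_decomposition_pure_cases(self):
        direction, height = pb_error_decomposition((0.6, 0.5), (0.4, 0.5))
        assert direction == pytest.approx(0.0, abs=1e-12)
        assert height == pytest.approx(math.degrees(0.2))
        direction, height = pb_error_decomposition((0.4, 0.8), (0.4, 0.5))
        assert height == pytest.approx(0.0, abs=1e-12)
        assert direction != 0.0

    def test_decomposition_mixed_case_against_oracle(self, rng):
        for _ in range(25):
            obs = (rng.uniform(0.1, 0.9), rng.uniform(-1.0, 1.0))
            des = (rng.uniform(0.1, 0.9), rng.uniform(-1.0, 1.0))
            direction, height = pb_error_decomposition(obs, des)
            dir_oracle = rotation_angle_between_axes(
                pb_axis(des[0], obs[1]), pb_axis(des[0], des[1])
            )
            assert abs(abs(direction) - dir_oracle) < 1e-6
            assert height == pytest.approx(
                abs(math.degrees(obs[0] - des[0]))
            )

    def test_decomposition_recombines_for_small_angles(self):
        des = (0.5, math.radians(30.0))
        obs = (0.52, math.radians(33.0))
        direction, height = pb_error_decomposition(obs, des)
        total = pb_error(obs, des)
        assert math.hypot(direction, height) == pytest.approx(total, rel=0.02)

    def test_lateral_sign_convention(self):
        # observed azimuth below desired = rotated toward the lateral axis
        direction, _ = pb_error_decomposition(
            (0.5, math.radians(20.0)), (0.5, math.radians(30.0))
        )
        assert direction > 0


class TestContinuity:
    def test_error_continuous_in_u(self, ba_gf, rs_gf, pb_gf, rng):
        """Finite-difference continuity on random non-gross-miss points."""
        cases = (
            (ba_gf, [0.2, 0.3], [1.0, 1.3]),
            (rs_gf, [-1.0, 0.5, -9.0], [1.0, 5.0, -2.0]),
            (pb_gf, [-3.0, -3.0, pb_gf.env.bag_bottom + 0.05],
             [3.0, 3.0, pb_gf.env.bag_top - 0.05]),
        )
        for gf, lo, hi in cases:
            for _ in range(10):
                u = rng.uniform(lo, hi)
                e0 = gf.error(u)
                if not np.isfinite(e0):
                    continue
                step = 1e-7
                for j in range(gf.arity):
                    du = np.zeros(gf.arity)
                    du[j] = step
                    assert abs(gf.error(u + du) - e0) < 1e-3
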