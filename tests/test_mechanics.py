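"""Plant-level oracles: geometry, Hill-muscle dynamics, joint kinematics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spinarm import mechanics as mech


@pytest.fixture
def biceps():
    return mech.biceps_params()


@pytest.fixture
def triceps():
    return mech.triceps_params()


class TestGeometry:
    @pytest.mark.parametrize(
        "angle, expected",
        [(0.0, 0.34), (120.0, 0.25), (60.0, 0.295)],
    )
    def test_biceps_length_of_angle(self, biceps, angle, expected):
        assert mech.muscle_length_of_angle(angle, biceps) == pytest.approx(expected)

    @pytest.mark.parametrize("angle, expected", [(0.0, 0.275), (120.0, 0.345)])
    def test_triceps_length_of_angle(self, triceps, angle, expected):
        assert mech.muscle_length_of_angle(angle, triceps) == pytest.approx(expected)

    @pytest.mark.parametrize("angle", [-1.0, 120.5, 300.0])
    def test_angle_domain_error(self, biceps, angle):
        with pytest.raises(ValueError):
            mech.muscle_length_of_angle(angle, biceps)

    def test_moment_arm_is_constant_slope(self, biceps, triceps):
        # flexor shortens with flexion, extensor lengthens
        assert biceps.length_slope == pytest.approx(-0.09 / 120)
        assert triceps.length_slope == pytest.approx(0.07 / 120)
        assert biceps.is_flexor and not triceps.is_flexor

    def test_forearm_inertia_positive_and_matches_rod_plus_point_mass(self):
        f, h = mech.FOREARM, mech.HAND
        expected = f.mass * f.length**2 / 3 + h.mass * (f.length + h.length / 2) ** 2
        got = mech.forearm_inertia()
        assert got > 0
        assert got == pytest.approx(expected, rel=1e-12)


class TestStimulusTension:
    def test_zero_at_rest_potential(self, biceps, triceps):
        assert mech.stimulus_tension(-60.0, biceps) == 0.0
        assert mech.stimulus_tension(-60.0, triceps) == 0.0

    def test_saturation(self, biceps):
        assert mech.stimulus_tension(1e3, biceps) == pytest.approx(395.5)

    def test_sigmoid_midpoint(self, biceps):
        assert mech.stimulus_tension(-20.0, biceps) == pytest.approx(195.5)

    @given(v=st.floats(-120, 40))
    @settings(max_examples=50, deadline=None)
    def test_nonnegative_and_monotone(self, v):
        p = mech.biceps_params()
        lo = mech.stimulus_tension(v, p)
        hi = mech.stimulus_tension(v + 1.0, p)
        assert 0.0 <= lo <= hi


class TestLengthTension:
    def test_peak_at_resting_length(self, biceps):
        assert mech.length_tension(biceps.lt_resting_length, biceps) == 1.0

    def test_zero_at_width_edge_and_beyond(self, biceps):
        edge = biceps.lt_resting_length + biceps.lt_width_Lwidth
        assert mech.length_tension(edge, biceps) == pytest.approx(0.0, abs=1e-12)
        assert mech.length_tension(edge + 0.5, biceps) == 0.0

    def test_tabulated_tension_percent_ranges(self, biceps, triceps):
        # flexor spans ~7-90% over its operating range, extensor ~90-99%
        assert mech.length_tension(0.34, biceps) == pytest.approx(0.897, abs=2e-3)
        assert mech.length_tension(0.25, biceps) == pytest.approx(0.070, abs=2e-3)
        assert mech.length_tension(0.275, triceps) == pytest.approx(0.901, abs=2e-3)
        assert mech.length_tension(0.345, triceps) == pytest.approx(0.987, abs=2e-3)


class TestHillDynamics:
    def test_rest_equilibrium_tension_stays_zero(self, biceps):
        state = mech.MuscleState(length=biceps.natural_length)
        for _ in range(1000):
            state = mech.hill_step(state, biceps.natural_length, 1e-3, biceps)
        assert state.tension == 0.0

    @pytest.mark.parametrize("v_drive, length", [(-20.0, 0.36), (-30.0, 0.35),
                                                 (-15.0, 0.34)])
    def test_isometric_steady_state_matches_closed_form(self, biceps, v_drive,
                                                        length):
        state = mech.MuscleState(length=length, membrane_potential=v_drive)
        for _ in range(5000):
            state = mech.hill_step(state, length, 1e-3, biceps)
        a = mech.activation(v_drive, length, biceps)
        expected = mech.isometric_steady_tension(length, a, biceps)
        assert state.tension == pytest.approx(expected, rel=1e-3)

    def test_passive_ramp_stretch_matches_analytic_solution(self, biceps):
        # stretch beyond slack at constant velocity; linear first-order ODE
        # dT/dt = a0 + a1*t - c*T has the closed-form solution below
        p = biceps
        l0, v = p.natural_length + 0.005, 0.02
        dt, n = 1e-3, 400
        state = mech.MuscleState(length=l0)
        state = mech.hill_step(state, l0, dt, p)  # sets length_rate history
        kse, kpe, b = p.serial_stiffness_Kse, p.parallel_stiffness_Kpe, p.damping_B
        c = (kse / b) * (1 + kpe / kse)
        a0 = (kse / b) * (kpe * (l0 - p.natural_length) + b * v)
        a1 = (kse / b) * kpe * v
        t0_tension = state.tension

        for i in range(n):
            state = mech.hill_step(state, l0 + v * (i + 1) * dt, dt, p)
        t_end = n * dt
        part = (a0 / c - a1 / c**2) + (a1 / c) * t_end
        part0 = a0 / c - a1 / c**2
        expected = part + (t0_tension - part0) * math.exp(-c * t_end)
        assert state.tension == pytest.approx(expected, rel=1e-3)

    @given(
        length=st.floats(0.25, 0.40),
        v=st.floats(-80.0, 0.0),
        ldot=st.floats(-0.2, 0.2),
    )
    @settings(max_examples=100, deadline=None)
    def test_tension_never_negative(self, length, v, ldot):
        p = mech.biceps_params()
        state = mech.MuscleState(length=length, membrane_potential=v)
        for _ in range(50):
            state = mech.hill_step(state, state.length + ldot * 1e-3, 1e-3, p)
            assert state.tension >= 0.0


class TestJointStep:
    def test_no_tension_no_motion(self):
        j = mech.JointState(angle=40.0)
        j2 = mech.joint_step(j, 0.0, 0.0, 1e-3)
        assert j2.angle == pytest.approx(40.0)
        assert j2.angular_velocity == 0.0

    def test_torque_balance_is_stationary(self):
        f, e = mech.biceps_params(), mech.triceps_params()
        t_flex = 50.0
        t_ext = t_flex * f.moment_arm / e.moment_arm
        j = mech.JointState(angle=60.0)
        j2 = mech.joint_step(j, t_flex, t_ext, 1e-3, f, e)
        assert j2.angle == pytest.approx(60.0, abs=1e-9)

    def test_constant_flexor_torque_matches_undamped_kinematics(self):
        f, e = mech.biceps_params(), mech.triceps_params()
        j = mech.JointState(angle=0.0)
        t_flex, dt, n = 40.0, 1e-4, 5000
        angles = [j.angle]
        for _ in range(n):
            j = mech.joint_step(j, t_flex, 0.0, dt, f, e, joint_damping=0.0)
            angles.append(j.angle)
        # strictly increasing until the 120 deg stop
        a = np.array(angles)
        rising = a < 120.0
        assert np.all(np.diff(a[rising]) > 0)
        # analytic: theta = 0.5 * (r*T/I) * t^2 until the stop
        alpha = f.moment_arm * t_flex / j.inertia / mech.DEG2RAD
        t_end = n * dt
        expected = min(120.0, 0.5 * alpha * t_end**2)
        assert a[-1] == pytest.approx(expected, rel=2e-3)

    def test_hard_stop_clips_and_zeroes_velocity(self):
        j = mech.JointState(angle=119.9, angular_velocity=500.0)
        j2 = mech.joint_step(j, 200.0, 0.0, 1e-2)
        assert j2.angle == 120.0
        assert j2.angular_velocity == 0.0


@given(angle=st.floats(0.0, 120.0))
@settings(max_examples=8, deadline=None)
def test_zero_activation_plant_is_stationary_everywhere(angle):
    """Passive plant parked at any posture stays put for 10 simulated s."""
    f, e = mech.biceps_params(), mech.triceps_params()
    j = mech.JointState(angle=angle)
    sf = mech.MuscleState(length=mech.muscle_length_of_angle(angle, f))
    se = mech.MuscleState(length=mech.muscle_length_of_angle(angle, e))
    dt = 1e-3
    for _ in range(10000):
        lf = mech.muscle_length_of_angle(j.angle, f)
        le = mech.muscle_length_of_angle(j.angle, e)
        sf = mech.hill_step(sf, lf, dt, f)
        se = mech.hill_step(se, le, dt, e)
        j = mech.joint_step(j, sf.tension, se.tension, dt, f, e)
    assert abs(j.angle - angle) < 1e-6
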