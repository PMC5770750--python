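"""Plant dynamics: inertia, Coriolis, muscle torques, integration, kinematics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reachopt import (
    ArmParams,
    PlantState,
    compute_inertia,
    coriolis,
    forward_kinematics,
    inverse_kinematics,
    muscle_torque,
    step,
)
from reachopt.arm import kinetic_energy


class TestInertia:
    def test_elbow_straight(self, params):
        M = compute_inertia(0.0, params)
        np.testing.assert_allclose(
            M, [[0.2746, 0.0978], [0.0978, 0.045]], atol=1e-12
        )

    def test_elbow_right_angle(self, params):
        M = compute_inertia(np.pi / 2, params)
        np.testing.assert_allclose(M, [[0.169, 0.045], [0.045, 0.045]], atol=1e-12)

    @given(q2=st.floats(-0.2, 3.0))
    @settings(deadline=None)
    def test_symmetric_positive_definite(self, q2):
        M = compute_inertia(q2, ArmParams())
        np.testing.assert_allclose(M, M.T)
        assert np.all(np.linalg.eigvalsh(M) > 0)


class TestMuscleTorque:
    def test_single_shoulder_flexor(self, params):
        tau, _ = muscle_torque(np.eye(6)[0], None, params)
        np.testing.assert_allclose(tau, [28.0, 0.0], atol=1e-12)

    def test_all_muscles_on(self, params):
        tau, _ = muscle_torque(np.ones(6), None, params)
        np.testing.assert_allclose(tau, [6.042, -3.503], atol=1e-12)

    def test_zero_command_immune_to_noise(self, params, rng):
        tau, u_noisy = muscle_torque(np.zeros(6), rng.standard_normal(6), params)
        np.testing.assert_array_equal(tau, 0.0)
        np.testing.assert_array_equal(u_noisy, 0.0)

    def test_rejects_out_of_box(self, params):
        with pytest.raises(ValueError):
            muscle_torque(np.full(6, 1.2), None, params)
        with pytest.raises(ValueError):
            muscle_torque(np.full(6, -0.1), None, params)

    def test_noisy_activation_stays_in_box(self, params, rng):
        for _ in range(200):
            _, u_noisy = muscle_torque(
                rng.uniform(0, 1, 6), 5 * rng.standard_normal(6), params
            )
            assert np.all(u_noisy >= 0) and np.all(u_noisy <= 1)

    def test_noise_unbiased_before_clamping(self, params, rng):
        # at u = 0.5 and kappa = 0.3 clamping is a ~1e-3 tail event, so the
        # mean of the noisy activation matches the command within 3 SE
        u = np.full(6, 0.5)
        n = 100_000
        draws = rng.standard_normal((n, 6))
        samples = np.clip(u * (1 + params.kappa * draws), 0, 1)
        se = samples.std() / np.sqrt(n)
        assert np.all(np.abs(samples.mean(axis=0) - 0.5) < 3 * se * np.sqrt(6))


class TestStep:
    def test_rest_is_equilibrium(self, params):
        state = PlantState([1.0, 1.5], [0.0, 0.0])
        new, _ = step(state, np.zeros(6), params, rng=None)
        np.testing.assert_array_equal(new.q, state.q)
        np.testing.assert_array_equal(new.q_dot, state.q_dot)

    def test_coriolis_value(self, params):
        c = coriolis(np.array([0.0, np.pi / 2]), np.array([1.0, 0.0]), params)
        np.testing.assert_allclose(c, [0.0, 0.0528], atol=1e-12)

    def test_energy_conserved_without_damping(self):
        # passive frictionless plant: Coriolis forces do no work, so kinetic
        # energy is conserved up to the integrator's O(dt) error
        p = ArmParams(B=np.zeros((2, 2)), dt=1e-5)
        state = PlantState([1.0, 1.5], [1.0, -0.5])
        e0 = kinetic_energy(state, p)
        for _ in range(10_000):  # 0.1 s
            state, _ = step(state, np.zeros(6), p, rng=None)
        assert abs(kinetic_energy(state, p) - e0) / e0 < 1e-4

    def test_damping_dissipates_energy(self, params):
        state = PlantState([1.0, 1.5], [2.0, -1.0])
        energies = [kinetic_energy(state, params)]
        for _ in range(200):
            state, _ = step(state, np.zeros(6), params, rng=None)
            energies.append(kinetic_energy(state, params))
        assert np.all(np.diff(energies) <= 1e-12)

    def test_deterministic_without_noise(self, params):
        u = np.full(6, 0.3)
        s1 = PlantState([1.0, 1.0], [0.0, 0.0])
        s2 = PlantState([1.0, 1.0], [0.0, 0.0])
        for _ in range(50):
            s1, _ = step(s1, u, params, rng=None)
            s2, _ = step(s2, u, params, rng=None)
        np.testing.assert_array_equal(s1.as_vector(), s2.as_vector())

    def test_joint_bounds_clamp_with_zeroed_velocity(self, params):
        state = PlantState([2.59, 1.0], [10.0, 0.0])
        state, _ = step(state, np.zeros(6), params, rng=None)
        assert state.q[0] == params.q_max[0]
        assert state.q_dot[0] == 0.0

    def test_non_finite_state_rejected(self, params):
        with pytest.raises(FloatingPointError):
            step(PlantState([np.nan, 1.0], [0.0, 0.0]), np.zeros(6), params)


class TestKinematics:
    def test_fully_extended(self, params):
        p, _ = forward_kinematics([np.pi / 2, 0.0], params)
        np.testing.assert_allclose(p, [0.0, 0.65], atol=1e-12)

    def test_right_angle_elbow(self, params):
        p, _ = forward_kinematics([0.0, np.pi / 2], params)
        np.testing.assert_allclose(p, [0.3, 0.35], atol=1e-12)

    def test_jacobian_maps_zero_velocity_to_zero(self, params, rng):
        _, jac = forward_kinematics(rng.uniform(-1, 2, 2), params)
        np.testing.assert_array_equal(jac @ np.zeros(2), 0.0)

    def test_jacobian_matches_finite_differences(self, params):
        q = np.array([0.7, 1.1])
        _, jac = forward_kinematics(q, params)
        eps = 1e-7
        for j in range(2):
            dq = np.zeros(2)
            dq[j] = eps
            num = (forward_kinematics(q + dq, params)[0]
                   - forward_kinematics(q - dq, params)[0]) / (2 * eps)
            np.testing.assert_allclose(jac[:, j], num, atol=1e-6)

    def test_ik_boundary_of_reach(self, params):
        q = inverse_kinematics([0.0, 0.65], params)
        np.testing.assert_allclose(q, [np.pi / 2, 0.0], atol=1e-6)

    def test_ik_wall_center(self, params):
        q = inverse_kinematics([0.0, 0.6175], params)
        assert q[1] == pytest.approx(0.6357, abs=2e-3)

    def test_round_trip_on_random_reachable_points(self, params, rng):
        for _ in range(100):
            r = rng.uniform(abs(params.l1 - params.l2) + 1e-6, params.arm_length - 1e-6)
            th = rng.uniform(0, 2 * np.pi)
            p = r * np.array([np.cos(th), np.sin(th)])
            q = inverse_kinematics(p, params)
            assert q[1] >= 0  # elbow-positive branch
            p_back, _ = forward_kinematics(q, params)
            np.testing.assert_allclose(p_back, p, atol=1e-9)

    def test_unreachable_point_names_radius(self, params):
        with pytest.raises(ValueError, match="radius"):
            inverse_kinematics([0.0, 0.9], params)


class TestParamValidation:
    def test_rejects_nonpositive_mass(self):
        with pytest.raises(ValueError, match="m1"):
            ArmParams(m1=0.0)

    def test_rejects_asymmetric_damping(self):
        with pytest.raises(ValueError, match="B"):
            ArmParams(B=np.array([[0.05, 0.01], [0.02, 0.05]]))

    def test_rejects_nonpositive_dt(self):
        with pytest.raises(ValueError, match="dt"):
            ArmParams(dt=0.0)
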