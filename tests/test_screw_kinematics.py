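"""Screw (helical axis) extraction tests against independent oracles."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from screwkin.core import PoseSeries, rotation_about_axis, unit
from screwkin.screw import (
    axis_angle,
    cumulative_rotation_vectors,
    estimate_mean_axis,
    five_point_derivative,
    incremental_rotation,
    incremental_rotations,
    iha_point,
    mean_axis_from_arrays,
    mean_flexion_axis,
    rodrigues_params,
    rotation_from_axis_angle,
    screw_series,
    translation_along_axis,
)
from screwkin.synthetic import make_screw_motion

from conftest import pitch_screw_truth, point_line_distance, quat_oracle, random_rotation


class TestRodriguesParams:
    def test_identity(self):
        assert np.allclose(rodrigues_params(np.eye(3)), (1.0, 0.0, 0.0, 0.0))

    def test_quarter_turn_about_z(self):
        R = rotation_about_axis([0.0, 0.0, 1.0], np.pi / 2)
        S, L, M, N = rodrigues_params(R)
        assert np.isclose(S, np.sqrt(2) / 2)
        assert np.isclose(L, 0.0, atol=1e-15)
        assert np.isclose(M, 0.0, atol=1e-15)
        assert np.isclose(N, np.sqrt(2) / 2)

    def test_matches_quaternion_oracle_up_to_sign(self, rng):
        for _ in range(300):
            R = random_rotation(rng)
            q = np.array(rodrigues_params(R))
            q_o = quat_oracle(R)
            assert min(np.abs(q - q_o).max(), np.abs(q + q_o).max()) < 1e-10

    def test_near_pi_branch_round_trips(self, rng):
        """Rotations within 1e-6 of a half turn still extract and rebuild."""
        for _ in range(20):
            axis = unit(rng.normal(size=3))
            R = rotation_about_axis(axis, np.pi - 1e-7)
            S, L, M, N = rodrigues_params(R)
            assert np.isclose(S**2 + L**2 + M**2 + N**2, 1.0, atol=1e-9)
            phi, n, ok = axis_angle(S, L, M, N)
            assert ok
            assert np.abs(rotation_from_axis_angle(phi, n) - R).max() < 1e-7


class TestAxisAngle:
    def test_zero_rotation_flags_undefined_axis(self):
        phi, n, ok = axis_angle(1.0, 0.0, 0.0, 0.0)
        assert phi == 0.0 and not ok and np.all(np.isnan(n))

    def test_half_quarter_turn(self):
        phi, n, ok = axis_angle(np.sqrt(2) / 2, 0.0, 0.0, np.sqrt(2) / 2)
        assert ok
        assert np.isclose(phi, np.pi / 2)
        assert np.allclose(n, [0.0, 0.0, 1.0])

    def test_rebuild_round_trip(self, rng):
        """Extraction followed by the rotation formula reproduces the input."""
        for _ in range(300):
            R = random_rotation(rng)
            phi, n, ok = axis_angle(*rodrigues_params(R))
            assert ok
            assert np.abs(rotation_from_axis_angle(phi, n) - R).max() < 1e-9

    def test_rejects_non_unit_quaternion(self):
        with pytest.raises(ValueError, match="unit"):
            axis_angle(1.0, 1.0, 0.0, 0.0)


class TestFivePointDerivative:
    def test_constant_and_linear_are_exact(self):
        t = 0.01 * np.arange(20)
        d, valid = five_point_derivative(np.full_like(t, 3.0), 0.01)
        assert np.abs(d[valid]).max() == 0.0
        c = 2.7
        d, valid = five_point_derivative(c * t, 0.01)
        assert np.abs(d[valid] - c).max() < 1e-12

    def test_exact_for_quartic(self):
        """The stencil differentiates degree-4 polynomials exactly."""
        t = 0.01 * np.arange(50)
        poly = np.polynomial.Polynomial([0.3, -1.2, 0.7, 2.0, -0.5])
        d, valid = five_point_derivative(poly(t), 0.01)
        expected = poly.deriv()(t)
        rel = np.abs(d[valid] - expected[valid]) / np.abs(expected[valid]).max()
        assert rel.max() < 1e-10

    def test_boundary_frames_invalid(self):
        d, valid = five_point_derivative(np.arange(10.0), 1.0)
        assert not valid[:2].any() and not valid[-2:].any()
        assert np.isnan(d[:2]).all() and np.isnan(d[-2:]).all()

    def test_too_few_frames(self):
        with pytest.raises(ValueError, match=">= 5"):
            five_point_derivative(np.arange(4.0), 1.0)


class TestIncrementalRotation:
    def _poses(self, rotations):
        n = len(rotations)
        return PoseSeries(
            times=0.01 * np.arange(n),
            rotations=np.array(rotations),
            origins=np.zeros((n, 3)),
        )

    def test_constant_orientation_gives_identity(self):
        R = random_rotation(np.random.default_rng(0))
        poses = self._poses([R] * 6)
        assert np.abs(incremental_rotation(poses, 2) - np.eye(3)).max() < 1e-12

    def test_fixed_axis_increment(self):
        w, dt = 0.5, 0.01
        rots = [rotation_about_axis([0, 0, 1.0], w * dt * k) for k in range(10)]
        poses = self._poses(rots)
        expected = rotation_about_axis([0, 0, 1.0], w * dt)
        for i in range(9):
            assert np.abs(incremental_rotation(poses, i) - expected).max() < 1e-12

    def test_increments_telescope_to_total_rotation(self, rng):
        """Composing all increments reproduces the final orientation."""
        rots = [np.eye(3)]
        for _ in range(30):
            rots.append(random_rotation(rng, (0.001, 0.05)) @ rots[-1])
        poses = self._poses(rots)
        inc = incremental_rotations(poses)
        prod = np.eye(3)
        for k in range(len(inc)):
            prod = inc[k] @ prod
        assert np.abs(prod @ poses.rotations[0] - poses.rotations[-1]).max() < 1e-9

    def test_index_out_of_range(self):
        poses = self._poses([np.eye(3)] * 3)
        with pytest.raises(IndexError):
            incremental_rotation(poses, 2)


class TestAngularVelocity:
    def test_fixed_axis_constant_rate(self):
        """Constant-rate rotation about z recovers omega = (0, 0, w)."""
        w, dt, n = 0.8, 0.01, 50
        poses = PoseSeries(
            times=dt * np.arange(n),
            rotations=rotation_about_axis([0, 0, 1.0], w * dt * np.arange(n)),
            origins=np.tile([5.0, 0.0, 0.0], (n, 1)),
        )
        s = screw_series(poses)
        interior = s.frame_valid
        assert np.abs(s.omega[interior] - [0.0, 0.0, w]).max() < 1e-9

    def test_zero_motion_gives_zero(self):
        n = 10
        poses = PoseSeries(
            times=0.01 * np.arange(n),
            rotations=np.tile(np.eye(3), (n, 1, 1)),
            origins=np.zeros((n, 3)),
        )
        s = screw_series(poses)
        assert np.abs(s.omega[2:-2]).max() < 1e-12

    def test_slowly_varying_axis_matches_matrix_log_oracle(self):
        """omega agrees with the skew(Rdot R^T) finite-difference oracle."""
        dt, n = 0.01, 200
        t = dt * np.arange(n)
        rv = np.column_stack(
            [0.3 * np.sin(0.2 * t), 0.1 * t, 0.5 * np.sin(0.15 * t + 0.3)]
        )
        rots = Rotation.from_rotvec(rv).as_matrix()
        poses = PoseSeries(times=t, rotations=rots, origins=np.zeros((n, 3)))
        s = screw_series(poses)
        Rdot = (rots[2:] - rots[:-2]) / (2 * dt)
        W = np.einsum("nij,nkj->nik", Rdot, rots[1:-1])
        omega_oracle = np.column_stack([W[:, 2, 1], W[:, 0, 2], W[:, 1, 0]])
        interior = slice(2, n - 2)
        err = np.abs(s.omega[interior] - omega_oracle[1:-1]).max()
        assert err < 5e-4  # both estimates are O(dt^2) of the true rate

    def test_scalar_mode_matches_rotvec_on_fixed_axis(self):
        truth = pitch_screw_truth(duration=2.0)
        poses = make_screw_motion(truth)
        s_vec = screw_series(poses)
        s_sca = screw_series(poses, angular_rate_mode="scalar")
        both = s_vec.frame_valid & s_sca.frame_valid
        assert np.abs(s_vec.omega[both] - s_sca.omega[both]).max() < 1e-9


class TestIhaPoint:
    def test_circular_motion_about_origin(self):
        A = iha_point([1.0, 0.0, 0.0], [0.0, 0.0, 1.0], [0.0, 1.0, 0.0])
        assert np.allclose(A, 0.0, atol=1e-15)

    def test_zero_angular_velocity_rejected(self):
        with pytest.raises(ValueError, match="omega_min"):
            iha_point([1.0, 0.0, 0.0], [0.0, 0.0, 0.0], [0.0, 1.0, 0.0])

    def test_noiseless_screw_points_lie_on_planted_axis(self):
        truth = pitch_screw_truth()
        poses = make_screw_motion(truth)
        s = screw_series(poses)
        dist = point_line_distance(
            s.A[s.frame_valid], truth.axis_point, truth.axis_direction
        )
        assert dist.max() < 1e-6


class TestTranslationAlongAxis:
    def test_no_displacement(self):
        assert translation_along_axis([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [0, 0, 1.0]) == 0.0

    def test_axial_displacement(self):
        d = translation_along_axis([0.0, 0.0, 0.0], [0.0, 0.0, 0.1], [0.0, 0.0, 1.0])
        assert np.isclose(d, 0.1)

    def test_undefined_axis_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            translation_along_axis([0.0] * 3, [1.0] * 3, [np.nan] * 3)

    def test_pitch_screw_translation_sums_to_closed_form(self):
        """Summed per-step translations equal pitch x total rotation."""
        truth = pitch_screw_truth(total_translation=0.457)
        poses = make_screw_motion(truth)
        s = screw_series(poses)
        assert abs(s.total_translation() - 0.457) < 1e-6


class TestMeanFlexionAxis:
    def test_identical_axes_recovered(self):
        axes = np.tile(unit([0.2, -0.1, 0.97]), (50, 1))
        m = mean_axis_from_arrays(axes, np.zeros((0, 3)))
        assert np.abs(m.n_m - axes[0]).max() < 1e-12

    def test_hemisphere_alignment_ignores_sign_flips(self, rng):
        axes = np.tile(unit([0.2, -0.1, 0.97]), (50, 1))
        jitter = rng.normal(scale=0.01, size=axes.shape)
        noisy = np.array([unit(a + j) for a, j in zip(axes, jitter)])
        flips = np.where(rng.random(50) < 0.5, -1.0, 1.0)
        m1 = mean_axis_from_arrays(noisy, np.zeros((0, 3)))
        m2 = mean_axis_from_arrays(flips[:, None] * noisy, np.zeros((0, 3)))
        assert min(np.abs(m1.n_m - m2.n_m).max(), np.abs(m1.n_m + m2.n_m).max()) < 1e-12

    def test_symmetric_cone_averages_to_cone_axis(self, rng):
        """Axes on a 5-degree cone with uniform azimuth average to the axis."""
        n = 10_000
        half = np.radians(5.0)
        az = rng.uniform(0, 2 * np.pi, n)
        axes = np.column_stack(
            [np.sin(half) * np.cos(az), np.sin(half) * np.sin(az), np.full(n, np.cos(half))]
        )
        m = mean_axis_from_arrays(axes, np.zeros((0, 3)))
        err = np.degrees(np.arccos(np.clip(abs(m.n_m @ [0, 0, 1.0]), 0, 1)))
        assert err < 0.2

    def test_telescoping_and_hemisphere_agree_on_clean_screw(self):
        truth = pitch_screw_truth(duration=4.0)
        s = screw_series(make_screw_motion(truth))
        m_t = mean_flexion_axis(s, method="telescoping")
        m_h = mean_flexion_axis(s, method="hemisphere")
        assert np.abs(m_t.n_m - m_h.n_m).max() < 1e-9
        assert np.abs(m_t.n_m - truth.axis_direction).max() < 1e-9
        assert point_line_distance(m_t.A_m, truth.axis_point, truth.axis_direction) < 1e-6

    def test_no_valid_steps_error(self):
        n = 10
        poses = PoseSeries(
            times=0.01 * np.arange(n),
            rotations=np.tile(np.eye(3), (n, 1, 1)),
            origins=np.zeros((n, 3)),
        )
        s = screw_series(poses)
        with pytest.raises(ValueError, match="valid"):
            mean_flexion_axis(s)


def test_cumulative_rotation_vectors_match_scipy(rng):
    """Unwrapped cumulative rotation vectors agree with scipy's rotvec."""
    n = 100
    t = 0.01 * np.arange(n)
    rots = rotation_about_axis(unit([0.3, 0.2, 0.9]), 2.0 * t)
    poses = PoseSeries(times=t, rotations=rots, origins=np.zeros((n, 3)))
    rho = cumulative_rotation_vectors(poses)
    expected = Rotation.from_matrix(
        np.einsum("nij,kj->nik", rots, rots[0])
    ).as_rotvec()
    assert np.abs(rho - expected).max() < 1e-9


def test_estimate_mean_axis_noiseless_matches_truth():
    truth = pitch_screw_truth(duration=4.0)
    poses = make_screw_motion(truth)
    m = estimate_mean_axis(poses)
    assert np.abs(m.n_m - truth.axis_direction).max() < 1e-9
    assert point_line_distance(m.A_m, truth.axis_point, truth.axis_direction) < 1e-6
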