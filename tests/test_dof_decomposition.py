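"""Joint-frame displacement decomposition and curve aggregation."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from screwkin.core import PoseSeries, rotation_about_axis, unit
from screwkin.dof import (
    DOF_NAMES,
    DofSamples,
    aggregate_curves,
    compose_tait_bryan,
    decompose_series,
    decompose_tait_bryan,
    flexion_angle_series,
    pose_in_joint_frame,
    significance_screen,
    t_critical,
)
from screwkin.frames import AnatomicalFrame
from screwkin.synthetic import make_scenario, make_screw_motion

from conftest import pitch_screw_truth, random_rotation


def _frame(origin=(0.0, 0.0, 0.0)) -> AnatomicalFrame:
    return AnatomicalFrame(
        U_X=np.array([1.0, 0, 0]),
        U_Y=np.array([0.0, 1.0, 0]),
        U_Z=np.array([0.0, 0, 1.0]),
        origin=np.asarray(origin, float),
    )


class TestPoseInJointFrame:
    def test_reference_pose_gives_identity_displacement(self, rng):
        R_ref = random_rotation(rng)
        O_ref = rng.normal(size=3)
        D, t = pose_in_joint_frame(R_ref, O_ref, _frame([5.0, 1.0, 2.0]), R_ref, O_ref)
        assert np.abs(D - np.eye(3)).max() < 1e-12
        assert np.abs(t).max() < 1e-12

    def test_rotation_about_frame_axis_is_pure_flexion(self):
        """Rotation about U_Z through O_beta gives pure R_Z, zero translation."""
        frame = _frame([3.0, -1.0, 2.0])
        R_ref, O_ref = np.eye(3), np.array([10.0, 0.0, 0.0])
        Rd = rotation_about_axis([0.0, 0, 1.0], np.radians(30.0))
        R = Rd @ R_ref
        O = Rd @ (O_ref - frame.origin) + frame.origin
        D, t = pose_in_joint_frame(R, O, frame, R_ref, O_ref)
        comps, gimbal = decompose_tait_bryan(D, t)
        assert not gimbal
        assert np.isclose(comps[0], 30.0, atol=1e-10)  # R_Z
        assert np.abs(comps[1:]).max() < 1e-10

    def test_round_trip_through_inverse_change_of_basis(self, rng):
        Q = random_rotation(rng)
        frame = AnatomicalFrame(
            U_X=Q[:, 0], U_Y=Q[:, 1], U_Z=Q[:, 2], origin=rng.normal(size=3)
        )
        R_ref, O_ref = random_rotation(rng), rng.normal(size=3)
        R, O = random_rotation(rng), rng.normal(size=3)
        D, t = pose_in_joint_frame(R, O, frame, R_ref, O_ref)
        # invert: Rd = Q D Q^T, then recover (R, O)
        Rd = Q @ D @ Q.T
        R_back = Rd @ R_ref
        O_back = frame.origin + Q @ t - Rd @ (frame.origin - O_ref)
        assert np.abs(R_back - R).max() < 1e-12
        assert np.abs(O_back - O).max() < 1e-12


class TestDecomposeTaitBryan:
    def test_identity_gives_all_zero(self):
        comps, gimbal = decompose_tait_bryan(np.eye(3), np.zeros(3))
        assert np.abs(comps).max() == 0.0 and not gimbal

    def test_pure_flexion(self):
        comps, _ = decompose_tait_bryan(compose_tait_bryan(30.0, 0.0, 0.0), np.zeros(3))
        assert np.allclose(comps, [30.0, 0, 0, 0, 0, 0], atol=1e-12)

    def test_forward_compose_recovers_all_six(self):
        """The published peak medial-lateral translation composes and recovers."""
        D = compose_tait_bryan(40.0, 0.02, 0.01)
        t = np.array([0.1, -0.2, 0.457])
        comps, _ = decompose_tait_bryan(D, t)
        assert np.abs(comps - [40.0, 0.02, 0.01, 0.1, -0.2, 0.457]).max() < 1e-9

    def test_matches_scipy_euler_oracle(self, rng):
        for _ in range(200):
            R = random_rotation(rng, (0.01, 1.4))
            comps, _ = decompose_tait_bryan(R, np.zeros(3))
            zyx = Rotation.from_matrix(R).as_euler("ZYX", degrees=True)
            assert np.abs(comps[:3] - zyx).max() < 1e-9

    def test_gimbal_proximity_flagged(self):
        D = compose_tait_bryan(10.0, 89.95, 5.0)
        _, gimbal = decompose_tait_bryan(D, np.zeros(3))
        assert gimbal


class TestFlexionAngle:
    def test_reference_pose_reads_zero(self):
        truth = pitch_screw_truth(duration=1.0)
        poses = make_screw_motion(truth)
        frame = AnatomicalFrame(
            U_X=truth.frame_rotation[:, 0],
            U_Y=truth.frame_rotation[:, 1],
            U_Z=truth.frame_rotation[:, 2],
            origin=truth.frame_origin,
        )
        R_ref, O_ref = truth.reference_pose
        ang = flexion_angle_series(poses, frame, np.array([1.0, -176.0, 0.0]), R_ref, O_ref)
        assert abs(ang[0]) < 1e-9

    def test_planted_profile_recovered(self):
        """Instantaneous flexion matches the generator profile, noiseless."""
        truth = pitch_screw_truth(duration=2.0)
        poses = make_screw_motion(truth)
        frame = AnatomicalFrame(
            U_X=truth.frame_rotation[:, 0],
            U_Y=truth.frame_rotation[:, 1],
            U_Z=truth.frame_rotation[:, 2],
            origin=truth.frame_origin,
        )
        R_ref, O_ref = truth.reference_pose
        ang = flexion_angle_series(poses, frame, np.array([1.0, -176.0, 0.0]), R_ref, O_ref)
        expected = truth.angle_profile(poses.times)
        assert np.abs(ang - expected).max() < 1e-6

    def test_degenerate_projection_rejected(self):
        truth = pitch_screw_truth(duration=1.0)
        poses = make_screw_motion(truth)
        frame = AnatomicalFrame(
            U_X=truth.frame_rotation[:, 0],
            U_Y=truth.frame_rotation[:, 1],
            U_Z=truth.frame_rotation[:, 2],
            origin=truth.frame_origin,
        )
        R_ref, O_ref = truth.reference_pose
        on_axis = truth.frame_origin + 3.0 * truth.axis_direction
        with pytest.raises(ValueError, match="undefined"):
            flexion_angle_series(poses, frame, on_axis, R_ref, O_ref)


class TestTCritical:
    def test_published_value_24_df(self):
        assert round(t_critical(24, 0.05), 3) == 2.064

    def test_normal_limit(self):
        assert abs(t_critical(10**6, 0.05) - 1.960) < 1e-3

    def test_small_sample(self):
        assert round(t_critical(4, 0.05), 3) == 2.776

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            t_critical(0, 0.05)
        with pytest.raises(ValueError):
            t_critical(10, 1.5)


def _samples_from_curve(flexion, values: dict, trial_id="t"):
    df = pd.DataFrame({dof: values.get(dof, np.zeros_like(flexion)) for dof in DOF_NAMES})
    df.insert(0, "flexion_deg", flexion)
    df.insert(0, "time", np.arange(flexion.size, dtype=float))
    return DofSamples(trial_id=trial_id, data=df, gimbal_flags=np.zeros(flexion.size, bool))


class TestAggregateCurves:
    def test_identical_trials_have_zero_half_width(self):
        flex = np.linspace(0, 90, 200)
        tz = 0.005 * flex
        trials = [_samples_from_curve(flex, {"T_Z": tz}, f"t{k}") for k in range(25)]
        curves = aggregate_curves(trials, np.arange(0.0, 91.0))
        assert np.nanmax(curves.half_widths["T_Z"]) < 1e-12
        assert np.abs(curves.means["T_Z"] - 0.005 * curves.flexion_grid).max() < 1e-12
        assert round(curves.t_critical, 3) == 2.064

    def test_permutation_invariance(self, rng):
        flex = np.linspace(0, 90, 100)
        trials = [
            _samples_from_curve(flex, {"T_Z": rng.normal(size=flex.size)}, f"t{k}")
            for k in range(8)
        ]
        grid = np.arange(5.0, 86.0)
        a = aggregate_curves(trials, grid)
        order = rng.permutation(len(trials))
        b = aggregate_curves([trials[i] for i in order], grid)
        # invariant up to float summation order
        assert np.allclose(a.means["T_Z"], b.means["T_Z"], atol=1e-12)
        assert np.allclose(a.half_widths["T_Z"], b.half_widths["T_Z"], atol=1e-12)

    def test_out_of_range_trials_excluded_with_count(self):
        flex_full = np.linspace(0, 90, 100)
        flex_short = np.linspace(0, 50, 60)
        trials = [
            _samples_from_curve(flex_full, {}, "a"),
            _samples_from_curve(flex_full, {}, "b"),
            _samples_from_curve(flex_short, {}, "c"),
        ]
        grid = np.arange(0.0, 91.0)
        curves = aggregate_curves(trials, grid)
        assert curves.excluded_points == int((grid > 50).sum())
        assert curves.n_used[grid <= 50].max() == 3
        assert curves.n_used[grid > 50].max() == 2

    def test_band_coverage_is_nominal(self, rng):
        """95% t-band covers the truth at ~95% of points (small simulation)."""
        grid = np.arange(0.0, 51.0)
        truth_curve = 0.01 * grid
        n_trials, n_rep = 25, 200
        hits = 0
        total = 0
        for _ in range(n_rep):
            trials = [
                _samples_from_curve(
                    grid, {"T_Z": truth_curve + rng.normal(0, 0.05, grid.size)}, f"t{k}"
                )
                for k in range(n_trials)
            ]
            curves = aggregate_curves(trials, grid)
            hits += int(
                (np.abs(curves.means["T_Z"] - truth_curve) <= curves.half_widths["T_Z"]).sum()
            )
            total += grid.size
        coverage = hits / total
        assert abs(coverage - 0.95) < 0.02

    def test_needs_at_least_two_trials(self):
        flex = np.linspace(0, 90, 10)
        with pytest.raises(ValueError, match=">= 2"):
            aggregate_curves([_samples_from_curve(flex, {})], np.arange(0.0, 91.0))


class TestSignificanceScreen:
    def _curves(self, means: dict, hw=0.001):
        flex = np.arange(0.0, 91.0)
        from screwkin.dof import DofCurves

        dofs = [d for d in DOF_NAMES if d != "R_Z"]
        return DofCurves(
            flexion_grid=flex,
            means={d: np.full(flex.size, means.get(d, 0.0)) for d in dofs},
            half_widths={d: np.full(flex.size, hw) for d in dofs},
            n_trials=25,
            n_used=np.full(flex.size, 25),
            t_critical=t_critical(24, 0.05),
            alpha=0.05,
        )

    def test_all_zero_curves_flag_nothing(self):
        sig = significance_screen(self._curves({}))
        assert not any(sig.values())

    def test_large_translation_flagged(self):
        sig = significance_screen(self._curves({"T_Z": 0.457}))
        assert sig == {"R_Y": False, "R_X": False, "T_X": False, "T_Y": False, "T_Z": True}

    def test_threshold_monotonicity(self):
        curves = self._curves({"T_Z": 0.457, "R_X": 0.5})
        sig = significance_screen(
            curves, translation_uncertainty_mm=10.0, rotation_uncertainty_deg=10.0
        )
        assert not any(sig.values())


def test_noiseless_fresh_profiles_recovered_through_decomposition():
    """On the noiseless fresh gesture the planted frame reproduces every DoF."""
    _, _, truth = make_scenario("fresh", 0, marker_noise_sigma=0.0, n_surface_points=60)
    poses = make_screw_motion(truth)
    frame = AnatomicalFrame(
        U_X=truth.frame_rotation[:, 0],
        U_Y=truth.frame_rotation[:, 1],
        U_Z=truth.frame_rotation[:, 2],
        origin=truth.frame_origin,
    )
    samples = decompose_series(
        poses, frame, np.array([1.0, -176.0, 0.0]),
        R_ref=truth.reference_pose[0], O_ref=truth.reference_pose[1],
    )
    d = samples.data
    planted = truth.planted_dof_profiles(d["flexion_deg"].to_numpy())
    assert np.abs(d["T_Z"].to_numpy() - planted["T_Z"]).max() < 1e-6
    for dof in ("T_X", "T_Y", "R_X", "R_Y"):
        assert np.abs(d[dof]).max() < 1e-6
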