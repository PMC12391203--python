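"""Forward kinematics, Jacobians, inverse kinematics, stance windows."""

import numpy as np
import pytest

import fullbody as fb
from fullbody.kinematics import (_axis_angle, fk_state, select_stance_window,
                                 solve_ik_frame, solve_ik_trajectory)


class TestForwardKinematics:
    def test_default_pose_reproduces_geometry(self, augmented, geometry):
        _, markers = fb.forward_kinematics(augmented, augmented.default_q())
        for i, m in enumerate(augmented.markers):
            expect = np.asarray(geometry.markers[m.name]["pos"], float)
            assert np.allclose(markers[i], expect, atol=1e-12), m.name

    def test_pelvis_translation_transports_all_markers(self, augmented):
        q = augmented.default_q()
        x0 = fb.marker_positions(augmented, q)
        d = np.array([0.3, -0.1, 0.25])
        for axis, name in enumerate(("pelvis_tx", "pelvis_ty", "pelvis_tz")):
            q[augmented.ind_index[name]] += d[axis]
        x1 = fb.marker_positions(augmented, q)
        assert np.allclose(x1 - x0, d, atol=1e-12)

    def test_pin_rotation_matches_hand_rotation_oracle(self, augmented,
                                                       geometry):
        """90 degrees of right knee flexion maps tibia markers by an explicit
        rotation matrix about the knee axis."""
        q = augmented.default_q()
        q[augmented.ind_index["knee_angle_r"]] = np.pi / 2
        x1 = fb.marker_positions(augmented, q)
        centre = geometry.jc("knee_r")
        R = _axis_angle(np.array([0.0, 0.0, 1.0]), np.pi / 2)
        names = augmented.marker_names
        for mname in ("RANK", "RTTUB", "RSHN"):  # markers on the tibia
            x0 = np.asarray(geometry.markers[mname]["pos"], float)
            expect = centre + R @ (x0 - centre)
            assert np.allclose(x1[names.index(mname)], expect, atol=1e-12)

    def test_pose_rotations_are_orthonormal(self, augmented, rng):
        q = augmented.default_q() + rng.uniform(-0.5, 0.5, 48)
        poses, _ = fb.forward_kinematics(augmented, q)
        for name, pose in poses.items():
            assert np.allclose(pose.R @ pose.R.T, np.eye(3), atol=1e-10), name
            assert np.linalg.det(pose.R) == pytest.approx(1.0, abs=1e-10)


class TestJacobian:
    def test_analytic_matches_finite_difference(self, augmented, rng):
        q = augmented.default_q() + rng.uniform(-0.4, 0.4, 48)
        Ja = fb.marker_jacobian(augmented, q, method="analytic")
        Jf = fb.marker_jacobian(augmented, q, method="fd")
        assert np.max(np.abs(Ja - Jf)) < 1e-6

    def test_pelvis_translation_columns_are_identity_blocks(self, augmented):
        J = fb.marker_jacobian(augmented, augmented.default_q())
        cols = [augmented.ind_index[n]
                for n in ("pelvis_tx", "pelvis_ty", "pelvis_tz")]
        block = J[:, cols].reshape(-1, 3, 3)
        assert np.allclose(block, np.eye(3), atol=1e-12)

    def test_subset_selects_rows(self, augmented):
        J = fb.marker_jacobian(augmented, augmented.default_q(),
                               marker_subset=["C7", "RD1M"])
        assert J.shape == (6, 48)


class TestInverseKinematics:
    def test_exact_recovery_from_noiseless_markers(self, augmented, rng):
        q_true = augmented.default_q() + rng.uniform(-0.3, 0.3, 48)
        x = fb.marker_positions(augmented, q_true)
        res = solve_ik_frame(augmented, x, q_init=augmented.default_q())
        assert res.converged
        assert np.max(np.abs(res.q - q_true)) < 1e-3
        assert res.objective < 1e-10

    def test_noisy_markers_give_noise_scale_errors(self, augmented, rng):
        """With isotropic sigma = 5 mm noise the converged per-marker RMS
        error sits at the noise scale (the fit absorbs a little of it)."""
        sigma = 5e-3
        errs = []
        for _ in range(8):
            q_true = augmented.default_q() + rng.uniform(-0.2, 0.2, 48)
            x = fb.marker_positions(augmented, q_true)
            noisy = x + rng.normal(0, sigma, x.shape)
            res = solve_ik_frame(augmented, noisy, q_init=q_true)
            errs.append(np.sqrt(np.nanmean(res.marker_sq_error)))
        mean_err = np.mean(errs)
        # 3D error for sigma per axis is sigma * sqrt(3) before absorption
        assert sigma < mean_err < np.sqrt(3) * sigma * 1.2

    def test_group_weighting_reduces_group_error(self, augmented, rng):
        """Weighting the torso group 10x never worsens its tracking on the
        same noisy data (the study's base-segment protocol)."""
        q_true = augmented.default_q() + rng.uniform(-0.25, 0.25, 48)
        x = fb.marker_positions(augmented, q_true)
        noisy = x + rng.normal(0, 4e-3, x.shape)
        torso_idx = [i for i, m in enumerate(augmented.markers)
                     if m.group == "torso"]
        uni = solve_ik_frame(augmented, noisy, q_init=q_true)
        wtd = solve_ik_frame(augmented, noisy, weights={"torso": 10.0},
                             q_init=q_true)
        assert (np.sum(wtd.marker_sq_error[torso_idx])
                <= np.sum(uni.marker_sq_error[torso_idx]) + 1e-15)

    def test_rank_deficiency_reported_with_few_markers(self, augmented):
        x = fb.marker_positions(augmented, augmented.default_q())
        mask = np.zeros(len(augmented.markers), bool)
        mask[:4] = True  # 12 constraints for 48 coordinates
        res = solve_ik_frame(augmented, x, mask=mask)
        assert res.rank_deficient

    def test_trajectory_constant_pose(self, augmented):
        q0 = augmented.default_q()
        truth = fb.CoordinateTrajectory(np.arange(10) / 100.0,
                                        augmented.independent_names,
                                        np.tile(q0, (10, 1)))
        markers = fb.synthesize_markers(augmented, truth)
        out = solve_ik_trajectory(augmented, markers)
        assert out.all_converged
        assert np.max(np.abs(out.trajectory.q - q0)) < 1e-6

    def test_trajectory_recovery_smooth_motion(self, augmented, vcut_trial):
        """Noiseless synthetic motion is recovered to well under half a
        degree on every coordinate."""
        out = solve_ik_trajectory(augmented, vcut_trial.markers)
        assert out.all_converged
        dev = np.abs(out.trajectory.q - vcut_trial.truth.q)
        assert dev.max() < np.radians(0.5)

    def test_occluded_marker_is_ignored(self, augmented):
        q0 = augmented.default_q()
        n = 8
        truth = fb.CoordinateTrajectory(np.arange(n) / 100.0,
                                        augmented.independent_names,
                                        np.tile(q0, (n, 1)))
        markers = fb.synthesize_markers(augmented, truth,
                                        dropout={"LBHD": (2, 5)})
        # corrupt the hidden samples; they must not influence the solution
        j = markers.index("LBHD")
        markers.positions[2:6, j] = 1e3
        out = solve_ik_trajectory(augmented, markers)
        assert np.max(np.abs(out.trajectory.q - q0)) < 1e-6
        assert np.all(np.isnan([r.marker_sq_error[
            augmented.marker_names.index("LBHD")] for r in out.frames[2:6]]))


class TestStanceWindow:
    def test_ten_percent_rule(self):
        times = np.arange(0, 2.0, 1 / 240.0)
        first, last = select_stance_window((1.0, 1.5), times)
        assert times[first] == pytest.approx(0.95, abs=1 / 240.0)
        assert times[last] <= 1.5 + 1e-12
        assert times[last] == pytest.approx(1.5, abs=1 / 240.0)

    def test_clipped_at_trial_start(self):
        times = np.arange(0, 1.0, 1 / 240.0)
        first, _ = select_stance_window((0.01, 0.5), times)
        assert first == 0

    def test_window_length(self):
        times = np.arange(0, 3.0, 1 / 240.0)
        first, last = select_stance_window((2.0, 2.4), times)
        assert times[last] - times[first] == pytest.approx(0.44, abs=2 / 240.0)

    def test_bad_events_rejected(self):
        times = np.arange(0, 1.0, 1 / 240.0)
        with pytest.raises(ValueError):
            select_stance_window((0.5, 0.4), times)
        with pytest.raises(ValueError):
            select_stance_window((5.0, 6.0), times)
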