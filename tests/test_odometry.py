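"""Dense RGB-D odometry: residual definitions, convergence, motion recovery."""

import numpy as np
import pytest

from herdrecon.camera import PinholeIntrinsics
from herdrecon.io import RGBDFrame
from herdrecon.odometry import (
    OdometryConfig,
    compute_rgbd_odometry,
    geometric_residuals,
    photometric_residuals,
    wide_baseline_init,
    _masked_objective,
    _residual_state,
)
from herdrecon.synthetic import look_at_pose, render_frame
from herdrecon.transforms import RigidTransform, rotation_angle, se3_exp

CFG = OdometryConfig(max_iterations=30, convergence_tol=1e-10)


def _pose_errors(T_est, T_true):
    rot = np.degrees(rotation_angle(T_est.rotation.T @ T_true.rotation))
    trans = np.linalg.norm(T_est.translation - T_true.translation)
    return rot, trans


class TestResiduals:
    def test_identical_frames_zero(self, side_frame, intrinsics_hi):
        rI = photometric_residuals(side_frame, side_frame, RigidTransform.identity(),
                                   intrinsics_hi)
        rD = geometric_residuals(side_frame, side_frame, RigidTransform.identity(),
                                 intrinsics_hi)
        assert len(rI) > 0 and np.allclose(rI, 0.0)
        assert np.allclose(rD, 0.0)

    def test_constant_intensity_zero_photometric(self, intrinsics_hi):
        K = intrinsics_hi
        depth = np.full((K.height, K.width), 2.0)
        f = RGBDFrame(np.full((K.height, K.width), 0.5), depth)
        T = se3_exp([0, 0.01, 0, 0.01, 0, 0])
        rI = photometric_residuals(f, f, T, K)
        assert np.allclose(rI, 0.0, atol=1e-12)

    def test_axial_shift_zeroes_geometric(self, intrinsics_hi):
        """Frame j 1 cm closer along the optical axis; T encoding the shift
        reproduces frame i's depth (flat scene: interpolation is exact)."""
        K = intrinsics_hi
        shape = (K.height, K.width)
        f_i = RGBDFrame(np.full(shape, 0.5), np.full(shape, 2.0))
        f_j = RGBDFrame(np.full(shape, 0.5), np.full(shape, 1.99))
        T = se3_exp([0, 0, 0, 0, 0, 0.01])   # moves points from 1.99 to 2.0
        rD = geometric_residuals(f_i, f_j, T, K)
        assert len(rD) > 0 and np.allclose(rD, 0.0, atol=1e-9)

    def test_sigma_one_is_pure_depth_objective(self, side_frame, intrinsics_hi):
        cfg = OdometryConfig(sigma=1.0)
        T = se3_exp([0.001, 0, 0, 0.002, 0, 0])
        state = _residual_state(side_frame.gray, side_frame.depth, side_frame.gray,
                                side_frame.depth, intrinsics_hi, T, cfg)
        obj = _masked_objective(state, state["ok"], cfg)
        expected = float(np.mean(state["rD"][state["ok"]] ** 2))
        assert obj == pytest.approx(expected, rel=1e-12)

    def test_hand_warped_toy(self):
        """Constant-depth toy scene under a pure 1-px horizontal shift: the
        photometric residuals equal the hand-shifted intensity differences."""
        K = PinholeIntrinsics(width=8, height=8, fx=10.0, fy=10.0, cx=3.5, cy=3.5)
        rng = np.random.default_rng(0)
        gray_j = rng.random((8, 8))
        gray_i = np.roll(gray_j, 1, axis=1)    # frame i is frame j shifted right
        depth = np.full((8, 8), 1.0)
        # pixel shift of +1 at depth 1 with fx=10 -> translation x = 0.1
        T = se3_exp([0, 0, 0, 0.1, 0, 0])
        r = photometric_residuals(RGBDFrame(gray_i, depth), RGBDFrame(gray_j, depth), T, K)
        # hand evaluation: pixel (u, v) of j warps to (u+1, v) in i, where
        # gray_i(u+1, v) = gray_j(u, v) exactly -> every residual is zero
        assert len(r) > 0
        assert np.allclose(r, 0.0, atol=1e-12)


class TestConvergence:
    def test_self_alignment_identity(self, side_frame, intrinsics_hi):
        res = compute_rgbd_odometry(side_frame, side_frame, intrinsics_hi, cfg=CFG)
        assert res.success
        assert rotation_angle(res.transform.rotation) < 1e-12
        assert np.linalg.norm(res.transform.translation) < 1e-12
        assert res.final_objective < 1e-20

    def test_known_motion_recovered(self, animal, intrinsics_hi, side_pose, side_frame):
        """A 2-degree rotation with 2 cm translation is recovered to a small
        fraction of the motion (sub-0.2-degree, few-mm)."""
        mesh, albedo = animal
        xi = np.concatenate([[np.radians(2.0), 0, 0], [0.01, 0.01, 0.01]])
        pose_j = side_pose @ se3_exp(xi)
        g, d = render_frame(mesh, albedo, intrinsics_hi, pose_j)
        res = compute_rgbd_odometry(side_frame, RGBDFrame(g, d), intrinsics_hi, cfg=CFG)
        T_gt = side_pose.invert() @ pose_j
        rot, trans = _pose_errors(res.transform, T_gt)
        assert res.success
        assert rot < 0.2
        assert trans < 0.0035    # interpolation-bias floor, documented in methods

    def test_median_recovery_over_random_motions(self, animal, intrinsics_hi,
                                                 side_pose, side_frame):
        """Median errors over random small motions stay below 0.2 degrees and
        1% of the mean scene depth (2.5 m)."""
        mesh, albedo = animal
        rng = np.random.default_rng(11)
        errs = []
        for _ in range(20):
            ax = rng.normal(size=3)
            ax /= np.linalg.norm(ax)
            tv = rng.normal(size=3)
            tv /= np.linalg.norm(tv)
            xi = np.concatenate([ax * np.radians(2.0), tv * 0.02])
            pose_j = side_pose @ se3_exp(xi)
            g, d = render_frame(mesh, albedo, intrinsics_hi, pose_j)
            res = compute_rgbd_odometry(side_frame, RGBDFrame(g, d), intrinsics_hi, cfg=CFG)
            errs.append(_pose_errors(res.transform, side_pose.invert() @ pose_j))
        med = np.median(np.array(errs), axis=0)
        assert med[0] < 0.2
        assert med[1] < 0.01 * 2.5

    def test_forward_backward_symmetry(self, animal, intrinsics_hi, side_pose, side_frame):
        mesh, albedo = animal
        pose_j = side_pose @ se3_exp([0, np.radians(1.0), 0, 0.005, 0.005, 0.005])
        g, d = render_frame(mesh, albedo, intrinsics_hi, pose_j)
        f_j = RGBDFrame(g, d)
        fwd = compute_rgbd_odometry(side_frame, f_j, intrinsics_hi, cfg=CFG).transform
        bwd = compute_rgbd_odometry(f_j, side_frame, intrinsics_hi, cfg=CFG).transform.invert()
        rot, trans = _pose_errors(fwd, bwd)
        assert rot < 0.1
        assert trans < 0.002

    def test_non_overlapping_frames_fail_gracefully(self, side_frame, intrinsics_hi):
        K = intrinsics_hi
        empty = RGBDFrame(np.zeros(side_frame.shape), np.zeros(side_frame.shape))
        res = compute_rgbd_odometry(side_frame, empty, K, cfg=CFG)
        assert not res.success
        assert "overlap" in res.message

    def test_sigma_extremes_converge_on_self_alignment(self, side_frame, intrinsics_hi):
        for sigma in (0.0, 1.0):
            cfg = OdometryConfig(sigma=sigma, max_iterations=10)
            res = compute_rgbd_odometry(side_frame, side_frame, intrinsics_hi, cfg=cfg)
            assert res.success
            assert np.linalg.norm(res.transform.translation) < 1e-9


class TestWideBaseline:
    def test_recovers_rough_alignment(self, animal, intrinsics_hi, side_pose, side_frame):
        """Feature-based initialization lands within the dense tracker's basin
        for a motion far beyond the adjacent-frame scale."""
        mesh, albedo = animal
        xi = np.concatenate([[0, np.radians(8.0), 0], [0.05, 0.02, 0.03]])
        pose_j = side_pose @ se3_exp(xi)
        g, d = render_frame(mesh, albedo, intrinsics_hi, pose_j)
        f_j = RGBDFrame(g, d)
        init = wide_baseline_init(side_frame, f_j, intrinsics_hi, seed=0)
        assert init is not None
        T_gt = side_pose.invert() @ pose_j
        rot, trans = _pose_errors(init, T_gt)
        assert rot < 3.0 and trans < 0.08
        refined = compute_rgbd_odometry(side_frame, f_j, intrinsics_hi, init=init, cfg=CFG)
        rot2, trans2 = _pose_errors(refined.transform, T_gt)
        assert rot2 < 0.3 and trans2 < 0.01
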