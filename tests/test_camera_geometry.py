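"""Pinhole projection, point-cloud construction, normals, registration metrics."""

import numpy as np
import pytest

from herdrecon.camera import PinholeIntrinsics, project, unproject
from herdrecon.io import RGBDFrame
from herdrecon.pointcloud import (
    PointCloud,
    depth_to_pointcloud,
    estimate_normals,
    evaluate_registration,
    voxel_downsample,
)
from herdrecon.transforms import RigidTransform, se3_exp

K = PinholeIntrinsics(width=640, height=480, fx=600.0, fy=600.0, cx=320.0, cy=240.0)


class TestProjection:
    def test_principal_point_on_axis(self):
        assert np.allclose(unproject(K.cx, K.cy, 1.0, K), (0, 0, 1, 1))
        u, v, d = project((0.0, 0.0, 1.0), K)
        assert (u, v, d) == (K.cx, K.cy, 1.0)

    def test_hand_evaluated_pixel(self):
        # (u-cx) d / fx = (920-320)*2/600 = 2.0
        assert np.allclose(unproject(920, 240, 2.0, K), (2.0, 0.0, 2.0, 1.0))
        u, v, d = project((2.0, 0.0, 2.0), K)
        assert np.allclose((u, v, d), (920.0, 240.0, 2.0))

    def test_roundtrip_random_pixels(self):
        rng = np.random.default_rng(0)
        u = rng.uniform(0, K.width - 1, 2000)
        v = rng.uniform(0, K.height - 1, 2000)
        d = rng.uniform(0.1, 10.0, 2000)
        s = unproject(u, v, d, K)
        u2, v2, d2 = project(s, K)
        assert np.allclose(u2, u, rtol=1e-9) and np.allclose(v2, v, rtol=1e-9)
        assert np.allclose(d2, d, rtol=1e-12)

    def test_invalid_depth_rejected(self):
        with pytest.raises(ValueError):
            unproject(10, 10, 0.0, K)
        with pytest.raises(ValueError):
            project((0.0, 0.0, -1.0), K)


class TestDepthToPointcloud:
    def test_constant_plane(self):
        frame = RGBDFrame(np.full((480, 640), 0.5), np.ones((480, 640)))
        pc = depth_to_pointcloud(frame, K, stride=4)
        assert np.allclose(pc.points[:, 2], 1.0)
        assert np.allclose(pc.intensity, 0.5)

    def test_all_invalid_gives_empty(self):
        frame = RGBDFrame(np.zeros((480, 640)), np.zeros((480, 640)))
        assert len(depth_to_pointcloud(frame, K)) == 0

    def test_count_matches_bruteforce(self):
        rng = np.random.default_rng(1)
        depth = np.where(rng.random((480, 640)) < 0.3, rng.uniform(0.5, 2, (480, 640)), 0.0)
        frame = RGBDFrame(np.zeros((480, 640)), depth)
        stride = 3
        expected = int(np.count_nonzero(depth[::stride, ::stride] > 0))
        assert len(depth_to_pointcloud(frame, K, stride=stride)) == expected


class TestNormals:
    def test_plane_normals_point_at_viewpoint(self):
        rng = np.random.default_rng(2)
        xy = rng.uniform(-1, 1, (500, 2))
        pc = PointCloud(np.column_stack([xy, np.ones(500)]))
        out = estimate_normals(pc, k_neighbors=10, viewpoint=(0, 0, 0))
        assert np.allclose(out.normals, [0, 0, -1], atol=1e-6)

    def test_sphere_normals_radial(self):
        import trimesh

        v = trimesh.creation.icosphere(subdivisions=4, radius=1.0).vertices
        out = estimate_normals(PointCloud(v), k_neighbors=12, viewpoint=(0, 0, 10))
        cos = np.abs(np.einsum("ij,ij->i", out.normals, v / np.linalg.norm(v, axis=1, keepdims=True)))
        assert np.degrees(np.arccos(np.clip(cos, -1, 1))).max() < 2.0

    def test_viewpoint_flip_flips_normals(self):
        rng = np.random.default_rng(4)
        xy = rng.uniform(-1, 1, (200, 2))
        pc = PointCloud(np.column_stack([xy, np.zeros(200)]))
        a = estimate_normals(pc, 10, viewpoint=(0, 0, 5)).normals
        b = estimate_normals(pc, 10, viewpoint=(0, 0, -5)).normals
        assert np.allclose(a, -b, atol=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            estimate_normals(PointCloud(np.zeros((3, 3))), k_neighbors=10)


class TestEvaluateRegistration:
    def test_identical_clouds(self):
        rng = np.random.default_rng(5)
        pc = PointCloud(rng.random((100, 3)))
        res = evaluate_registration(pc, pc, RigidTransform.identity(), 0.01)
        assert res.fitness == 1.0 and res.inlier_rmse == 0.0

    def test_separated_clouds(self):
        rng = np.random.default_rng(6)
        a = PointCloud(rng.random((50, 3)))
        b = PointCloud(rng.random((50, 3)) + 100.0)
        res = evaluate_registration(a, b, RigidTransform.identity(), 0.05)
        assert res.fitness == 0.0

    def test_three_point_toy_matches_hand_computation(self):
        target = PointCloud(np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], dtype=float))
        source = PointCloud(np.array([[0.01, 0, 0], [1, 0.02, 0], [0, 1, 0.5]], dtype=float))
        res = evaluate_registration(source, target, RigidTransform.identity(), 0.1)
        # nearest neighbors by hand: dists 0.01, 0.02; third point is 0.5 away (outlier)
        assert res.fitness == pytest.approx(2 / 3)
        assert res.inlier_rmse == pytest.approx(np.sqrt((0.01**2 + 0.02**2) / 2), rel=1e-12)

    def test_invariance_under_common_rigid_motion(self):
        rng = np.random.default_rng(7)
        src = PointCloud(rng.random((200, 3)))
        tgt = PointCloud(rng.random((300, 3)))
        T = se3_exp(rng.normal(size=6) * 0.3)
        G = se3_exp(rng.normal(size=6) * 0.5)
        base = evaluate_registration(src, tgt, T, 0.05)
        moved = evaluate_registration(src.transformed(G), tgt.transformed(G),
                                      G @ T @ G.invert(), 0.05)
        assert moved.fitness == pytest.approx(base.fitness, abs=1e-12)
        assert moved.inlier_rmse == pytest.approx(base.inlier_rmse, abs=1e-9)

    def test_empty_cloud_rejected(self):
        with pytest.raises(ValueError):
            evaluate_registration(PointCloud(np.empty((0, 3))),
                                  PointCloud(np.zeros((1, 3))),
                                  RigidTransform.identity(), 0.1)


class TestVoxelDownsample:
    def test_single_voxel_averages(self):
        pc = PointCloud(np.array([[0.001, 0.001, 0.001], [0.003, 0.003, 0.003]]),
                        intensity=np.array([0.2, 0.4]))
        out = voxel_downsample(pc, 0.01)
        assert len(out) == 1
        assert np.allclose(out.points[0], [0.002, 0.002, 0.002])
        assert out.intensity[0] == pytest.approx(0.3)

    def test_reduces_density(self):
        rng = np.random.default_rng(8)
        pc = PointCloud(rng.random((5000, 3)))
        out = voxel_downsample(pc, 0.2)
        assert 0 < len(out) <= 6**3
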