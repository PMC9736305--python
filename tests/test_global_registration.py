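"""FPFH features, correspondence matching, FGR and the RANSAC baseline."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from herdrecon.global_registration import (
    RobustPenaltyConfig,
    compute_fpfh,
    fgr_register,
    match_features,
    ransac_register,
    rigid_fit,
)
from herdrecon.pointcloud import CorrespondenceSet, PointCloud, estimate_normals
from herdrecon.transforms import RigidTransform, rotation_angle, se3_exp


def _spfh_oracle(points, normals, radius):
    """Exhaustive O(N^2) SPFH + FPFH: plain loops, no KD-tree, no vectorization."""
    n = len(points)
    nbins = 11
    spfh = np.zeros((n, 33))
    neighbors = [[] for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = points[j] - points[i]
            dist = np.linalg.norm(d)
            if dist > radius or dist == 0:
                continue
            neighbors[i].append(j)
            dhat = d / dist
            u = normals[i]
            phi = float(u @ dhat)
            v = np.cross(dhat, u)
            vn = np.linalg.norm(v)
            v = v / max(vn, 1e-12)
            w = np.cross(u, v)
            alpha = float(v @ normals[j])
            theta = float(np.arctan2(w @ normals[j], u @ normals[j]))
            ba = min(int((alpha + 1) / 2 * nbins), nbins - 1)
            bp = min(int((phi + 1) / 2 * nbins), nbins - 1)
            bt = min(int((theta + np.pi) / (2 * np.pi) * nbins), nbins - 1)
            spfh[i, ba] += 1
            spfh[i, nbins + bp] += 1
            spfh[i, 2 * nbins + bt] += 1
    fpfh = spfh.copy()
    for i in range(n):
        if not neighbors[i]:
            continue
        acc = np.zeros(33)
        for j in neighbors[i]:
            acc += spfh[j] / np.linalg.norm(points[j] - points[i])
        fpfh[i] += acc / len(neighbors[i])
    for b in range(3):
        block = fpfh[:, b * nbins:(b + 1) * nbins]
        s = block.sum(axis=1, keepdims=True)
        nz = s[:, 0] > 0
        block[nz] = block[nz] / s[nz] * 100.0
    return fpfh


class TestFPFH:
    def test_matches_bruteforce_oracle_on_toy(self):
        rng = np.random.default_rng(0)
        pts = rng.random((5, 3))
        nrm = rng.normal(size=(5, 3))
        nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
        pc = PointCloud(pts, normals=nrm)
        ours, isolated = compute_fpfh(pc, radius=2.0)
        oracle = _spfh_oracle(pts, nrm, 2.0)
        assert np.allclose(ours, oracle, atol=1e-9)
        assert not isolated.any()

    def test_rigid_invariance(self, surface_patch):
        pc = surface_patch
        T = se3_exp([0.3, -0.2, 0.5, 1.0, -2.0, 0.5])
        f0, _ = compute_fpfh(pc, radius=0.05)
        f1, _ = compute_fpfh(pc.transformed(T), radius=0.05)
        assert np.allclose(f0, f1, atol=1e-6)

    def test_plane_interior_histograms_identical(self):
        xs, ys = np.meshgrid(np.linspace(0, 1, 15), np.linspace(0, 1, 15))
        pts = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(225)])
        nrm = np.tile([0.0, 0.0, 1.0], (225, 1))
        f, _ = compute_fpfh(PointCloud(pts, normals=nrm), radius=0.09)
        interior = (
            (pts[:, 0] > 0.25) & (pts[:, 0] < 0.75)
            & (pts[:, 1] > 0.25) & (pts[:, 1] < 0.75)
        )
        ref = f[interior][0]
        assert np.allclose(f[interior], ref, atol=1e-6)

    def test_isolated_point_flagged_zero(self):
        pts = np.array([[0, 0, 0], [10, 0, 0], [10.01, 0, 0], [10, 0.01, 0]])
        nrm = np.tile([0.0, 0.0, 1.0], (4, 1))
        f, isolated = compute_fpfh(PointCloud(pts, normals=nrm), radius=0.1)
        assert isolated[0] and not isolated[1]
        assert np.allclose(f[0], 0.0)


class TestMatching:
    def test_self_match_is_identity(self, surface_patch):
        f, _ = compute_fpfh(surface_patch, radius=0.05)
        corr = match_features(f, f, surface_patch.points, surface_patch.points,
                              tuple_test=False)
        identity_pairs = np.count_nonzero(corr.pairs[:, 0] == corr.pairs[:, 1])
        assert identity_pairs / len(corr) > 0.95

    def test_rigid_copy_recovers_permutation(self, surface_patch):
        pc = surface_patch
        T = se3_exp([0.1, 0.2, -0.1, 0.5, 0.0, 0.3])
        moved = pc.transformed(T)
        fp, _ = compute_fpfh(pc, radius=0.05)
        fq, _ = compute_fpfh(moved, radius=0.05)
        corr = match_features(fp, fq, pc.points, moved.points, seed=0)
        good = np.count_nonzero(corr.pairs[:, 0] == corr.pairs[:, 1])
        assert len(corr) >= 10
        assert good / len(corr) >= 0.9

    def test_mutual_nn_matches_distance_matrix_oracle(self):
        rng = np.random.default_rng(1)
        fp = rng.random((50, 33))
        fq = rng.random((40, 33))
        corr = match_features(fp, fq, tuple_test=False)
        # exhaustive oracle
        D = np.linalg.norm(fp[:, None, :] - fq[None, :, :], axis=2)
        expected = {
            (int(np.argmin(D[:, j])), j)
            for j in range(40)
            if np.argmin(D[np.argmin(D[:, j])]) == j
        }
        assert {tuple(p) for p in corr.pairs} == expected

    def test_empty_features_rejected(self):
        with pytest.raises(ValueError):
            match_features(np.empty((0, 33)), np.ones((3, 33)))


class TestFGR:
    def _make_pair(self, n=300, outlier_frac=0.0, seed=0):
        rng = np.random.default_rng(seed)
        P = rng.uniform(-0.5, 0.5, (n, 3))
        T_true = se3_exp([0.05, -0.08, 0.1, 0.05, 0.02, -0.04])
        Q = T_true.invert().apply(P)        # aligning Q onto P recovers T_true
        pairs = np.column_stack([np.arange(n), np.arange(n)])
        n_out = int(outlier_frac * n)
        if n_out:
            pairs[:n_out, 0] = rng.integers(0, n, n_out)   # spurious matches
        return PointCloud(P), PointCloud(Q), CorrespondenceSet(pairs), T_true

    def test_exact_copy_identity(self):
        rng = np.random.default_rng(2)
        P = PointCloud(rng.random((100, 3)))
        pairs = CorrespondenceSet(np.column_stack([np.arange(100), np.arange(100)]))
        res = fgr_register(P, P, pairs)
        assert rotation_angle(res.transform.rotation) < 1e-9
        assert np.linalg.norm(res.transform.translation) < 1e-9

    def test_robust_to_30pct_spurious(self):
        P, Q, corr, T_true = self._make_pair(outlier_frac=0.3, seed=3)
        res = fgr_register(P, Q, corr)
        assert np.degrees(rotation_angle(res.transform.rotation.T @ T_true.rotation)) < 0.5
        assert np.linalg.norm(res.transform.translation - T_true.translation) < 0.005

    def test_huge_mu_matches_least_squares_oracle(self):
        """With a single outer iteration at enormous mu every weight is ~1 and
        the result equals the closed-form rigid fit."""
        P, Q, corr, _ = self._make_pair(outlier_frac=0.2, seed=4)
        cfg = RobustPenaltyConfig(mu_init=1e12, mu_final=1e11,
                                  outer_iterations=1, anneal_every=10)
        res = fgr_register(P, Q, corr, cfg=cfg)
        oracle = rigid_fit(P.points[corr.target_indices], Q.points[corr.source_indices])
        assert np.allclose(res.transform.matrix, oracle.matrix, atol=1e-6)

    def test_degenerate_geometry_flagged(self):
        t = np.linspace(0, 1, 10)
        line = np.column_stack([t, t, t])
        pairs = CorrespondenceSet(np.column_stack([np.arange(10), np.arange(10)]))
        res = fgr_register(PointCloud(line), PointCloud(line + 0.01), pairs)
        assert not res.converged
        assert "degenerate" in res.message


class TestRANSAC:
    def test_exact_copy_identity(self):
        rng = np.random.default_rng(5)
        P = PointCloud(rng.random((80, 3)))
        pairs = CorrespondenceSet(np.column_stack([np.arange(80), np.arange(80)]))
        res = ransac_register(P, P, pairs, max_dist=0.01, seed=0)
        assert rotation_angle(res.transform.rotation) < 1e-9

    def test_robust_to_half_outliers(self):
        rng = np.random.default_rng(6)
        P = rng.uniform(-0.5, 0.5, (200, 3))
        T_true = se3_exp([0.1, 0.05, -0.1, 0.1, -0.05, 0.02])
        Q = T_true.invert().apply(P)
        pairs = np.column_stack([np.arange(200), np.arange(200)])
        pairs[:100, 0] = rng.integers(0, 200, 100)
        res = ransac_register(PointCloud(P), PointCloud(Q), CorrespondenceSet(pairs),
                              max_dist=0.02, seed=1)
        assert np.degrees(rotation_angle(res.transform.rotation.T @ T_true.rotation)) < 1.0
        assert np.linalg.norm(res.transform.translation - T_true.translation) < 0.01

    def test_seed_determinism(self):
        rng = np.random.default_rng(7)
        P = rng.uniform(-0.5, 0.5, (100, 3))
        Q = P + rng.normal(0, 0.005, P.shape)
        pairs = CorrespondenceSet(np.column_stack([np.arange(100), np.arange(100)]))
        a = ransac_register(PointCloud(P), PointCloud(Q), pairs, max_dist=0.02, seed=42)
        b = ransac_register(PointCloud(P), PointCloud(Q), pairs, max_dist=0.02, seed=42)
        assert np.array_equal(a.transform.matrix, b.transform.matrix)
        assert a.fitness == b.fitness and a.inlier_rmse == b.inlier_rmse


class TestComparison:
    def test_fgr_at_least_as_tight_as_ransac(self, surface_patch):
        """On overlapping synthetic patch pairs, FGR's refined inlier RMSE beats
        RANSAC's in a clear majority of seeded trials (direction only)."""
        pc = surface_patch
        wins = 0
        trials = 10
        for seed in range(trials):
            rng = np.random.default_rng(seed)
            T_true = se3_exp(rng.normal(size=6) * np.array([0.05] * 3 + [0.05] * 3))
            moved = pc.transformed(T_true.invert())
            fp, _ = compute_fpfh(pc, radius=0.05)
            fq, _ = compute_fpfh(moved, radius=0.05)
            corr = match_features(fp, fq, pc.points, moved.points, seed=seed)
            if len(corr) < 4:
                continue
            fgr = fgr_register(pc, moved, corr, eval_dist=0.02)
            ran = ransac_register(pc, moved, corr, max_dist=0.02, max_iters=500,
                                  seed=seed, eval_dist=0.02)
            if fgr.inlier_rmse <= ran.inlier_rmse + 1e-9:
                wins += 1
        assert wins >= 0.8 * trials
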