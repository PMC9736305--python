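"""Coarse alignment of fragment clouds without an initial guess.

Correspondences come from FPFH descriptors (33-bin fast point feature
histograms) matched by mutual nearest neighbor and pruned with the
length-ratio tuple test.  The robust objective

    E(T) = sum_{(p,q) in K} rho(p - T q)

with rho the scaled Geman-McClure penalty ``rho(r) = mu |r|^2 / (mu + |r|^2)``
is minimized by graduated non-convexity: alternating closed-form
line-process weights with an exact weighted rigid fit, annealing mu from
coarse to fine.  A classic correspondence-RANSAC solver is provided as
the comparison baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .pointcloud import CorrespondenceSet, PointCloud, RegistrationResult, evaluate_registration
from .transforms import RigidTransform

__all__ = [
    "RobustPenaltyConfig",
    "rigid_fit",
    "compute_fpfh",
    "match_features",
    "fgr_register",
    "ransac_register",
]


@dataclass
class RobustPenaltyConfig:
    mu_init: float | None = None        # squared meters; None -> (diameter/2)^2
    mu_final: float = 2.5e-5            # (5 mm)^2
    division_factor: float = 1.4
    outer_iterations: int = 64
    anneal_every: int = 4               # iterations between mu divisions

    def __post_init__(self):
        if self.division_factor <= 1:
            raise ValueError("division_factor must exceed 1")
        if self.mu_init is not None and self.mu_init <= self.mu_final:
            raise ValueError("mu_init must exceed mu_final")


def rigid_fit(p: np.ndarray, q: np.ndarray, weights=None) -> RigidTransform:
    """Closed-form (weighted Kabsch) T minimizing sum w |p - (R q + t)|^2."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    w = np.ones(len(p)) if weights is None else np.asarray(weights, dtype=float)
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("weights sum to zero")
    pc = (w[:, None] * p).sum(axis=0) / wsum
    qc = (w[:, None] * q).sum(axis=0) / wsum
    H = ((q - qc) * w[:, None]).T @ (p - pc)
    U, s, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = pc - R @ qc
    return RigidTransform.from_rotation_translation(R, t)


def _fit_is_degenerate(q: np.ndarray) -> bool:
    """Rank check: correspondence geometry must span 3D (non-collinear)."""
    qc = q - q.mean(axis=0)
    s = np.linalg.svd(qc, compute_uv=False)
    return s[1] < 1e-9 * max(s[0], 1e-12)


# ------------------------------------------------------------------ FPFH

_N_BINS = 11


def _pair_features(p_src, n_src, p_tgt, n_tgt):
    """Darboux-frame angles (alpha, phi, theta) for directed pairs src -> tgt."""
    d = p_tgt - p_src
    dist = np.linalg.norm(d, axis=1)
    dist = np.maximum(dist, 1e-12)
    d = d / dist[:, None]
    u = n_src
    phi = np.einsum("ij,ij->i", u, d)
    v = np.cross(d, u)
    vn = np.linalg.norm(v, axis=1)
    vn = np.maximum(vn, 1e-12)
    v = v / vn[:, None]
    w = np.cross(u, v)
    alpha = np.einsum("ij,ij->i", v, n_tgt)
    theta = np.arctan2(np.einsum("ij,ij->i", w, n_tgt), np.einsum("ij,ij->i", u, n_tgt))
    return alpha, phi, theta, dist


def _bin_features(alpha, phi, theta):
    ba = np.clip(((alpha + 1.0) / 2.0 * _N_BINS).astype(int), 0, _N_BINS - 1)
    bp = np.clip(((phi + 1.0) / 2.0 * _N_BINS).astype(int), 0, _N_BINS - 1)
    bt = np.clip(((theta + np.pi) / (2 * np.pi) * _N_BINS).astype(int), 0, _N_BINS - 1)
    return ba, bp, bt


def _spfh(points, normals, src_idx, tgt_idx, n_points):
    """Per-point 33-bin simplified histograms from directed neighbor pairs."""
    alpha, phi, theta, _ = _pair_features(
        points[src_idx], normals[src_idx], points[tgt_idx], normals[tgt_idx]
    )
    ba, bp, bt = _bin_features(alpha, phi, theta)
    hist = np.zeros((n_points, 3 * _N_BINS))
    np.add.at(hist, (src_idx, ba), 1.0)
    np.add.at(hist, (src_idx, _N_BINS + bp), 1.0)
    np.add.at(hist, (src_idx, 2 * _N_BINS + bt), 1.0)
    return hist


def compute_fpfh(pc: PointCloud, radius: float):
    """FPFH descriptors, (N, 33); isolated points get zero histograms.

    Returns ``(features, isolated_mask)``.
    """
    if pc.normals is None:
        raise ValueError("FPFH requires normals")
    if radius <= 0:
        raise ValueError("radius must be positive")
    n = len(pc)
    tree = pc.kdtree()
    pairs = tree.query_pairs(radius, output_type="ndarray")
    if pairs.size == 0:
        return np.zeros((n, 3 * _N_BINS)), np.ones(n, dtype=bool)
    src = np.concatenate([pairs[:, 0], pairs[:, 1]])
    tgt = np.concatenate([pairs[:, 1], pairs[:, 0]])
    spfh = _spfh(pc.points, pc.normals, src, tgt, n)

    # neighbor-weighted aggregation: F(p) = S(p) + (1/k) sum_r S(r) / dist(p, r)
    dists = np.linalg.norm(pc.points[src] - pc.points[tgt], axis=1)
    inv_d = 1.0 / np.maximum(dists, 1e-12)
    k_counts = np.bincount(src, minlength=n).astype(float)
    fpfh = spfh.copy()
    weighted_sum = np.zeros_like(spfh)
    for c in range(spfh.shape[1]):
        weighted_sum[:, c] = np.bincount(src, weights=spfh[tgt, c] * inv_d, minlength=n)
    has_neigh = k_counts > 0
    fpfh[has_neigh] += weighted_sum[has_neigh] / k_counts[has_neigh, None]

    # normalize each 11-bin block to sum 100 (scale-free histograms)
    for b in range(3):
        block = fpfh[:, b * _N_BINS : (b + 1) * _N_BINS]
        sums = block.sum(axis=1, keepdims=True)
        nz = sums[:, 0] > 0
        block[nz] = block[nz] / sums[nz] * 100.0
    return fpfh, ~has_neigh


def match_features(
    fpfh_p: np.ndarray,
    fpfh_q: np.ndarray,
    points_p: np.ndarray | None = None,
    points_q: np.ndarray | None = None,
    tuple_test: bool = True,
    tuple_scale: float = 0.9,
    n_tuples: int = 1000,
    seed: int = 0,
) -> CorrespondenceSet:
    """Mutual nearest neighbors in 33-dim feature space, optionally pruned
    by the length-ratio tuple test (needs the point coordinates)."""
    if len(fpfh_p) == 0 or len(fpfh_q) == 0:
        raise ValueError("empty feature set")
    tree_p = cKDTree(fpfh_p)
    tree_q = cKDTree(fpfh_q)
    _, q_to_p = tree_p.query(fpfh_q)
    _, p_to_q = tree_q.query(fpfh_p)
    j = np.arange(len(fpfh_q))
    mutual = p_to_q[q_to_p] == j
    pairs = np.column_stack([q_to_p[mutual], j[mutual]])
    if pairs.shape[0] == 0:
        return CorrespondenceSet(np.empty((0, 2), dtype=int))

    if tuple_test and points_p is not None and points_q is not None and len(pairs) >= 3:
        rng = np.random.default_rng(seed)
        m = len(pairs)
        keep = np.zeros(m, dtype=bool)
        trials = rng.integers(0, m, size=(n_tuples, 3))
        lo, hi = tuple_scale, 1.0 / tuple_scale
        for tri in trials:
            if len(set(tri.tolist())) < 3:
                continue
            pi = points_p[pairs[tri, 0]]
            qi = points_q[pairs[tri, 1]]
            ok = True
            for a, b in ((0, 1), (1, 2), (0, 2)):
                dp = np.linalg.norm(pi[a] - pi[b])
                dq = np.linalg.norm(qi[a] - qi[b])
                if dq < 1e-12 or not (lo <= dp / dq <= hi):
                    ok = False
                    break
            if ok:
                keep[tri] = True
        if np.any(keep):
            pairs = pairs[keep]
    return CorrespondenceSet(pairs)


# ------------------------------------------------------------------ FGR

def fgr_register(
    P: PointCloud,
    Q: PointCloud,
    K: CorrespondenceSet,
    cfg: RobustPenaltyConfig | None = None,
    eval_dist: float = 0.025,
) -> RegistrationResult:
    """Graduated-non-convexity minimization of the Geman-McClure objective.

    Each outer iteration computes closed-form line-process weights
    ``l = (mu / (mu + |r|^2))^2`` and re-fits T by the exact weighted rigid
    fit; mu is divided by ``division_factor`` every ``anneal_every``
    iterations down to ``mu_final``.  The joint line-process objective is
    non-increasing at fixed mu by construction of the alternation.
    """
    cfg = cfg or RobustPenaltyConfig()
    if len(K) < 4:
        raise ValueError("FGR needs at least 4 correspondences")
    p = P.points[K.target_indices]
    q = Q.points[K.source_indices]
    if _fit_is_degenerate(q) or _fit_is_degenerate(p):
        return RegistrationResult(
            RigidTransform.identity(), 0.0, 0.0, K, converged=False,
            message="degenerate correspondence geometry (rank-deficient)",
        )

    if cfg.mu_init is None:
        span = np.vstack([p, q])
        diameter = np.linalg.norm(span.max(axis=0) - span.min(axis=0))
        mu = max((diameter / 2.0) ** 2, cfg.mu_final * 2)
    else:
        mu = cfg.mu_init

    T = RigidTransform.identity()
    for it in range(cfg.outer_iterations):
        r2 = np.sum((p - T.apply(q)) ** 2, axis=1)
        l = (mu / (mu + r2)) ** 2
        T = rigid_fit(p, q, weights=l)
        if (it + 1) % cfg.anneal_every == 0:
            mu = max(mu / cfg.division_factor, cfg.mu_final)

    result = evaluate_registration(Q, P, T, max_dist=eval_dist)
    result.iterations = cfg.outer_iterations
    return result


def ransac_register(
    P: PointCloud,
    Q: PointCloud,
    K: CorrespondenceSet,
    max_dist: float,
    max_iters: int = 4000,
    seed: int = 0,
    eval_dist: float | None = None,
) -> RegistrationResult:
    """Correspondence RANSAC: best of ``max_iters`` 3-point closed-form fits
    scored by inlier count at ``max_dist``, refit on the final inlier set.
    Deterministic given ``seed``."""
    if len(K) < 3:
        raise ValueError("RANSAC needs at least 3 correspondences")
    p = P.points[K.target_indices]
    q = Q.points[K.source_indices]
    rng = np.random.default_rng(seed)
    m = len(p)
    best_inliers = None
    best_count = 2
    for _ in range(max_iters):
        tri = rng.integers(0, m, size=3)
        if len(set(tri.tolist())) < 3:
            continue
        qs = q[tri]
        if _fit_is_degenerate(qs):
            continue
        T = rigid_fit(p[tri], qs)
        resid = np.linalg.norm(p - T.apply(q), axis=1)
        inliers = resid <= max_dist
        count = int(inliers.sum())
        if count > best_count:
            best_count = count
            best_inliers = inliers
    if best_inliers is None or best_count < 3:
        return RegistrationResult(
            RigidTransform.identity(), 0.0, 0.0, K, converged=False,
            message="no consensus model with >= 3 inliers",
        )
    T = rigid_fit(p[best_inliers], q[best_inliers])
    result = evaluate_registration(Q, P, T, max_dist=eval_dist or max_dist)
    result.iterations = max_iters
    return result
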