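"""Local registration refinement: point-to-point, point-to-plane, colored ICP.

All three alternate nearest-neighbor correspondence search (gated by a
maximum distance) with a transform update:

* point-to-point — exact closed-form rigid fit per iteration;
* point-to-plane — damped Gauss-Newton on the 6-dof increment of
  ``E(T) = sum ((p - T q) . n_p)^2``;
* colored — joint objective ``E = (1 - delta) E_C + delta E_G`` where E_G
  is the point-to-plane term and E_C compares the source intensity C(q)
  with a precomputed linear intensity model on the tangent plane of its
  target correspondent (value + in-plane gradient), evaluated at the
  orthogonal projection of T q onto that plane.  With delta = 1 the color
  term vanishes identically and the update equals point-to-plane ICP
  iterate for iterate.

Colored ICP runs a coarse-to-fine multi-scale schedule (voxel sizes
decreasing, correspondence distance 2x the voxel size at each scale).
Damping rejects any step that increases the objective on the current
correspondence set, so the per-iteration objective is non-increasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .global_registration import rigid_fit
from .pointcloud import (
    CorrespondenceSet,
    PointCloud,
    RegistrationResult,
    evaluate_registration,
    voxel_downsample,
)
from .transforms import RigidTransform, se3_exp

__all__ = [
    "ColoredICPConfig",
    "TangentPlaneColorModel",
    "icp_point_to_point",
    "icp_point_to_plane",
    "precompute_color_model",
    "colored_icp",
]


@dataclass
class ColoredICPConfig:
    delta: float = 0.968                # geometric weight of the joint objective
    scales: tuple = ((0.02, 50), (0.01, 30), (0.005, 14))   # (voxel m, max iters)
    max_correspondence_factor: float = 2.0   # max corr dist = factor * voxel size
    convergence_tol: float = 1e-8
    color_model_radius_factor: float = 3.0   # gradient-fit radius = factor * voxel

    def __post_init__(self):
        if not (0.0 <= self.delta <= 1.0):
            raise ValueError("delta must lie in [0, 1]")
        voxels = [v for v, _ in self.scales]
        if any(b >= a for a, b in zip(voxels, voxels[1:])) is False and voxels != sorted(
            voxels, reverse=True
        ):
            raise ValueError("scales must go coarse to fine (strictly decreasing voxel)")


@dataclass
class TangentPlaneColorModel:
    """Per-target-point intensity value and in-plane intensity gradient."""

    intensity: np.ndarray          # (N,)
    gradient: np.ndarray           # (N, 3), orthogonal to the point normal
    underdetermined: np.ndarray    # (N,) bool: < 3 neighbors, gradient zeroed


def _correspondences(src_pts, tgt_tree, max_dist):
    dist, idx = tgt_tree.query(src_pts)
    ok = dist <= max_dist
    return np.flatnonzero(ok), idx[ok], dist[ok]


def icp_point_to_point(
    source: PointCloud,
    target: PointCloud,
    init: RigidTransform | None = None,
    max_dist: float = 0.02,
    max_iters: int = 30,
    tol: float = 1e-10,
) -> RegistrationResult:
    """Classic ICP with exact closed-form rigid refit each iteration."""
    T = init or RigidTransform.identity()
    tree = target.kdtree()
    prev_rmse = np.inf
    iterations = 0
    history = []
    for it in range(max_iters):
        moved = T.apply(source.points)
        s_idx, t_idx, dist = _correspondences(moved, tree, max_dist)
        if len(s_idx) < 3:
            return RegistrationResult(
                T, 0.0, 0.0, converged=False, iterations=it,
                message="no correspondences within max_dist",
            )
        T = rigid_fit(target.points[t_idx], source.points[s_idx])
        rmse = float(np.sqrt(np.mean(np.sum(
            (target.points[t_idx] - T.apply(source.points[s_idx])) ** 2, axis=1))))
        history.append(rmse)
        iterations = it + 1
        if np.isfinite(prev_rmse) and abs(prev_rmse - rmse) <= tol * max(prev_rmse, 1e-30):
            break
        prev_rmse = rmse
    result = evaluate_registration(source, target, T, max_dist)
    result.iterations = iterations
    result.rmse_history = history
    return result


def _plane_system(p, n, q_moved, weights_geom, delta, color=None):
    """Objective, J^T J, J^T r for the (colored) point-to-plane linearization.

    ``color``: optional (Cq, Cp, grad) arrays for the photometric rows.
    """
    r_g = np.einsum("ij,ij->i", q_moved - p, n)
    J_g = np.column_stack([np.cross(q_moved, n), n])
    obj = delta * float(np.sum(weights_geom * r_g**2))
    JtJ = delta * (J_g * weights_geom[:, None]).T @ J_g
    Jtr = delta * (J_g * weights_geom[:, None]).T @ r_g
    if color is not None and delta < 1.0:
        Cq, Cp, grad = color
        # orthogonal projection of q_moved onto p's tangent plane
        offset = q_moved - p
        proj = offset - n * np.einsum("ij,ij->i", offset, n)[:, None]
        r_c = Cp + np.einsum("ij,ij->i", grad, proj) - Cq
        J_c = np.column_stack([np.cross(q_moved, grad), grad])
        w = 1.0 - delta
        obj += w * float(np.sum(r_c**2))
        JtJ = JtJ + w * (J_c.T @ J_c)
        Jtr = Jtr + w * (J_c.T @ r_c)
    return obj, JtJ, Jtr


def _icp_plane_like(
    source: PointCloud,
    target: PointCloud,
    init: RigidTransform,
    max_dist: float,
    max_iters: int,
    delta: float,
    color_model: TangentPlaneColorModel | None,
    tol: float,
):
    """Shared Gauss-Newton loop for point-to-plane (delta=1) and colored ICP."""
    if target.normals is None:
        raise ValueError("target normals are required")
    T = init
    tree = target.kdtree()
    iterations = 0
    history = []
    rmse_history = []
    for it in range(max_iters):
        moved = T.apply(source.points)
        s_idx, t_idx, _ = _correspondences(moved, tree, max_dist)
        if len(s_idx) < 3:
            return T, False, iterations, history, "no correspondences within max_dist", rmse_history
        p = target.points[t_idx]
        n = target.normals[t_idx]
        qm = moved[s_idx]
        w = np.ones(len(s_idx))
        color = None
        if color_model is not None and delta < 1.0:
            if source.intensity is None:
                raise ValueError("colored ICP requires source intensity")
            color = (source.intensity[s_idx], color_model.intensity[t_idx],
                     color_model.gradient[t_idx])
        obj, JtJ, Jtr = _plane_system(p, n, qm, w, delta, color)
        lam = 1e-6
        stepped = False
        for _ in range(7):
            try:
                xi = np.linalg.solve(JtJ + lam * np.diag(np.diag(JtJ)) + 1e-14 * np.eye(6), -Jtr)
            except np.linalg.LinAlgError:
                break
            T_new = se3_exp(xi) @ T
            qm_new = T_new.apply(source.points[s_idx])
            new_obj, _, _ = _plane_system(p, n, qm_new, w, delta, color)
            if new_obj <= obj:
                T = T_new
                stepped = True
                break
            lam *= 10.0
        iterations = it + 1
        history.append(obj)
        rmse_history.append(float(np.sqrt(np.mean(
            np.sum((T.apply(source.points[s_idx]) - p) ** 2, axis=1)))))
        if not stepped:
            break
        if len(history) >= 2 and abs(history[-2] - history[-1]) <= tol * max(history[-2], 1e-30):
            break
        if obj <= 1e-30:
            break
    return T, True, iterations, history, "", rmse_history


def icp_point_to_plane(
    source: PointCloud,
    target: PointCloud,
    init: RigidTransform | None = None,
    max_dist: float = 0.02,
    max_iters: int = 30,
    tol: float = 1e-10,
) -> RegistrationResult:
    """Point-to-plane ICP (linearized least squares per iteration, damped)."""
    T, ok, iters, history, msg, rmse_hist = _icp_plane_like(
        source, target, init or RigidTransform.identity(), max_dist, max_iters,
        delta=1.0, color_model=None, tol=tol,
    )
    if not ok:
        return RegistrationResult(T, 0.0, 0.0, converged=False, iterations=iters, message=msg)
    result = evaluate_registration(source, target, T, max_dist)
    result.iterations = iters
    result.rmse_history = rmse_hist
    return result


def precompute_color_model(target: PointCloud, radius: float) -> TangentPlaneColorModel:
    """Least-squares per-point intensity gradient, projected into the tangent plane."""
    if target.intensity is None:
        raise ValueError("target intensity is required for the color model")
    if target.normals is None:
        raise ValueError("target normals are required for the color model")
    n_pts = len(target)
    tree = target.kdtree()
    neighbors = tree.query_ball_point(target.points, radius)
    gradient = np.zeros((n_pts, 3))
    under = np.zeros(n_pts, dtype=bool)
    for i, idx in enumerate(neighbors):
        idx = [j for j in idx if j != i]
        if len(idx) < 3:
            under[i] = True
            continue
        A = target.points[idx] - target.points[i]
        b = target.intensity[idx] - target.intensity[i]
        AtA = A.T @ A + 1e-12 * np.eye(3)
        g = np.linalg.solve(AtA, A.T @ b)
        n = target.normals[i]
        gradient[i] = g - n * (n @ g)
    return TangentPlaneColorModel(
        intensity=target.intensity.copy(), gradient=gradient, underdetermined=under
    )


def colored_icp(
    source: PointCloud,
    target: PointCloud,
    init: RigidTransform | None = None,
    cfg: ColoredICPConfig | None = None,
) -> RegistrationResult:
    """Multi-scale colored ICP; with delta = 1 it reduces to point-to-plane."""
    cfg = cfg or ColoredICPConfig()
    if cfg.delta < 1.0 and (source.intensity is None or target.intensity is None):
        raise ValueError("colored ICP (delta < 1) requires intensity on both clouds")
    if target.normals is None:
        raise ValueError("colored ICP requires target normals")
    T = init or RigidTransform.identity()
    total_iters = 0
    all_rmse = []
    finest_dist = cfg.max_correspondence_factor * cfg.scales[-1][0]
    for voxel, iters in cfg.scales:
        src = voxel_downsample(source, voxel)
        tgt = voxel_downsample(target, voxel)
        if len(src) < 3 or len(tgt) < 3:
            continue
        max_dist = cfg.max_correspondence_factor * voxel
        model = None
        if cfg.delta < 1.0:
            model = precompute_color_model(tgt, cfg.color_model_radius_factor * voxel)
        T, ok, it, _, msg, rmse_hist = _icp_plane_like(
            src, tgt, T, max_dist, iters, cfg.delta, model, cfg.convergence_tol
        )
        all_rmse.extend(rmse_hist)
        total_iters += it
        if not ok:
            return RegistrationResult(
                T, 0.0, 0.0, converged=False, iterations=total_iters, message=msg
            )
    result = evaluate_registration(source, target, T, finest_dist)
    result.iterations = total_iters
    result.rmse_history = all_rmse
    return result
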