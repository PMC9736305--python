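"""Dense RGB-D frame-to-frame odometry.

Estimates the rigid motion T aligning frame j to frame i by minimizing a
joint objective over frame j's valid-pixel grid:

    E(T) = (1 - sigma) * E_I(T) + sigma * E_D(T)

where E_I sums squared intensity differences between each pixel x of
frame j and its warp x' into frame i (unproject with j's depth, apply T,
project), and E_D sums squared differences between frame i's depth at x'
and the z of the transformed point.  Minimization is damped Gauss-Newton
on a 6-dof se(3) increment, coarse-to-fine over an image pyramid; an
accepted step never increases the (mean per-pixel) objective.

Photometric residuals carry Huber weights so saturated/overexposed
regions do not dominate; both terms are evaluated on the same domain
(frame j's valid pixels that warp into frame i's valid area).

For non-adjacent frames :func:`wide_baseline_init` provides a rough
initialization from FAST-corner patch matches lifted to 3D through the
depth images and fitted rigidly inside RANSAC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .camera import PinholeIntrinsics
from .io import RGBDFrame
from .transforms import RigidTransform, se3_exp

__all__ = [
    "OdometryConfig",
    "OdometryResult",
    "photometric_residuals",
    "geometric_residuals",
    "compute_rgbd_odometry",
    "wide_baseline_init",
]


@dataclass
class OdometryConfig:
    sigma: float = 0.5                  # geometric-term weight in [0, 1]
    pyramid_levels: int = 3
    max_iterations: int = 10            # per pyramid level
    convergence_tol: float = 1e-6       # relative objective change
    max_depth_diff: float = 0.07        # meters; geometric-residual gate
    huber_scale: float = 0.03           # intensity units, photometric robustness
    min_inliers: int = 100              # success floor at the finest level

    def __post_init__(self):
        if not (0.0 <= self.sigma <= 1.0):
            raise ValueError("sigma must lie in [0, 1]")
        if self.pyramid_levels < 1:
            raise ValueError("pyramid_levels must be >= 1")


@dataclass
class OdometryResult:
    transform: RigidTransform
    success: bool
    final_objective: float
    inlier_pixel_count: int
    message: str = ""


# ------------------------------------------------------------------ helpers

def _downsample_gray(img):
    h, w = img.shape
    h2, w2 = h // 2, w // 2
    return img[: 2 * h2, : 2 * w2].reshape(h2, 2, w2, 2).mean(axis=(1, 3))


def _downsample_depth(img):
    h, w = img.shape
    h2, w2 = h // 2, w // 2
    blocks = img[: 2 * h2, : 2 * w2].reshape(h2, 2, w2, 2)
    valid = blocks > 0
    count = valid.sum(axis=(1, 3))
    total = (blocks * valid).sum(axis=(1, 3))
    out = np.zeros((h2, w2))
    nz = count > 0
    out[nz] = total[nz] / count[nz]
    return out


def _build_pyramid(frame: RGBDFrame, K: PinholeIntrinsics, levels: int):
    grays, depths, Ks = [frame.gray], [frame.depth], [K]
    for _ in range(levels - 1):
        grays.append(_downsample_gray(grays[-1]))
        depths.append(_downsample_depth(depths[-1]))
        k = Ks[-1]
        Ks.append(
            PinholeIntrinsics(
                width=grays[-1].shape[1],
                height=grays[-1].shape[0],
                fx=k.fx / 2,
                fy=k.fy / 2,
                cx=(k.cx + 0.5) / 2 - 0.5,
                cy=(k.cy + 0.5) / 2 - 0.5,
            )
        )
    return grays, depths, Ks


def _bilinear(img, u, v):
    """Bilinear sample; returns (values, valid) — valid requires in-bounds support."""
    h, w = img.shape
    u0 = np.floor(u).astype(int)
    v0 = np.floor(v).astype(int)
    inb = (u0 >= 0) & (u0 <= w - 2) & (v0 >= 0) & (v0 <= h - 2)
    u0c = np.clip(u0, 0, w - 2)
    v0c = np.clip(v0, 0, h - 2)
    fu = u - u0c
    fv = v - v0c
    p00 = img[v0c, u0c]
    p01 = img[v0c, u0c + 1]
    p10 = img[v0c + 1, u0c]
    p11 = img[v0c + 1, u0c + 1]
    val = (1 - fv) * ((1 - fu) * p00 + fu * p01) + fv * ((1 - fu) * p10 + fu * p11)
    return val, inb


def _bilinear_depth(img, u, v, interior=None):
    """Like :func:`_bilinear` but all four support depths must be valid (> 0).

    ``interior``: optional boolean mask; when given, all four support pixels
    must also be interior (used to keep warped samples away from silhouette
    edges whose finite-difference depth gradients are meaningless).
    """
    h, w = img.shape
    u0 = np.floor(u).astype(int)
    v0 = np.floor(v).astype(int)
    inb = (u0 >= 0) & (u0 <= w - 2) & (v0 >= 0) & (v0 <= h - 2)
    u0c = np.clip(u0, 0, w - 2)
    v0c = np.clip(v0, 0, h - 2)
    fu = u - u0c
    fv = v - v0c
    p00 = img[v0c, u0c]
    p01 = img[v0c, u0c + 1]
    p10 = img[v0c + 1, u0c]
    p11 = img[v0c + 1, u0c + 1]
    support = (p00 > 0) & (p01 > 0) & (p10 > 0) & (p11 > 0)
    if interior is not None:
        support &= (
            interior[v0c, u0c] & interior[v0c, u0c + 1]
            & interior[v0c + 1, u0c] & interior[v0c + 1, u0c + 1]
        )
    val = (1 - fv) * ((1 - fu) * p00 + fu * p01) + fv * ((1 - fu) * p10 + fu * p11)
    return val, inb & support


def _gradients(img):
    gy, gx = np.gradient(img)
    return gx, gy


def _warp(gray_i, depth_i, gray_j, depth_j, K_j, K_i, T: RigidTransform):
    """Warp frame j's valid pixels into frame i; returns per-pixel quantities."""
    from scipy.ndimage import binary_erosion

    interior_i = binary_erosion(depth_i > 0, np.ones((3, 3), dtype=bool))
    valid_j = depth_j > 0
    v_idx, u_idx = np.nonzero(valid_j)
    d_j = depth_j[valid_j]
    x = (u_idx - K_j.cx) * d_j / K_j.fx
    y = (v_idx - K_j.cy) * d_j / K_j.fy
    p_j = np.column_stack([x, y, d_j])
    p_i = p_j @ T.rotation.T + T.translation
    front = p_i[:, 2] > 1e-6
    u_w = np.full(len(p_i), -1.0)
    v_w = np.full(len(p_i), -1.0)
    u_w[front] = p_i[front, 0] * K_i.fx / p_i[front, 2] + K_i.cx
    v_w[front] = p_i[front, 1] * K_i.fy / p_i[front, 2] + K_i.cy
    I_i, ok_I = _bilinear(gray_i, u_w, v_w)
    D_i, ok_D = _bilinear_depth(depth_i, u_w, v_w, interior=interior_i)
    ok = front & ok_I & ok_D
    I_j = gray_j[valid_j]
    return dict(
        ok=ok, p_i=p_i, u_w=u_w, v_w=v_w, I_i=I_i, D_i=D_i, I_j=I_j, d_j=d_j,
        u_idx=u_idx, v_idx=v_idx,
    )


def photometric_residuals(frame_i, frame_j, T, K):
    """Per-pixel intensity residuals I_i(warp(x)) - I_j(x) on the shared valid domain."""
    w = _warp(frame_i.gray, frame_i.depth, frame_j.gray, frame_j.depth, K, K, T)
    ok = w["ok"]
    return (w["I_i"] - w["I_j"])[ok]


def geometric_residuals(frame_i, frame_j, T, K, max_depth_diff: float = 0.07):
    """Per-pixel depth residuals D_i(warp(x)) - z(T p(x)), gated at max_depth_diff."""
    w = _warp(frame_i.gray, frame_i.depth, frame_j.gray, frame_j.depth, K, K, T)
    ok = w["ok"]
    r = (w["D_i"] - w["p_i"][:, 2])[ok]
    return r[np.abs(r) <= max_depth_diff]


def _huber_rho(r, scale):
    """Huber loss (quadratic core, linear tails)."""
    a = np.abs(r)
    return np.where(a <= scale, r**2, scale * (2 * a - scale))


def _residual_state(gray_i, depth_i, gray_j, depth_j, K, T, cfg):
    """Residuals of every valid frame-j pixel under T.

    ``ok`` marks pixels with a valid, in-gate warp; arrays are aligned over
    all valid-j pixels so states under different T can be compared pixel for
    pixel (step acceptance uses the intersection of their ``ok`` sets).
    """
    w = _warp(gray_i, depth_i, gray_j, depth_j, K, K, T)
    ok = w["ok"].copy()
    rI = np.where(ok, w["I_i"] - w["I_j"], 0.0)
    rD = np.where(ok, w["D_i"] - w["p_i"][:, 2], 0.0)
    ok &= np.abs(rD) <= cfg.max_depth_diff
    return dict(ok=ok, rI=rI, rD=rD, p=w["p_i"], u_w=w["u_w"], v_w=w["v_w"])


def _masked_objective(state, mask, cfg):
    n = int(np.count_nonzero(mask))
    if n == 0:
        return np.inf
    rI = state["rI"][mask]
    rD = state["rD"][mask]
    return float(
        ((1 - cfg.sigma) * np.sum(_huber_rho(rI, cfg.huber_scale))
         + cfg.sigma * np.sum(rD**2)) / n
    )


def _gn_system(gray_i, depth_i, K, state, cfg):
    """Gauss-Newton normal equations from the in-gate pixels of ``state``."""
    ok = state["ok"]
    n = int(np.count_nonzero(ok))
    if n == 0:
        return None, None
    p = state["p"][ok]
    rI = state["rI"][ok]
    rD = state["rD"][ok]
    u_w = state["u_w"][ok]
    v_w = state["v_w"][ok]
    gx_I, gy_I = _gradients(gray_i)
    gx_D, gy_D = _gradients(depth_i)
    gIx, _ = _bilinear(gx_I, u_w, v_w)
    gIy, _ = _bilinear(gy_I, u_w, v_w)
    gDx, _ = _bilinear(gx_D, u_w, v_w)
    gDy, _ = _bilinear(gy_D, u_w, v_w)

    x, y, z = p[:, 0], p[:, 1], p[:, 2]
    iz = 1.0 / z
    du = np.column_stack([K.fx * iz, np.zeros_like(z), -K.fx * x * iz**2])
    dv = np.column_stack([np.zeros_like(z), K.fy * iz, -K.fy * y * iz**2])

    # dp/dxi for a left-multiplied increment: [ -hat(p) | I ]
    def chain(gu, gv, extra=None):
        gp = gu[:, None] * du + gv[:, None] * dv      # (n, 3) dr/dp
        if extra is not None:
            gp = gp + extra
        Jw = np.empty((len(z), 6))
        Jw[:, 0] = gp[:, 1] * (-z) + gp[:, 2] * y
        Jw[:, 1] = gp[:, 0] * z - gp[:, 2] * x
        Jw[:, 2] = gp[:, 1] * x - gp[:, 0] * y
        Jw[:, 3:] = gp
        return Jw

    J_I = chain(gIx, gIy)
    dz = np.zeros((len(z), 3))
    dz[:, 2] = -1.0
    J_D = chain(gDx, gDy, extra=dz)

    huber = np.minimum(1.0, cfg.huber_scale / np.maximum(np.abs(rI), 1e-12))
    wI = (1 - cfg.sigma) * huber
    wD = np.full(n, cfg.sigma)
    JtJ = ((J_I * wI[:, None]).T @ J_I + (J_D * wD[:, None]).T @ J_D) / n
    Jtr = ((J_I * wI[:, None]).T @ rI + (J_D * wD[:, None]).T @ rD) / n
    return JtJ, Jtr


def compute_rgbd_odometry(
    frame_i: RGBDFrame,
    frame_j: RGBDFrame,
    K: PinholeIntrinsics,
    init: RigidTransform | None = None,
    cfg: OdometryConfig | None = None,
) -> OdometryResult:
    """Estimate T aligning frame j to frame i (identity init for adjacent frames)."""
    cfg = cfg or OdometryConfig()
    T = init or RigidTransform.identity()
    grays_i, depths_i, Ks = _build_pyramid(frame_i, K, cfg.pyramid_levels)
    grays_j, depths_j, _ = _build_pyramid(frame_j, K, cfg.pyramid_levels)

    obj = np.inf
    n_inliers = 0
    for level in range(cfg.pyramid_levels - 1, -1, -1):
        gi, di, gj, dj, Kl = grays_i[level], depths_i[level], grays_j[level], depths_j[level], Ks[level]
        state = _residual_state(gi, di, gj, dj, Kl, T, cfg)
        n_inliers = int(np.count_nonzero(state["ok"]))
        obj = _masked_objective(state, state["ok"], cfg)
        if n_inliers == 0:
            continue
        lam = 1e-6
        for _ in range(cfg.max_iterations):
            JtJ, Jtr = _gn_system(gi, di, Kl, state, cfg)
            if JtJ is None:
                break
            accepted = False
            for _try in range(7):
                try:
                    delta = np.linalg.solve(
                        JtJ + lam * np.diag(np.diag(JtJ)) + 1e-14 * np.eye(6), -Jtr
                    )
                except np.linalg.LinAlgError:
                    break
                T_new = se3_exp(delta) @ T
                new_state = _residual_state(gi, di, gj, dj, Kl, T_new, cfg)
                # like-for-like comparison on the shared pixel set
                inter = state["ok"] & new_state["ok"]
                obj_old = _masked_objective(state, inter, cfg)
                obj_new = _masked_objective(new_state, inter, cfg)
                overlap_kept = (
                    np.count_nonzero(new_state["ok"]) >= 0.5 * np.count_nonzero(state["ok"])
                )
                if obj_new <= obj_old and overlap_kept:
                    rel = (obj_old - obj_new) / max(obj_old, 1e-30)
                    T = T_new
                    state = new_state
                    n_inliers = int(np.count_nonzero(state["ok"]))
                    obj = _masked_objective(state, state["ok"], cfg)
                    lam = max(lam / 3.0, 1e-9)
                    accepted = True
                    break
                lam *= 10.0
            if not accepted:
                break
            if rel < cfg.convergence_tol:
                break

    success = n_inliers >= cfg.min_inliers and np.isfinite(obj)
    msg = "" if success else f"insufficient overlap: {n_inliers} inlier pixels"
    return OdometryResult(
        transform=T,
        success=success,
        final_objective=float(obj if np.isfinite(obj) else 0.0),
        inlier_pixel_count=int(n_inliers),
        message=msg,
    )


# ------------------------------------------------------------------ wide baseline

def wide_baseline_init(
    frame_i: RGBDFrame,
    frame_j: RGBDFrame,
    K: PinholeIntrinsics,
    seed: int = 0,
    patch: int = 9,
    max_corners: int = 300,
) -> RigidTransform | None:
    """Rough alignment for non-adjacent frames: FAST corners, patch matching,
    3D lift through depth, rigid fit inside RANSAC.  Returns None on failure."""
    from skimage.feature import corner_fast, corner_peaks

    from .global_registration import ransac_register
    from .pointcloud import CorrespondenceSet, PointCloud

    def keypoints(frame):
        resp = corner_fast(frame.gray, n=9, threshold=0.05)
        pts = corner_peaks(resp, min_distance=3, num_peaks=max_corners)
        r = patch // 2
        keep = []
        h, w = frame.gray.shape
        for vy, ux in pts:
            if r <= vy < h - r and r <= ux < w - r and frame.depth[vy, ux] > 0:
                keep.append((vy, ux))
        return keep

    kp_i = keypoints(frame_i)
    kp_j = keypoints(frame_j)
    if len(kp_i) < 4 or len(kp_j) < 4:
        return None
    r = patch // 2

    def descriptors(frame, kps):
        d = np.array(
            [frame.gray[vy - r : vy + r + 1, ux - r : ux + r + 1].ravel() for vy, ux in kps]
        )
        d = d - d.mean(axis=1, keepdims=True)
        norm = np.linalg.norm(d, axis=1, keepdims=True)
        return d / np.maximum(norm, 1e-9)

    Di = descriptors(frame_i, kp_i)
    Dj = descriptors(frame_j, kp_j)
    sim = Di @ Dj.T
    best_j = sim.argmax(axis=1)
    best_i = sim.argmax(axis=0)
    mutual = [(a, b) for a, b in enumerate(best_j) if best_i[b] == a and sim[a, b] > 0.6]
    if len(mutual) < 4:
        return None

    def lift(frame, kps, idx):
        vy, ux = kps[idx]
        d = frame.depth[vy, ux]
        return ((ux - K.cx) * d / K.fx, (vy - K.cy) * d / K.fy, d)

    P = PointCloud(np.array([lift(frame_i, kp_i, a) for a, _ in mutual]))
    Q = PointCloud(np.array([lift(frame_j, kp_j, b) for _, b in mutual]))
    pairs = np.column_stack([np.arange(len(mutual)), np.arange(len(mutual))])
    res = ransac_register(
        P, Q, CorrespondenceSet(pairs), max_dist=0.05, max_iters=500, seed=seed
    )
    return res.transform if res.converged else None
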