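"""Stereo depth: disparity-to-depth conversion and a semi-global matcher.

Depth follows the rectified-stereo relation ``depth = B * fx / disparity``
on valid pixels (disparity > 0); disparity 0 is the invalid sentinel and
maps to invalid depth 0.  The matcher is a classical semi-global scheme —
census-transform matching cost, scanline cost aggregation over 8
directions, winner-take-all with a left-right consistency check — meant
as the traditional baseline to whatever external matcher produced the
input disparities.  The reconstruction pipeline accepts externally
produced disparity or depth images unchanged.

Disparity images on disk use 16-bit PNG with fixed-point scale
``DISPARITY_SCALE = 16`` counts per pixel of disparity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .camera import StereoRig

__all__ = ["DisparityMap", "DISPARITY_SCALE", "disparity_to_depth", "sgm_disparity"]

DISPARITY_SCALE = 16.0  # counts per pixel for 16-bit PNG storage


@dataclass
class DisparityMap:
    values: np.ndarray          # (H, W) float pixels; 0 = invalid
    min_disparity: float = 0.0
    max_disparity: float = np.inf

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        v = self.values[self.values > 0]
        if v.size and (np.any(v < self.min_disparity) or np.any(v > self.max_disparity)):
            raise ValueError("valid disparities outside the searched [min, max] range")


def disparity_to_depth(disp: DisparityMap | np.ndarray, rig: StereoRig) -> np.ndarray:
    """depth = B * fx / disparity on valid (>0) pixels, 0 elsewhere."""
    values = disp.values if isinstance(disp, DisparityMap) else np.asarray(disp, dtype=float)
    depth = np.zeros_like(values, dtype=float)
    valid = values > 0
    depth[valid] = rig.baseline * rig.intrinsics.fx / values[valid]
    return depth


def depth_to_disparity(depth: np.ndarray, rig: StereoRig) -> np.ndarray:
    """Inverse of :func:`disparity_to_depth` on valid pixels (used as ground truth)."""
    depth = np.asarray(depth, dtype=float)
    disp = np.zeros_like(depth)
    valid = depth > 0
    disp[valid] = rig.baseline * rig.intrinsics.fx / depth[valid]
    return disp


# ------------------------------------------------------------------ census SGM

def _census(img: np.ndarray, window: int = 5) -> np.ndarray:
    """Census transform: per pixel, bitstring of sign(img[neighbor] - img[center])."""
    h, w = img.shape
    r = window // 2
    padded = np.pad(img, r, mode="edge")
    out = np.zeros((h, w), dtype=np.uint32)
    bit = 0
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            if dy == 0 and dx == 0:
                continue
            neighbor = padded[r + dy : r + dy + h, r + dx : r + dx + w]
            out = (out << np.uint32(1)) | (neighbor > img).astype(np.uint32)
            bit += 1
    return out


def _hamming(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    x = (a ^ b).astype(np.uint32)
    count = np.zeros(x.shape, dtype=np.uint8)
    while np.any(x):
        count += (x & 1).astype(np.uint8)
        x >>= np.uint32(1)
    return count


def _cost_volume(left: np.ndarray, right: np.ndarray, max_disp: int, window: int,
                 sad_weight: float = 12.0, sad_cap: float = 0.12) -> np.ndarray:
    """(H, W, D) matching cost of left pixel x against right pixel x-d.

    Census hamming distance (robust to gain/offset differences such as
    overexposure) plus a truncated absolute intensity difference that keeps
    low-texture regions discriminative on well-exposed data.
    """
    cl = _census(left, window)
    cr = _census(right, window)
    h, w = left.shape
    n_bits = window * window - 1
    worst = n_bits + sad_weight
    cost = np.full((h, w, max_disp + 1), worst, dtype=np.float64)
    for d in range(max_disp + 1):
        lc = cl[:, d:]
        rc = cr[:, : w - d]
        sad = np.minimum(np.abs(left[:, d:] - right[:, : w - d]), sad_cap) / sad_cap
        cost[:, d:, d] = _hamming(lc, rc) + sad_weight * sad
    return cost


def aggregate_costs(cost: np.ndarray, P1: float, P2: float, directions=None) -> np.ndarray:
    """Sum of SGM path costs over scanline directions.

    The per-direction recurrence is the standard one:
    ``L(p,d) = C(p,d) + min(L(q,d), L(q,d±1)+P1, min_d' L(q,d')+P2) - min_d' L(q,d')``
    with q the predecessor pixel along the direction.
    """
    if directions is None:
        directions = [(0, 1), (0, -1), (1, 0), (-1, 0), (1, 1), (1, -1), (-1, 1), (-1, -1)]
    h, w, D = cost.shape
    total = np.zeros_like(cost, dtype=np.float64)
    for dy, dx in directions:
        total += _aggregate_one(cost, P1, P2, dy, dx)
    return total


def _sgm_step(prev: np.ndarray, cur_cost: np.ndarray, P1: float, P2: float) -> np.ndarray:
    """One recurrence step; prev/cur_cost are (..., D)."""
    m = prev.min(axis=-1, keepdims=True)
    down = np.roll(prev, 1, axis=-1) + P1
    down[..., 0] = np.inf   # no d-1 neighbor for d=0
    up = np.roll(prev, -1, axis=-1) + P1
    up[..., -1] = np.inf    # no d+1 neighbor for d=D-1
    best = np.minimum(np.minimum(prev, down), np.minimum(up, m + P2))
    return cur_cost + best - m


def _aggregate_one(cost: np.ndarray, P1: float, P2: float, dy: int, dx: int) -> np.ndarray:
    h, w, D = cost.shape
    L = np.zeros((h, w, D), dtype=np.float64)
    c = cost.astype(np.float64)
    if dy == 0:
        # horizontal sweep, vectorized over rows
        rng = range(w) if dx > 0 else range(w - 1, -1, -1)
        prev = None
        for x in rng:
            if prev is None:
                L[:, x] = c[:, x]
            else:
                L[:, x] = _sgm_step(prev, c[:, x], P1, P2)
            prev = L[:, x]
        return L
    # vertical / diagonal sweep, vectorized over columns with x-shift per row
    rows = range(h) if dy > 0 else range(h - 1, -1, -1)
    prev_row = None
    for y in rows:
        if prev_row is None:
            L[y] = c[y]
        else:
            if dx == 0:
                pred = prev_row
                L[y] = _sgm_step(pred, c[y], P1, P2)
            else:
                # predecessor of pixel x is (y-dy, x-dx); shift prev row by dx
                pred = np.full((w, D), np.inf)
                if dx > 0:
                    pred[dx:] = prev_row[:-dx]
                else:
                    pred[:dx] = prev_row[-dx:]
                has_pred = np.isfinite(pred[:, 0])
                stepped = _sgm_step(pred[has_pred], c[y][has_pred], P1, P2)
                L[y] = c[y]
                L[y][has_pred] = stepped
        prev_row = L[y]
    return L


def _wta(aggregated: np.ndarray, subpixel: bool = True) -> np.ndarray:
    """Winner-take-all with parabolic subpixel refinement of the minimum."""
    d = aggregated.argmin(axis=-1)
    if not subpixel:
        return d.astype(float)
    D = aggregated.shape[-1]
    interior = (d >= 1) & (d <= D - 2)
    idx = np.where(interior, d, 1)
    h, w = d.shape
    yy, xx = np.mgrid[0:h, 0:w]
    c0 = aggregated[yy, xx, idx - 1]
    c1 = aggregated[yy, xx, idx]
    c2 = aggregated[yy, xx, idx + 1]
    denom = c0 - 2 * c1 + c2
    offset = np.where(denom > 0, (c0 - c2) / np.maximum(2 * denom, 1e-12), 0.0)
    offset = np.clip(offset, -0.5, 0.5)
    out = d.astype(float)
    out[interior] += offset[interior]
    return out


def sgm_disparity(
    left: np.ndarray,
    right: np.ndarray,
    max_disp: int,
    penalties=(8.0, 96.0),
    window: int = 5,
    lr_threshold: float = 1.0,
) -> DisparityMap:
    """Semi-global disparity of the left image against the right.

    Failures of the left-right consistency check (threshold ``lr_threshold``
    pixels) are invalidated to 0 so the Eq.-style valid-pixel masking applies
    downstream unchanged.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != right.shape:
        raise ValueError("left/right shapes differ (pair must be rectified and equal-size)")
    if max_disp >= left.shape[1]:
        raise ValueError("max_disp must be smaller than the image width")
    P1, P2 = penalties
    if not (0 < P1 < P2):
        raise ValueError("penalties must satisfy 0 < P1 < P2")

    cost_l = _cost_volume(left, right, max_disp, window)
    disp_l = _wta(aggregate_costs(cost_l, P1, P2)).astype(float)

    # right disparity from the same costs: C_R(x, d) = C_L(x + d, d)
    h, w, D = cost_l.shape
    cost_r = np.full_like(cost_l, (window * window - 1))
    for d in range(D):
        if d == 0:
            cost_r[:, :, 0] = cost_l[:, :, 0]
        else:
            cost_r[:, :-d, d] = cost_l[:, d:, d]
    disp_r = _wta(aggregate_costs(cost_r, P1, P2)).astype(float)

    # left-right consistency
    xs = np.arange(w)[None, :].repeat(h, axis=0)
    xr = np.clip((xs - disp_l).astype(int), 0, w - 1)
    ok = np.abs(disp_l - disp_r[np.arange(h)[:, None], xr]) <= lr_threshold
    out = np.where(ok, disp_l, 0.0)
    # a computed disparity of exactly 0 is indistinguishable from invalid; keep as invalid
    return DisparityMap(out, min_disparity=0.0, max_disparity=float(max_disp))
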