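"""Ground-truthed synthetic RGB-D scans of an animal-scale body.

The generator emulates a hand-held orbiting scan of a standing cow-sized
animal: a procedural quadruped mesh with cow-like intensity markings, a
circular-arc camera trajectory looking at the body, and a deterministic
perspective renderer producing registered gray + depth frames with
optional stereo-style depth noise, dropout, and saturated (overexposed)
patches.  Every artifact is a pure function of the scene spec and its
seed, so pipeline stages can be tested against exact ground truth.

Default geometry: 2.2 m body, 2.5 m orbit radius, 270 degree arc, 500
frames — a plausible walk-around scan of livestock with a stereo rig
(50 mm baseline).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from numba import njit
from skimage import measure

from .camera import PinholeIntrinsics, StereoRig
from .io import RGBDFrame, Trajectory
from .transforms import RigidTransform

__all__ = [
    "NoiseSpec",
    "SceneSpec",
    "default_intrinsics",
    "make_animal_mesh",
    "make_orbit_trajectory",
    "look_at_pose",
    "render_frame",
    "render_sequence",
    "make_stereo_pair",
]


def default_intrinsics(width: int = 160, height: int = 120) -> PinholeIntrinsics:
    """A 60-degree-horizontal-FOV pinhole camera at the requested resolution."""
    fx = width / (2 * np.tan(np.radians(30.0)))
    return PinholeIntrinsics(
        width=width, height=height, fx=fx, fy=fx, cx=(width - 1) / 2.0, cy=(height - 1) / 2.0
    )


@dataclass
class NoiseSpec:
    """Stereo-style depth degradation: sigma(d) = depth_sigma * (d / 1 m)^2."""

    depth_sigma: float = 0.002      # meters at 1 m
    dropout: float = 0.02           # fraction of valid pixels invalidated
    overexposure_rate: float = 0.5  # expected saturated patches per frame

    @classmethod
    def none(cls) -> "NoiseSpec":
        return cls(depth_sigma=0.0, dropout=0.0, overexposure_rate=0.0)


@dataclass
class SceneSpec:
    mesh: trimesh.Trimesh
    albedo: np.ndarray              # per-vertex intensity in [0, 1]
    trajectory: Trajectory
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0


# ------------------------------------------------------------------ mesh

def _superellipsoid(p, center, semi, exponent=2.5):
    semi = np.asarray(semi, dtype=float)
    q = np.abs((p - center) / semi) ** exponent
    return q.sum(axis=-1) ** (1.0 / exponent) - 1.0


def _ellipsoid(p, center, semi):
    q = ((p - center) / np.asarray(semi, dtype=float)) ** 2
    return np.sqrt(q.sum(axis=-1)) - 1.0


def _capsule(p, a, b, radius):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ab = b - a
    t = np.clip(((p - a) @ ab) / (ab @ ab), 0.0, 1.0)
    closest = a + t[..., None] * ab
    return np.linalg.norm(p - closest, axis=-1) - radius


def make_animal_mesh(size: float = 2.2, detail: int = 56, seed: int = 0):
    """Procedural quadruped: superellipsoid body, leg capsules, neck + head.

    The implicit union is polygonized by marching cubes (hence watertight and
    manifold by construction), lightly smoothed, and rescaled so the longest
    bounding-box axis equals ``size``.  Returns ``(mesh, albedo)`` where
    ``albedo`` is a per-vertex intensity field with smooth variation plus
    dark/light cow-like patches (texture signal for photometric alignment).
    """
    if size <= 0:
        raise ValueError("size must be positive")
    rng = np.random.default_rng(seed)

    # canonical animal ~2 units long, z up, standing on z=-1.05
    body_semi = np.array([1.0, 0.42, 0.48])
    head_c = np.array([1.05, 0.0, 0.45])
    head_semi = np.array([0.30, 0.22, 0.24])
    neck_a = np.array([0.75, 0.0, 0.25])
    leg_r = 0.11
    leg_tops = np.array(
        [[0.62, 0.26, -0.2], [0.62, -0.26, -0.2], [-0.62, 0.26, -0.2], [-0.62, -0.26, -0.2]]
    )
    leg_len = 0.85

    lo = np.array([-1.45, -0.85, -1.35])
    hi = np.array([1.6, 0.85, 0.95])
    n = int(detail)
    spacing = (hi - lo) / (n - 1)
    axes = [np.linspace(lo[i], hi[i], n) for i in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    P = np.stack([X, Y, Z], axis=-1)

    f = _superellipsoid(P, np.zeros(3), semi=body_semi)
    f = np.minimum(f, _ellipsoid(P, head_c, head_semi))
    f = np.minimum(f, _capsule(P, neck_a, head_c, 0.17))
    for top in leg_tops:
        bottom = top + np.array([0.0, 0.0, -leg_len])
        f = np.minimum(f, _capsule(P, top, bottom, leg_r))

    verts, faces, _, _ = measure.marching_cubes(f, level=0.0, spacing=tuple(spacing))
    verts = verts + lo
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    trimesh.smoothing.filter_taubin(mesh, lamb=0.5, nu=-0.53, iterations=8)

    extents = mesh.bounding_box.extents
    mesh.apply_scale(size / extents.max())
    mesh.fix_normals()

    # band-limited multi-octave texture + high-contrast patchy markings
    v = mesh.vertices
    albedo = np.full(len(v), 0.55)
    for freq_lo, freq_hi, amp in ((1.5, 4.0, 0.08), (4.0, 10.0, 0.06), (10.0, 22.0, 0.05)):
        for _ in range(4):
            freq = rng.uniform(freq_lo, freq_hi)
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            phase = rng.uniform(0, 2 * np.pi)
            albedo += amp * np.sin(freq * (v @ direction) / size * 2 * np.pi + phase)
    n_patches = 18
    centers = v[rng.integers(0, len(v), size=n_patches)]
    radii = rng.uniform(0.05, 0.18, size=n_patches) * size
    values = rng.choice([0.10, 0.95], size=n_patches)
    for c, r, val in zip(centers, radii, values):
        mask = np.linalg.norm(v - c, axis=1) < r
        albedo[mask] = val
    return mesh, np.clip(albedo, 0.02, 0.98)


# ------------------------------------------------------------------ trajectory

def look_at_pose(eye, target, up=(0.0, 0.0, 1.0)) -> RigidTransform:
    """Camera-to-world pose with +z optical axis through ``target``, image v downward."""
    eye = np.asarray(eye, dtype=float)
    z = np.asarray(target, dtype=float) - eye
    z = z / np.linalg.norm(z)
    x = np.cross(z, np.asarray(up, dtype=float))
    nx = np.linalg.norm(x)
    if nx < 1e-9:  # looking straight along up: pick an arbitrary right vector
        x = np.array([1.0, 0.0, 0.0])
        nx = 1.0
    x = x / nx
    y = np.cross(z, x)
    R = np.column_stack([x, y, z])
    return RigidTransform.from_rotation_translation(R, eye)


def make_orbit_trajectory(
    n_frames: int,
    radius: float = 2.5,
    arc: float = 270.0,
    height: float = 0.4,
    center=(0.0, 0.0, 0.0),
) -> Trajectory:
    """Poses on a circular arc around ``center``, optical axis through it.

    The angular step is exactly ``arc / (n_frames - 1)`` degrees, small enough
    for identity-initialized frame-to-frame odometry at the default counts.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    center = np.asarray(center, dtype=float)
    angles = np.radians(np.linspace(0.0, arc, n_frames))
    traj = Trajectory()
    for i, a in enumerate(angles):
        eye = center + np.array([radius * np.cos(a), radius * np.sin(a), height])
        traj.append(i, look_at_pose(eye, center))
    return traj


# ------------------------------------------------------------------ renderer

@njit(cache=True)
def _rasterize_kernel(uv, z, attr, H, W):  # pragma: no cover - jit
    depth = np.zeros((H, W))
    image = np.zeros((H, W))
    F = uv.shape[0]
    for fidx in range(F):
        u0, v0 = uv[fidx, 0, 0], uv[fidx, 0, 1]
        u1, v1 = uv[fidx, 1, 0], uv[fidx, 1, 1]
        u2, v2 = uv[fidx, 2, 0], uv[fidx, 2, 1]
        area = (u1 - u0) * (v2 - v0) - (v1 - v0) * (u2 - u0)
        if area == 0.0:
            continue
        xmin = max(int(np.floor(min(u0, min(u1, u2)))), 0)
        xmax = min(int(np.ceil(max(u0, max(u1, u2)))), W - 1)
        ymin = max(int(np.floor(min(v0, min(v1, v2)))), 0)
        ymax = min(int(np.ceil(max(v0, max(v1, v2)))), H - 1)
        if xmin > xmax or ymin > ymax:
            continue
        iz0 = 1.0 / z[fidx, 0]
        iz1 = 1.0 / z[fidx, 1]
        iz2 = 1.0 / z[fidx, 2]
        a0 = attr[fidx, 0] * iz0
        a1 = attr[fidx, 1] * iz1
        a2 = attr[fidx, 2] * iz2
        for py in range(ymin, ymax + 1):
            for px in range(xmin, xmax + 1):
                w0 = ((u1 - px) * (v2 - py) - (v1 - py) * (u2 - px)) / area
                w1 = ((u2 - px) * (v0 - py) - (v2 - py) * (u0 - px)) / area
                w2 = 1.0 - w0 - w1
                if w0 < 0.0 or w1 < 0.0 or w2 < 0.0:
                    continue
                inv_z = w0 * iz0 + w1 * iz1 + w2 * iz2
                pz = 1.0 / inv_z
                if depth[py, px] == 0.0 or pz < depth[py, px]:
                    depth[py, px] = pz
                    image[py, px] = (w0 * a0 + w1 * a1 + w2 * a2) * pz
    return depth, image


DEFAULT_LIGHT = (0.35, -0.45, 0.82)   # fixed world light, normalized at use


def render_frame(
    mesh: trimesh.Trimesh,
    albedo: np.ndarray,
    K: PinholeIntrinsics,
    pose: RigidTransform,
    near: float = 0.05,
    light_dir=DEFAULT_LIGHT,
):
    """Render exact depth and Lambertian gray for one camera pose.

    Illumination is a fixed directional world light plus ambient, as in a
    statically lit barn: the shading is attached to the surface, not the
    camera, so Lambertian intensity is view-independent (the photometric-
    constancy assumption dense alignment relies on).  Returns
    ``(gray, depth)``; background pixels carry gray 0, depth 0.  Purely
    deterministic: a perspective-correct z-buffer over the mesh triangles
    with Gouraud-interpolated shaded intensity.
    """
    world_to_cam = pose.invert()
    v_cam = world_to_cam.apply(mesh.vertices)

    light = np.asarray(light_dir, dtype=float)
    light = light / np.linalg.norm(light)
    lambert = np.clip(mesh.vertex_normals @ light, 0.0, 1.0)
    shaded = np.clip(albedo * (0.35 + 0.65 * lambert), 0.0, 1.0)

    faces = mesh.faces
    tri_z = v_cam[faces][:, :, 2]
    front = np.all(tri_z > near, axis=1)
    # backface cull on outward normals
    centroids = v_cam[faces].mean(axis=1)
    fn_cam = mesh.face_normals @ world_to_cam.rotation.T
    visible = front & (np.einsum("fi,fi->f", fn_cam, centroids) < 0)
    faces = faces[visible]
    if faces.shape[0] == 0:
        z = np.zeros((K.height, K.width))
        return z.copy(), z

    tv = v_cam[faces]                      # (F, 3, 3)
    uz = tv[:, :, 2]
    uu = tv[:, :, 0] * K.fx / uz + K.cx
    vv = tv[:, :, 1] * K.fy / uz + K.cy
    uvs = np.stack([uu, vv], axis=-1)
    attrs = shaded[faces]
    depth, gray = _rasterize_kernel(
        np.ascontiguousarray(uvs),
        np.ascontiguousarray(uz),
        np.ascontiguousarray(attrs),
        K.height,
        K.width,
    )
    return gray, depth


def _apply_noise(gray, depth, noise: NoiseSpec, rng: np.random.Generator):
    depth = depth.copy()
    gray = gray.copy()
    valid = depth > 0
    if noise.depth_sigma > 0 and np.any(valid):
        sigma = noise.depth_sigma * depth[valid] ** 2
        depth[valid] = np.maximum(depth[valid] + rng.normal(0.0, 1.0, sigma.shape) * sigma, 0.0)
    if noise.dropout > 0 and np.any(valid):
        drop = rng.random(depth.shape) < noise.dropout
        depth[drop & valid] = 0.0
    if noise.overexposure_rate > 0:
        n_patches = rng.poisson(noise.overexposure_rate)
        h, w = gray.shape
        for _ in range(n_patches):
            cy, cx = rng.uniform(0, h), rng.uniform(0, w)
            ry, rx = rng.uniform(h * 0.03, h * 0.12), rng.uniform(w * 0.03, w * 0.12)
            yy, xx = np.mgrid[0:h, 0:w]
            patch = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
            gray[patch] = 1.0
    return gray, depth


def render_sequence(spec: SceneSpec, K: PinholeIntrinsics):
    """Render every trajectory pose; returns ``(frames, ground_truth_trajectory)``.

    Noise is seeded from ``spec.seed`` so two calls with the same spec are
    bit-identical.  A pose from which the mesh is invisible yields an empty
    frame and a warning entry in the returned trajectory is NOT made — the
    pose list is the ground truth regardless.
    """
    import warnings

    rng = np.random.default_rng(spec.seed)
    frames = []
    for idx, pose in spec.trajectory:
        gray, depth = render_frame(spec.mesh, spec.albedo, K, pose)
        if not np.any(depth > 0):
            warnings.warn(f"mesh not visible from pose {idx}")
        gray, depth = _apply_noise(gray, depth, spec.noise, rng)
        frames.append(RGBDFrame(gray, depth, timestamp_index=idx))
    return frames, spec.trajectory


def make_stereo_pair(spec: SceneSpec, rig: StereoRig, pose: RigidTransform):
    """Left/right gray renders plus the exact ground-truth disparity of the left.

    The right camera is the left displaced by the baseline along +x (camera
    frame); ground-truth disparity is ``B * fx / depth`` on valid pixels and
    0 on background.
    """
    from .stereo import DisparityMap

    K = rig.intrinsics
    left_gray, left_depth = render_frame(spec.mesh, spec.albedo, K, pose)
    shift = RigidTransform.from_rotation_translation(np.eye(3), (rig.baseline, 0.0, 0.0))
    right_pose = pose @ shift
    right_gray, _ = render_frame(spec.mesh, spec.albedo, K, right_pose)
    disparity = np.zeros_like(left_depth)
    valid = left_depth > 0
    disparity[valid] = rig.baseline * K.fx / left_depth[valid]
    return left_gray, right_gray, DisparityMap(disparity, 0.0, float(disparity.max(initial=0.0)))
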