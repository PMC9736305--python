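"""On-disk artifact I/O.

Conventions (all documented in the README):

* depth: 16-bit single-channel PNG, ``counts = depth_m * depth_scale``
  (default scale 1000 counts/m, i.e. millimeter resolution); count 0 is
  the invalid sentinel and round-trips as depth 0.0.
* gray: 8-bit single-channel PNG, intensity mapped linearly to [0, 1].
* intrinsics: JSON with explicit field names (optionally ``baseline``).
* trajectories: TUM text lines ``idx tx ty tz qx qy qz qw``.
* point clouds / meshes: PLY via trimesh (binary by default, ASCII on request).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import trimesh

from .camera import PinholeIntrinsics
from .pointcloud import PointCloud
from .transforms import RigidTransform

__all__ = [
    "RGBDFrame",
    "Trajectory",
    "DEFAULT_DEPTH_SCALE",
    "read_depth_png",
    "write_depth_png",
    "read_gray_png",
    "write_gray_png",
    "read_trajectory",
    "write_trajectory",
    "write_trajectory_log",
    "load_rgbd_sequence",
    "save_rgbd_sequence",
    "read_pointcloud_ply",
    "write_pointcloud_ply",
    "read_mesh_ply",
    "write_mesh_ply",
]

DEFAULT_DEPTH_SCALE = 1000.0  # counts per meter (mm resolution)


class FormatError(ValueError):
    """A file exists but is not in the expected format."""


@dataclass
class RGBDFrame:
    """A registered intensity + depth image pair sharing one camera frame."""

    gray: np.ndarray        # (H, W) float in [0, 1]
    depth: np.ndarray       # (H, W) float meters, 0 = invalid
    timestamp_index: int = 0

    def __post_init__(self):
        self.gray = np.asarray(self.gray, dtype=float)
        self.depth = np.asarray(self.depth, dtype=float)
        if self.gray.shape != self.depth.shape:
            raise ValueError(
                f"gray {self.gray.shape} and depth {self.depth.shape} shapes differ"
            )
        if not (np.all(np.isfinite(self.gray)) and np.all(np.isfinite(self.depth))):
            raise ValueError("frame contains non-finite values")
        if np.any(self.depth < 0):
            raise ValueError("depth values must be >= 0 (0 marks invalid)")

    @property
    def shape(self):
        return self.gray.shape


class Trajectory:
    """Ordered camera-to-world poses keyed by strictly increasing frame index."""

    def __init__(self, entries=()):
        self.indices: list[int] = []
        self.poses: list[RigidTransform] = []
        for idx, pose in entries:
            self.append(idx, pose)

    def append(self, index: int, pose: RigidTransform) -> None:
        if self.indices and index <= self.indices[-1]:
            raise ValueError("frame indices must be strictly increasing")
        self.indices.append(int(index))
        self.poses.append(pose)

    def __len__(self) -> int:
        return len(self.indices)

    def __iter__(self):
        return iter(zip(self.indices, self.poses))

    def __getitem__(self, i: int):
        return self.indices[i], self.poses[i]

    def pose_of(self, index: int) -> RigidTransform:
        return self.poses[self.indices.index(index)]


# ---------------------------------------------------------------- images

def read_depth_png(path, depth_scale: float = DEFAULT_DEPTH_SCALE) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = iio.imread(path)
    if arr.dtype != np.uint16 or arr.ndim != 2:
        raise FormatError(
            f"{path}: expected a 16-bit single-channel PNG, got dtype={arr.dtype} ndim={arr.ndim}"
        )
    return arr.astype(float) / depth_scale


def write_depth_png(depth: np.ndarray, path, depth_scale: float = DEFAULT_DEPTH_SCALE) -> None:
    depth = np.asarray(depth, dtype=float)
    max_depth = 65535.0 / depth_scale
    if np.any(depth < 0) or np.any(depth > max_depth):
        raise ValueError(f"depth outside representable range [0, {max_depth:.3f}] m")
    counts = np.round(depth * depth_scale).astype(np.uint16)
    iio.imwrite(Path(path), counts)


def read_gray_png(path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = iio.imread(path)
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected a single-channel gray PNG")
    return arr.astype(float) / np.iinfo(arr.dtype).max

def write_gray_png(gray: np.ndarray, path) -> None:
    g = np.clip(np.asarray(gray, dtype=float), 0.0, 1.0)
    iio.imwrite(Path(path), np.round(g * 255).astype(np.uint8))


# ---------------------------------------------------------------- trajectories

def read_trajectory(path) -> Trajectory:
    traj = Trajectory()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 8:
                raise FormatError(f"{path}:{lineno}: expected 8 fields, got {len(parts)}")
            idx = int(float(parts[0]))
            tx, ty, tz, qx, qy, qz, qw = map(float, parts[1:])
            qn = np.sqrt(qx * qx + qy * qy + qz * qz + qw * qw)
            if abs(qn - 1.0) > 1e-6:
                raise FormatError(
                    f"{path}:{lineno}: quaternion norm {qn:.8f} deviates from 1 beyond 1e-6"
                )
            traj.append(idx, RigidTransform.from_quaternion(qx, qy, qz, qw, (tx, ty, tz)))
    return traj


def write_trajectory(traj: Trajectory, path) -> None:
    with open(path, "w") as fh:
        for idx, pose in traj:
            t = pose.translation
            qx, qy, qz, qw = pose.to_quaternion()
            fh.write(
                f"{idx} {t[0]:.12g} {t[1]:.12g} {t[2]:.12g} "
                f"{qx:.12g} {qy:.12g} {qz:.12g} {qw:.12g}\n"
            )


def write_trajectory_log(traj: Trajectory, path) -> None:
    """Redwood ``.log`` export (secondary format): per-pose 4x4 matrix blocks."""
    with open(path, "w") as fh:
        for idx, pose in traj:
            fh.write(f"{idx} {idx} {idx + 1}\n")
            for row in pose.matrix:
                fh.write(" ".join(f"{v:.12g}" for v in row) + "\n")


# ---------------------------------------------------------------- sequences

_GRAY_RE = re.compile(r"^gray_(\d+)\.png$")
_DEPTH_RE = re.compile(r"^depth_(\d+)\.png$")


def save_rgbd_sequence(
    frames, directory, intrinsics: PinholeIntrinsics, depth_scale: float = DEFAULT_DEPTH_SCALE
) -> None:
    """Write ``gray_%06d.png`` / ``depth_%06d.png`` pairs plus ``intrinsics.json``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    intrinsics.save_json(directory / "intrinsics.json")
    for frame in frames:
        i = frame.timestamp_index
        write_gray_png(frame.gray, directory / f"gray_{i:06d}.png")
        write_depth_png(frame.depth, directory / f"depth_{i:06d}.png", depth_scale)


def load_rgbd_sequence(
    directory,
    intrinsics_path=None,
    depth_scale: float = DEFAULT_DEPTH_SCALE,
):
    """Load a frame directory; returns ``(frames, intrinsics)``.

    Frames are ordered by their numeric index and validated against the
    intrinsics' image size; an unpaired or mis-shaped file is an error.
    """
    directory = Path(directory)
    if intrinsics_path is None:
        intrinsics_path = directory / "intrinsics.json"
    K = PinholeIntrinsics.load_json(intrinsics_path)
    grays, depths = {}, {}
    for p in directory.iterdir():
        m = _GRAY_RE.match(p.name)
        if m:
            grays[int(m.group(1))] = p
            continue
        m = _DEPTH_RE.match(p.name)
        if m:
            depths[int(m.group(1))] = p
    if set(grays) != set(depths):
        odd = sorted(set(grays).symmetric_difference(depths))
        raise FormatError(f"{directory}: unpaired gray/depth indices {odd[:10]}")
    frames = []
    for idx in sorted(grays):
        gray = read_gray_png(grays[idx])
        depth = read_depth_png(depths[idx], depth_scale)
        if gray.shape != depth.shape:
            raise FormatError(f"frame {idx}: gray {gray.shape} vs depth {depth.shape}")
        if gray.shape != (K.height, K.width):
            raise FormatError(
                f"frame {idx}: image {gray.shape} does not match intrinsics "
                f"({K.height}, {K.width})"
            )
        frames.append(RGBDFrame(gray, depth, timestamp_index=idx))
    return frames, K


# ---------------------------------------------------------------- PLY

def write_pointcloud_ply(pc: PointCloud, path, ascii: bool = False) -> None:
    cloud = trimesh.PointCloud(pc.points)
    if pc.intensity is not None:
        g = np.clip(np.round(pc.intensity * 255), 0, 255).astype(np.uint8)
        cloud.colors = np.column_stack([g, g, g, np.full_like(g, 255)])
    data = cloud.export(file_type="ply", encoding="ascii" if ascii else "binary")
    mode = "w" if isinstance(data, str) else "wb"
    with open(path, mode) as fh:
        fh.write(data)
    if pc.normals is not None:
        # trimesh PointCloud drops normals; sidecar keeps them lossless
        np.savetxt(str(path) + ".normals.txt", pc.normals, fmt="%.9g")


def read_pointcloud_ply(path) -> PointCloud:
    loaded = trimesh.load(str(path), process=False)
    pts = np.asarray(loaded.vertices, dtype=float)
    intensity = None
    colors = getattr(loaded, "colors", None)
    if colors is not None and len(colors):
        intensity = np.asarray(colors, dtype=float)[:, 0] / 255.0
    normals = None
    sidecar = Path(str(path) + ".normals.txt")
    if sidecar.exists():
        normals = np.loadtxt(sidecar).reshape(-1, 3)
        normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    return PointCloud(pts, normals=normals, intensity=intensity)


def write_mesh_ply(mesh: trimesh.Trimesh, path, ascii: bool = False) -> None:
    data = mesh.export(file_type="ply", encoding="ascii" if ascii else "binary")
    mode = "w" if isinstance(data, str) else "wb"
    with open(path, mode) as fh:
        fh.write(data)


def read_mesh_ply(path) -> trimesh.Trimesh:
    mesh = trimesh.load(str(path), process=False)
    if not isinstance(mesh, trimesh.Trimesh):
        raise FormatError(f"{path}: not a triangle mesh")
    return mesh
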