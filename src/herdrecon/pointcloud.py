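"""Point clouds, normal estimation and registration quality metrics.

The :class:`PointCloud` container holds metric 3D points with optional
unit normals and per-point scalar intensity in [0, 1] (the gray value the
point was observed with).  Registration quality follows the usual
convention: *fitness* is the fraction of source points whose nearest
target neighbor (after applying the candidate transform) lies within a
distance threshold, and *inlier RMSE* is the RMSE of those inlier
distances — higher fitness and lower RMSE mean a tighter alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .camera import PinholeIntrinsics
from .transforms import RigidTransform

__all__ = [
    "PointCloud",
    "CorrespondenceSet",
    "RegistrationResult",
    "depth_to_pointcloud",
    "estimate_normals",
    "evaluate_registration",
    "voxel_downsample",
]


@dataclass
class PointCloud:
    points: np.ndarray                      # (N, 3) meters
    normals: np.ndarray | None = None       # (N, 3) unit vectors
    intensity: np.ndarray | None = None     # (N,) in [0, 1]

    def __post_init__(self):
        self.points = np.ascontiguousarray(self.points, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.points)):
            raise ValueError("point cloud contains non-finite coordinates")
        if self.normals is not None:
            self.normals = np.ascontiguousarray(self.normals, dtype=float).reshape(-1, 3)
            if self.normals.shape[0] != self.points.shape[0]:
                raise ValueError("normals/points length mismatch")
            norms = np.linalg.norm(self.normals, axis=1)
            good = norms > 0
            if not np.allclose(norms[good], 1.0, atol=1e-6):
                raise ValueError("normals must be unit length (tolerance 1e-6)")
        if self.intensity is not None:
            self.intensity = np.ascontiguousarray(self.intensity, dtype=float).reshape(-1)
            if self.intensity.shape[0] != self.points.shape[0]:
                raise ValueError("intensity/points length mismatch")

    def __len__(self) -> int:
        return self.points.shape[0]

    def transformed(self, T: RigidTransform) -> "PointCloud":
        normals = None
        if self.normals is not None:
            normals = self.normals @ T.rotation.T
        return PointCloud(
            T.apply(self.points),
            normals=normals,
            intensity=None if self.intensity is None else self.intensity.copy(),
        )

    def select(self, idx) -> "PointCloud":
        return PointCloud(
            self.points[idx],
            normals=None if self.normals is None else self.normals[idx],
            intensity=None if self.intensity is None else self.intensity[idx],
        )

    def kdtree(self) -> cKDTree:
        return cKDTree(self.points)


@dataclass
class CorrespondenceSet:
    """Index pairs (i into target P, j into source Q) plus the distance gate used."""

    pairs: np.ndarray                       # (M, 2) int
    max_distance: float = np.inf

    def __post_init__(self):
        self.pairs = np.ascontiguousarray(self.pairs, dtype=int).reshape(-1, 2)
        if self.pairs.shape[0]:
            uniq = np.unique(self.pairs, axis=0)
            if uniq.shape[0] != self.pairs.shape[0]:
                raise ValueError("duplicate correspondence pairs")

    def __len__(self) -> int:
        return self.pairs.shape[0]

    @property
    def target_indices(self) -> np.ndarray:
        return self.pairs[:, 0]

    @property
    def source_indices(self) -> np.ndarray:
        return self.pairs[:, 1]


@dataclass
class RegistrationResult:
    transform: RigidTransform
    fitness: float
    inlier_rmse: float
    correspondences: CorrespondenceSet | None = None
    converged: bool = True
    iterations: int = 0
    message: str = ""
    rmse_history: list = field(default_factory=list)   # per-iteration correspondence RMSE

    def __post_init__(self):
        if not (0.0 <= self.fitness <= 1.0):
            raise ValueError("fitness must lie in [0, 1]")
        if self.inlier_rmse < 0:
            raise ValueError("inlier_rmse must be non-negative")


def depth_to_pointcloud(frame, K: PinholeIntrinsics, stride: int = 1) -> PointCloud:
    """Unproject every valid depth pixel on the stride grid; intensity from gray."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    depth = frame.depth[::stride, ::stride]
    gray = frame.gray[::stride, ::stride]
    vv, uu = np.mgrid[0 : frame.depth.shape[0] : stride, 0 : frame.depth.shape[1] : stride]
    valid = depth > 0
    if not np.any(valid):
        return PointCloud(np.empty((0, 3)), intensity=np.empty(0))
    u = uu[valid].astype(float)
    v = vv[valid].astype(float)
    d = depth[valid]
    x = (u - K.cx) * d / K.fx
    y = (v - K.cy) * d / K.fy
    pts = np.column_stack([x, y, d])
    return PointCloud(pts, intensity=gray[valid].astype(float))


def estimate_normals(
    pc: PointCloud, k_neighbors: int = 20, viewpoint=(0.0, 0.0, 0.0)
) -> PointCloud:
    """PCA normals from the k nearest neighbors, oriented toward ``viewpoint``.

    The normal is the eigenvector of the local covariance with the smallest
    eigenvalue; its sign is flipped so it points at the observing camera.
    """
    n = len(pc)
    if k_neighbors < 3:
        raise ValueError("k_neighbors must be >= 3")
    if n < k_neighbors:
        raise ValueError(f"cloud has {n} points, fewer than k_neighbors={k_neighbors}")
    tree = pc.kdtree()
    _, idx = tree.query(pc.points, k=k_neighbors)
    neigh = pc.points[idx]                              # (N, k, 3)
    centered = neigh - neigh.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centered, centered) / k_neighbors
    eigvals, eigvecs = np.linalg.eigh(cov)              # ascending
    normals = eigvecs[:, :, 0]
    to_view = np.asarray(viewpoint, dtype=float) - pc.points
    flip = np.einsum("ni,ni->n", normals, to_view) < 0
    normals[flip] = -normals[flip]
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    return PointCloud(pc.points.copy(), normals=normals, intensity=pc.intensity)


def evaluate_registration(
    source: PointCloud,
    target: PointCloud,
    T: RigidTransform,
    max_dist: float,
) -> RegistrationResult:
    """Fitness / inlier-RMSE of aligning ``source`` onto ``target`` with ``T``."""
    if max_dist <= 0:
        raise ValueError("max_dist must be positive")
    if len(source) == 0 or len(target) == 0:
        raise ValueError("cannot evaluate registration with an empty cloud")
    moved = T.apply(source.points)
    dist, idx = target.kdtree().query(moved)
    inlier = dist <= max_dist
    fitness = float(np.count_nonzero(inlier)) / len(source)
    rmse = float(np.sqrt(np.mean(dist[inlier] ** 2))) if np.any(inlier) else 0.0
    pairs = np.column_stack([idx[inlier], np.flatnonzero(inlier)])
    return RegistrationResult(
        transform=T,
        fitness=fitness,
        inlier_rmse=rmse,
        correspondences=CorrespondenceSet(pairs, max_distance=max_dist),
    )


def voxel_downsample(pc: PointCloud, voxel_size: float) -> PointCloud:
    """Average points (and attributes) falling in each voxel of an axis-aligned grid."""
    if voxel_size <= 0:
        raise ValueError("voxel_size must be positive")
    if len(pc) == 0:
        return pc
    keys = np.floor(pc.points / voxel_size).astype(np.int64)
    # lexicographic voxel id -> group by sorting (deterministic)
    order = np.lexsort((keys[:, 2], keys[:, 1], keys[:, 0]))
    keys_sorted = keys[order]
    boundaries = np.any(np.diff(keys_sorted, axis=0) != 0, axis=1)
    group_ids = np.concatenate([[0], np.cumsum(boundaries)])
    n_groups = group_ids[-1] + 1
    counts = np.bincount(group_ids, minlength=n_groups).astype(float)

    def _mean(values):
        if values.ndim == 1:
            return np.bincount(group_ids, weights=values[order], minlength=n_groups) / counts
        out = np.empty((n_groups, values.shape[1]))
        for c in range(values.shape[1]):
            out[:, c] = (
                np.bincount(group_ids, weights=values[order, c], minlength=n_groups) / counts
            )
        return out

    points = _mean(pc.points)
    normals = None
    if pc.normals is not None:
        normals = _mean(pc.normals)
        norms = np.linalg.norm(normals, axis=1)
        norms[norms == 0] = 1.0
        normals = normals / norms[:, None]
    intensity = None if pc.intensity is None else _mean(pc.intensity)
    return PointCloud(points, normals=normals, intensity=intensity)
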