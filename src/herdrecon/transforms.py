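"""Rigid-body (SE(3)) transforms and the axis-angle exponential map.

Poses and relative motions throughout the package are 4x4 homogeneous
matrices wrapped in :class:`RigidTransform`.  Optimizers parameterize
increments as 6-vectors ``xi = (omega, t)`` (rotation axis-angle, then
translation) applied on the left: ``T <- exp(xi) @ T``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "RigidTransform",
    "so3_exp",
    "so3_log",
    "se3_exp",
    "se3_log",
    "rotation_angle",
]

_EPS = 1e-12


class RigidTransform:
    """An element of SE(3): rotation ``R`` plus translation ``t``.

    Parameters
    ----------
    matrix : (4, 4) array_like, optional
        Homogeneous matrix.  Defaults to the identity.  The rotation block
        must be orthonormal with determinant +1 (validated to 1e-9 by
        default) and the last row must be (0, 0, 0, 1).
    """

    __slots__ = ("matrix",)

    def __init__(self, matrix=None, *, validate: bool = True, tol: float = 1e-9):
        if matrix is None:
            self.matrix = np.eye(4)
            return
        M = np.asarray(matrix, dtype=float)
        if M.shape != (4, 4):
            raise ValueError(f"expected a 4x4 matrix, got shape {M.shape}")
        if validate:
            R = M[:3, :3]
            if not np.allclose(R.T @ R, np.eye(3), atol=max(tol, 1e-9) * 10):
                raise ValueError("rotation block is not orthonormal")
            if not np.isclose(np.linalg.det(R), 1.0, atol=max(tol, 1e-9) * 10):
                raise ValueError("rotation block has det != +1 (reflection?)")
            if not np.allclose(M[3], (0.0, 0.0, 0.0, 1.0), atol=1e-12):
                raise ValueError("last row must be (0, 0, 0, 1)")
        self.matrix = M

    # -- constructors -------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_rotation_translation(cls, R, t) -> "RigidTransform":
        M = np.eye(4)
        M[:3, :3] = np.asarray(R, dtype=float)
        M[:3, 3] = np.asarray(t, dtype=float)
        return cls(M)

    @classmethod
    def from_quaternion(cls, qx, qy, qz, qw, t=(0.0, 0.0, 0.0)) -> "RigidTransform":
        """Build from a unit quaternion (x, y, z, w order) and translation."""
        q = np.array([qx, qy, qz, qw], dtype=float)
        n = np.linalg.norm(q)
        if abs(n - 1.0) > 1e-6:
            raise ValueError(f"quaternion norm {n:.3e} deviates from 1 beyond 1e-6")
        x, y, z, w = q / n
        R = np.array(
            [
                [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
                [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
                [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
            ]
        )
        return cls.from_rotation_translation(R, t)

    # -- accessors ----------------------------------------------------
    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    def to_quaternion(self):
        """Return (qx, qy, qz, qw) with qw >= 0."""
        R = self.rotation
        tr = np.trace(R)
        if tr > 0:
            s = np.sqrt(tr + 1.0) * 2
            w = 0.25 * s
            x = (R[2, 1] - R[1, 2]) / s
            y = (R[0, 2] - R[2, 0]) / s
            z = (R[1, 0] - R[0, 1]) / s
        else:
            i = int(np.argmax(np.diag(R)))
            j, k = (i + 1) % 3, (i + 2) % 3
            s = np.sqrt(max(R[i, i] - R[j, j] - R[k, k] + 1.0, 0.0)) * 2
            q = np.empty(4)
            q[i] = 0.25 * s
            q[3] = (R[k, j] - R[j, k]) / s
            q[j] = (R[j, i] + R[i, j]) / s
            q[k] = (R[k, i] + R[i, k]) / s
            x, y, z, w = q
        q = np.array([x, y, z, w])
        if q[3] < 0:
            q = -q
        return q / np.linalg.norm(q)

    # -- algebra ------------------------------------------------------
    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self @ other (apply ``other`` first)."""
        return RigidTransform(self.matrix @ other.matrix, validate=False)

    def invert(self) -> "RigidTransform":
        R = self.rotation
        t = self.translation
        M = np.eye(4)
        M[:3, :3] = R.T
        M[:3, 3] = -R.T @ t
        return RigidTransform(M, validate=False)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (N, 3) array of points (or a single 3-vector)."""
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        pts = np.atleast_2d(pts)
        out = pts @ self.rotation.T + self.translation
        return out[0] if single else out

    def __matmul__(self, other):
        if isinstance(other, RigidTransform):
            return self.compose(other)
        return NotImplemented

    def almost_equal(self, other: "RigidTransform", rot_tol_deg=1e-6, trans_tol=1e-9):
        dR = rotation_angle(self.rotation.T @ other.rotation)
        dt = np.linalg.norm(self.translation - other.translation)
        return np.degrees(dR) <= rot_tol_deg and dt <= trans_tol

    def __repr__(self):
        t = self.translation
        return (
            f"RigidTransform(angle={np.degrees(rotation_angle(self.rotation)):.3f} deg, "
            f"t=[{t[0]:.4f}, {t[1]:.4f}, {t[2]:.4f}])"
        )


def _hat(w: np.ndarray) -> np.ndarray:
    return np.array(
        [[0, -w[2], w[1]], [w[2], 0, -w[0]], [-w[1], w[0], 0]], dtype=float
    )


def so3_exp(omega) -> np.ndarray:
    """Rodrigues' formula; small-angle safe."""
    w = np.asarray(omega, dtype=float)
    theta = np.linalg.norm(w)
    W = _hat(w)
    if theta < 1e-8:
        # second-order series keeps orthonormality to machine precision here
        return np.eye(3) + W + 0.5 * (W @ W)
    A = np.sin(theta) / theta
    B = (1 - np.cos(theta)) / theta**2
    return np.eye(3) + A * W + B * (W @ W)


def so3_log(R: np.ndarray) -> np.ndarray:
    """Inverse of :func:`so3_exp` (angle in [0, pi])."""
    cos_theta = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    theta = np.arccos(cos_theta)
    if theta < 1e-8:
        return np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]]) / 2.0
    if np.pi - theta < 1e-6:
        # near pi the axis comes from the symmetric part
        S = (R + np.eye(3)) / 2.0
        axis = np.sqrt(np.maximum(np.diag(S), 0.0))
        # fix signs from off-diagonals
        i = int(np.argmax(axis))
        if axis[i] > 0:
            axis = axis.copy()
            for j in range(3):
                if j != i and S[i, j] < 0:
                    axis[j] = -axis[j]
        axis = axis / max(np.linalg.norm(axis), _EPS)
        return theta * axis
    v = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    return theta / (2 * np.sin(theta)) * v


def se3_exp(xi) -> RigidTransform:
    """Exponential map R^6 -> SE(3), ``xi = (omega, t_param)``."""
    xi = np.asarray(xi, dtype=float)
    w, u = xi[:3], xi[3:]
    theta = np.linalg.norm(w)
    R = so3_exp(w)
    W = _hat(w)
    if theta < 1e-8:
        V = np.eye(3) + 0.5 * W + (W @ W) / 6.0
    else:
        A = (1 - np.cos(theta)) / theta**2
        B = (theta - np.sin(theta)) / theta**3
        V = np.eye(3) + A * W + B * (W @ W)
    return RigidTransform.from_rotation_translation(R, V @ u)


def se3_log(T: RigidTransform) -> np.ndarray:
    """Inverse of :func:`se3_exp`."""
    w = so3_log(T.rotation)
    theta = np.linalg.norm(w)
    W = _hat(w)
    if theta < 1e-8:
        Vinv = np.eye(3) - 0.5 * W + (W @ W) / 12.0
    else:
        half = theta / 2.0
        cot = 1.0 / np.tan(half)
        Vinv = (
            np.eye(3)
            - 0.5 * W
            + (1.0 / theta**2) * (1 - half * cot) * (W @ W)
        )
    return np.concatenate([w, Vinv @ T.translation])


def rotation_angle(R: np.ndarray) -> float:
    """Geodesic angle of a rotation matrix, radians in [0, pi]."""
    return float(np.arccos(np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)))
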