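"""Pinhole camera model: intrinsics, projection and unprojection.

Pixel coordinates are 0-based with ``(u, v) = (column, row)``; a depth
pixel ``(u, v, d)`` unprojects to the homogeneous camera-space point

    h(u, v, d) = ((u - cx) d / fx, (v - cy) d / fy, d, 1)

and projection ``g`` is its inverse, mapping a frontal 3D point back to
``(u, v, d)``.  Depth is metric; 0 marks an invalid pixel everywhere in
the package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = ["PinholeIntrinsics", "StereoRig", "unproject", "project"]


@dataclass(frozen=True)
class PinholeIntrinsics:
    width: int
    height: int
    fx: float
    fy: float
    cx: float
    cy: float

    def __post_init__(self):
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        if not (0 <= self.cx < self.width):
            raise ValueError(f"cx={self.cx} outside [0, {self.width})")
        if not (0 <= self.cy < self.height):
            raise ValueError(f"cy={self.cy} outside [0, {self.height})")

    def scaled(self, factor: float) -> "PinholeIntrinsics":
        """Intrinsics for an image resized by ``factor`` (e.g. 0.5 per pyramid level)."""
        return PinholeIntrinsics(
            width=int(round(self.width * factor)),
            height=int(round(self.height * factor)),
            fx=self.fx * factor,
            fy=self.fy * factor,
            cx=self.cx * factor,
            cy=self.cy * factor,
        )

    def to_dict(self) -> dict:
        return {
            "width": self.width,
            "height": self.height,
            "fx": self.fx,
            "fy": self.fy,
            "cx": self.cx,
            "cy": self.cy,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PinholeIntrinsics":
        return cls(
            width=int(d["width"]),
            height=int(d["height"]),
            fx=float(d["fx"]),
            fy=float(d["fy"]),
            cx=float(d["cx"]),
            cy=float(d["cy"]),
        )

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    @classmethod
    def load_json(cls, path) -> "PinholeIntrinsics":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class StereoRig:
    """A rectified stereo pair: shared intrinsics plus baseline in meters."""

    intrinsics: PinholeIntrinsics
    baseline: float

    def __post_init__(self):
        if self.baseline <= 0:
            raise ValueError("stereo baseline must be positive")

    def to_dict(self) -> dict:
        d = self.intrinsics.to_dict()
        d["baseline"] = self.baseline
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StereoRig":
        return cls(PinholeIntrinsics.from_dict(d), float(d["baseline"]))


def unproject(u, v, d, K: PinholeIntrinsics) -> np.ndarray:
    """Depth pixel(s) -> homogeneous camera-space point(s).

    Accepts scalars or broadcastable arrays; returns shape (..., 4).
    Raises on non-positive depth.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("unproject requires positive depth (0 marks invalid pixels)")
    x = (u - K.cx) * d / K.fx
    y = (v - K.cy) * d / K.fy
    return np.stack(np.broadcast_arrays(x, y, d, np.ones_like(d)), axis=-1)


def project(s, K: PinholeIntrinsics):
    """3D point(s) -> (u, v, d).  Accepts (..., 3) or (..., 4) homogeneous."""
    s = np.asarray(s, dtype=float)
    x, y, z = s[..., 0], s[..., 1], s[..., 2]
    if np.any(z <= 0):
        raise ValueError("project requires points in front of the camera (z > 0)")
    u = x * K.fx / z + K.cx
    v = y * K.fy / z + K.cy
    return u, v, z
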