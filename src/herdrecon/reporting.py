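"""Quantitative evaluation: registration quality, trajectory error, surface error.

Mirrors the usual registration-benchmark triple (fitness / inlier RMSE /
wall time) per method, plus absolute trajectory error against a
ground-truth trajectory and vertex-to-surface error percentiles against a
ground-truth mesh.  Wall times are reported but never asserted on.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field

import numpy as np

from .io import Trajectory
from .meshdist import point_mesh_distance
from .global_registration import rigid_fit

__all__ = [
    "EvaluationReport",
    "gauge_alignment",
    "trajectory_ate",
    "surface_error",
    "compare_methods",
]


@dataclass
class EvaluationReport:
    rows: list = field(default_factory=list)    # dicts: method, fitness, inlier_rmse, time_s, ...
    ate: float | None = None
    surface_percentiles: dict | None = None
    config: dict = field(default_factory=dict)
    seeds: list = field(default_factory=list)

    def add_row(self, method: str, **metrics) -> None:
        self.rows.append({"method": method, **metrics})

    def to_dict(self) -> dict:
        return {
            "rows": self.rows,
            "ate": self.ate,
            "surface_percentiles": self.surface_percentiles,
            "config": self.config,
            "seeds": self.seeds,
        }

    def to_json(self, indent=2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True, default=float)

    def to_markdown(self) -> str:
        if not self.rows:
            return "(empty report)"
        keys = ["method", "fitness", "inlier_rmse", "time_s"]
        extra = [k for k in self.rows[0] if k not in keys]
        keys += extra
        lines = ["| " + " | ".join(keys) + " |", "|" + "---|" * len(keys)]
        for row in self.rows:
            cells = []
            for k in keys:
                v = row.get(k, "")
                cells.append(f"{v:.6g}" if isinstance(v, float) else str(v))
            lines.append("| " + " | ".join(cells) + " |")
        return "\n".join(lines)


def gauge_alignment(estimated: Trajectory, truth: Trajectory):
    """Closed-form rigid transform mapping the estimated trajectory's frame
    onto the truth frame (the unobservable global gauge)."""
    if list(estimated.indices) != list(truth.indices):
        raise ValueError("trajectories cover different frame indices")
    p_est = np.array([pose.translation for _, pose in estimated])
    p_true = np.array([pose.translation for _, pose in truth])
    if len(p_est) >= 3 and not _is_degenerate(p_true):
        return rigid_fit(p_true, p_est)
    from .transforms import RigidTransform

    return RigidTransform.from_rotation_translation(
        np.eye(3), p_true.mean(axis=0) - p_est.mean(axis=0)
    )


def trajectory_ate(estimated: Trajectory, truth: Trajectory) -> float:
    """RMSE of camera positions after closed-form rigid gauge alignment.

    Frame indices must match exactly; a global rigid transform between the
    two trajectories is removed first (it is unobservable), so a uniformly
    shifted or rotated copy of the truth scores zero.
    """
    if list(estimated.indices) != list(truth.indices):
        raise ValueError("trajectories cover different frame indices")
    if len(estimated) == 0:
        raise ValueError("empty trajectory")
    p_est = np.array([pose.translation for _, pose in estimated])
    p_true = np.array([pose.translation for _, pose in truth])
    if len(p_est) >= 3 and not _is_degenerate(p_true):
        T = rigid_fit(p_true, p_est)
        p_est = T.apply(p_est)
    else:
        p_est = p_est - p_est.mean(axis=0) + p_true.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((p_est - p_true) ** 2, axis=1))))


def _is_degenerate(pts) -> bool:
    c = pts - pts.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    return s[0] < 1e-12 or s[1] < 1e-9 * s[0]


def surface_error(mesh, truth_mesh, percentiles=(50, 95, 100)) -> dict:
    """Vertex-to-surface distances from ``mesh`` to ``truth_mesh`` (meters)."""
    if len(mesh.vertices) == 0 or len(truth_mesh.vertices) == 0:
        raise ValueError("cannot compute surface error for an empty mesh")
    d = point_mesh_distance(np.asarray(mesh.vertices), truth_mesh)
    return {f"p{p}": float(np.percentile(d, p)) for p in percentiles}


def compare_methods(source, target, methods: dict, seeds=(0,), truth_transform=None):
    """Run several registration methods on one cloud pair; returns an EvaluationReport.

    ``methods`` maps a name to a callable ``f(source, target, seed) ->
    RegistrationResult``.  Per-method failures are recorded as rows with
    ``error`` set; the table is still emitted.
    """
    from .transforms import rotation_angle

    report = EvaluationReport(seeds=list(seeds))
    for name, fn in methods.items():
        for seed in seeds:
            t0 = time.perf_counter()
            try:
                res = fn(source, target, seed)
            except Exception as exc:  # failure recorded per cell
                report.add_row(name, seed=seed, error=str(exc))
                continue
            elapsed = time.perf_counter() - t0
            row = dict(
                seed=seed,
                fitness=float(res.fitness),
                inlier_rmse=float(res.inlier_rmse),
                time_s=float(elapsed),
                converged=bool(res.converged),
            )
            if truth_transform is not None:
                dR = res.transform.rotation.T @ truth_transform.rotation
                row["rotation_error_deg"] = float(np.degrees(rotation_angle(dR)))
                row["translation_error_m"] = float(
                    np.linalg.norm(res.transform.translation - truth_transform.translation)
                )
            report.add_row(name, **row)
    return report
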