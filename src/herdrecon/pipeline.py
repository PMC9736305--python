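"""Fragment-based reconstruction pipeline.

The scan is split into consecutive k-frame segments (k = 100 by default,
matching a few hundred frames per scan).  Within each segment, dense
RGB-D odometry chained over adjacent frames (identity initialization)
gives a local trajectory, and the frames are fused into a fragment point
cloud by a small local TSDF.  Fragment pairs are then registered —
adjacent pairs initialized by the aggregated odometry, all non-adjacent
pairs tried as loop-closure candidates via FPFH + FGR — and refined with
colored ICP.  Validated edges feed a robust pose graph whose optimized
fragment poses place every frame in world space for the final TSDF
integration, optionally followed by a joint pose/depth-calibration
(SLAC-style) refinement pass.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .camera import PinholeIntrinsics
from .global_registration import compute_fpfh, fgr_register, match_features
from .icp import ColoredICPConfig, colored_icp
from .io import RGBDFrame, Trajectory, write_trajectory
from .odometry import OdometryConfig, compute_rgbd_odometry, wide_baseline_init
from .pointcloud import PointCloud, estimate_normals, evaluate_registration, voxel_downsample
from .posegraph import PoseGraph, PoseGraphConfig, PoseGraphEdge, optimize_pose_graph
from .transforms import RigidTransform
from .tsdf import TSDFVolume, integrate_frames

__all__ = [
    "Fragment",
    "PipelineConfig",
    "split_fragments",
    "build_fragment",
    "propose_pairs",
    "register_pair",
    "run_pipeline",
]


@dataclass
class Fragment:
    id: int
    start: int
    end: int                          # frame index range [start, end)
    trajectory: Trajectory            # camera-to-fragment poses, starts at identity
    cloud: PointCloud                 # fused cloud with normals + intensity
    odometry_world: RigidTransform = None   # drifted world-from-fragment from chained odometry
    truncated: bool = False

    def __post_init__(self):
        if self.odometry_world is None:
            self.odometry_world = RigidTransform.identity()


@dataclass
class PipelineConfig:
    k: int = 100
    seed: int = 0
    odometry: OdometryConfig = field(default_factory=lambda: OdometryConfig(
        max_iterations=15, convergence_tol=1e-8))
    fragment_voxel: float = 0.015        # local TSDF voxel per fragment
    fragment_frame_stride: int = 2
    registration_voxel: float = 0.025    # heavy downsampling for global registration
    fpfh_radius_factor: float = 4.0   # FPFH support = factor * registration voxel
    overlap_fitness: float = 0.3         # loop-closure validity threshold
    refine: ColoredICPConfig = field(default_factory=lambda: ColoredICPConfig(
        scales=((0.04, 30), (0.02, 20), (0.01, 10))))
    pose_graph: PoseGraphConfig = field(default_factory=PoseGraphConfig)
    final_voxel: float = 0.012
    final_frame_stride: int = 2
    use_slac: bool = True


def split_fragments(n_frames: int, k: int) -> list[tuple[int, int]]:
    """Consecutive length-k ranges; a remainder shorter than k/2 merges backward."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if k < 2:
        raise ValueError("k must be >= 2")
    ranges = []
    start = 0
    while start < n_frames:
        end = min(start + k, n_frames)
        ranges.append((start, end))
        start = end
    if len(ranges) > 1 and (ranges[-1][1] - ranges[-1][0]) < k / 2:
        last = ranges.pop()
        prev = ranges.pop()
        ranges.append((prev[0], last[1]))
    return ranges


def build_fragment(
    frames: list[RGBDFrame],
    K: PinholeIntrinsics,
    cfg: PipelineConfig | None = None,
    fragment_id: int = 0,
    start_index: int = 0,
) -> Fragment:
    """Chain adjacent-frame odometry and fuse the segment in a local TSDF."""
    cfg = cfg or PipelineConfig()
    if len(frames) < 2:
        raise ValueError("a fragment needs at least 2 frames")
    traj = Trajectory()
    traj.append(frames[0].timestamp_index, RigidTransform.identity())
    X = RigidTransform.identity()
    used = [frames[0]]
    truncated = False
    for prev, cur in zip(frames, frames[1:]):
        res = compute_rgbd_odometry(prev, cur, K, cfg=cfg.odometry)
        if not res.success:
            init = wide_baseline_init(prev, cur, K, seed=cfg.seed)
            if init is not None:
                res = compute_rgbd_odometry(prev, cur, K, init=init, cfg=cfg.odometry)
        if not res.success:
            warnings.warn(
                f"fragment {fragment_id}: odometry failed between frames "
                f"{prev.timestamp_index} and {cur.timestamp_index}; truncating "
                f"({res.message})"
            )
            truncated = True
            break
        X = X @ res.transform
        traj.append(cur.timestamp_index, X)
        used.append(cur)

    vol = integrate_frames(
        used, K, traj.poses, voxel_size=cfg.fragment_voxel,
        frame_stride=cfg.fragment_frame_stride,
    )
    cloud = vol.extract_pointcloud()
    return Fragment(
        id=fragment_id,
        start=start_index,
        end=start_index + len(used),
        trajectory=traj,
        cloud=cloud,
        truncated=truncated,
    )


def propose_pairs(fragments: list[Fragment]):
    """Adjacent pairs with odometry-aggregated inits; all others as loop candidates."""
    if len(fragments) < 2:
        raise ValueError("need at least 2 fragments")
    pairs = []
    for i in range(len(fragments)):
        for j in range(i + 1, len(fragments)):
            if j == i + 1:
                init = fragments[i].odometry_world.invert() @ fragments[j].odometry_world
                pairs.append((i, j, init))
            else:
                pairs.append((i, j, None))
    return pairs


def _edge_information(source: PointCloud, target: PointCloud, T, max_dist: float):
    """Approximate information matrix: J^T J of the point-to-plane rows at convergence."""
    res = evaluate_registration(source, target, T, max_dist)
    pairs = res.correspondences.pairs
    if len(pairs) == 0 or target.normals is None:
        return np.eye(6)
    q = T.apply(source.points[pairs[:, 1]])
    n = target.normals[pairs[:, 0]]
    J = np.column_stack([np.cross(q, n), n])
    return J.T @ J


def register_pair(
    frag_i: Fragment,
    frag_j: Fragment,
    init: RigidTransform | None,
    cfg: PipelineConfig | None = None,
):
    """Register fragment j onto fragment i; returns a PoseGraphEdge or None.

    Without an init the pair is treated as a loop-closure candidate: FPFH
    correspondences, FGR, then colored-ICP refinement; with an init the ICP
    refinement runs directly.  The edge is valid only if the refined fitness
    reaches the overlap threshold.
    """
    cfg = cfg or PipelineConfig()
    P, Q = frag_i.cloud, frag_j.cloud
    if len(P) == 0 or len(Q) == 0:
        return None
    kind = "odometry" if init is not None else "loop_closure"
    if init is None:
        voxel = cfg.registration_voxel
        P_d = voxel_downsample(P, voxel)
        Q_d = voxel_downsample(Q, voxel)
        if len(P_d) < 10 or len(Q_d) < 10:
            return None
        radius = cfg.fpfh_radius_factor * voxel
        fp, _ = compute_fpfh(P_d, radius)
        fq, _ = compute_fpfh(Q_d, radius)
        corr = match_features(fp, fq, P_d.points, Q_d.points, seed=cfg.seed)
        if len(corr) < 4:
            return None
        try:
            coarse = fgr_register(P_d, Q_d, corr, eval_dist=2 * voxel)
        except ValueError:
            return None
        if not coarse.converged or coarse.fitness < cfg.overlap_fitness:
            return None
        init = coarse.transform
    refined = colored_icp(Q, P, init=init, cfg=cfg.refine)
    if not refined.converged or refined.fitness < cfg.overlap_fitness:
        return None
    info = _edge_information(Q, P, refined.transform,
                             cfg.refine.max_correspondence_factor * cfg.refine.scales[-1][0])
    return PoseGraphEdge(
        i=frag_i.id, j=frag_j.id, transform=refined.transform,
        information=info, kind=kind,
    ), refined


def run_pipeline(frames, K: PinholeIntrinsics, cfg: PipelineConfig | None = None,
                 out_dir=None):
    """Full reconstruction: split -> build -> propose -> register -> optimize ->
    integrate (-> SLAC).  Returns a dict with trajectory, mesh, cloud and report.

    The report is deterministic given the config seeds; wall-times go into a
    separate ``timings`` mapping (and file) so the report itself is
    reproducible bit for bit.
    """
    from . import slac as slac_mod

    cfg = cfg or PipelineConfig()
    timings = {}
    report = {"n_frames": len(frames), "k": cfg.k, "seed": cfg.seed, "stages": {}}

    t0 = time.perf_counter()
    ranges = split_fragments(len(frames), cfg.k)
    fragments = []
    world = RigidTransform.identity()
    for fid, (s, e) in enumerate(ranges):
        frag = build_fragment(frames[s:e], K, cfg, fragment_id=fid, start_index=s)
        frag.odometry_world = world
        # aggregate odometry across the fragment boundary for the next fragment
        if e < len(frames):
            X_last = frag.trajectory.poses[-1]
            res = compute_rgbd_odometry(frames[e - 1], frames[e], K, cfg=cfg.odometry)
            boundary = res.transform if res.success else RigidTransform.identity()
            world = world @ X_last @ boundary
        fragments.append(frag)
    report["stages"]["fragments"] = {
        "count": len(fragments),
        "ranges": [[f.start, f.end] for f in fragments],
        "truncated": [f.id for f in fragments if f.truncated],
    }
    timings["fragments_s"] = time.perf_counter() - t0

    # pairwise registration
    t0 = time.perf_counter()
    edges = []
    reg_rows = []
    if len(fragments) >= 2:
        for i, j, init in propose_pairs(fragments):
            out = register_pair(fragments[i], fragments[j], init, cfg)
            if out is None:
                reg_rows.append({"i": i, "j": j, "valid": False})
                continue
            edge, refined = out
            edges.append(edge)
            reg_rows.append({
                "i": i, "j": j, "valid": True, "kind": edge.kind,
                "fitness": round(refined.fitness, 9),
                "inlier_rmse": round(refined.inlier_rmse, 9),
            })
    report["stages"]["registration"] = {"pairs": reg_rows}
    timings["registration_s"] = time.perf_counter() - t0

    # pose graph
    t0 = time.perf_counter()
    nodes = [f.odometry_world for f in fragments]
    graph = PoseGraph(nodes=nodes, edges=edges)
    if len(fragments) >= 2 and edges:
        graph = optimize_pose_graph(graph, cfg.pose_graph)
    report["stages"]["pose_graph"] = {
        "edges": [
            {"i": e.i, "j": e.j, "kind": e.kind, "line_weight": round(e.line_weight, 9)}
            for e in graph.edges
        ],
    }
    timings["pose_graph_s"] = time.perf_counter() - t0

    # per-frame world poses
    traj = Trajectory()
    for frag, X in zip(fragments, graph.nodes):
        for idx, local in frag.trajectory:
            traj.append(idx, X @ local)

    # optional SLAC-style refinement
    model = None
    if cfg.use_slac and len(fragments) >= 2:
        t0 = time.perf_counter()
        slac_res = slac_mod.slac_optimize(fragments, graph, frames, K, slac_mod.SlacConfig())
        graph = slac_res.graph
        model = slac_res.model
        if not model.is_identity:
            frames = [slac_mod.apply_distortion_correction(f, model, K) for f in frames]
        traj = Trajectory()
        for frag, X in zip(fragments, graph.nodes):
            for idx, local in frag.trajectory:
                traj.append(idx, X @ local)
        report["stages"]["slac"] = {
            "a1": round(model.a1, 9), "a2": round(model.a2, 9),
            "objective_history": [round(v, 12) for v in slac_res.objective_history],
        }
        timings["slac_s"] = time.perf_counter() - t0

    # final integration
    t0 = time.perf_counter()
    pose_by_index = dict(zip(traj.indices, traj.poses))
    frames_posed = [f for f in frames if f.timestamp_index in pose_by_index]
    poses = [pose_by_index[f.timestamp_index] for f in frames_posed]
    vol = integrate_frames(frames_posed, K, poses, voxel_size=cfg.final_voxel,
                           frame_stride=cfg.final_frame_stride)
    mesh = vol.extract_mesh()
    cloud = vol.extract_pointcloud()
    report["stages"]["integration"] = {
        "voxel_size": cfg.final_voxel,
        "mesh_vertices": int(len(mesh.vertices)),
        "mesh_faces": int(len(mesh.faces)),
    }
    timings["integration_s"] = time.perf_counter() - t0

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_trajectory(traj, out_dir / "trajectory.tum")
        from .io import write_mesh_ply, write_pointcloud_ply

        write_mesh_ply(mesh, out_dir / "mesh.ply")
        write_pointcloud_ply(cloud, out_dir / "cloud.ply")
        (out_dir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n")
        (out_dir / "timings.json").write_text(
            json.dumps(timings, indent=2, sort_keys=True) + "\n")

    return {
        "fragments": fragments,
        "graph": graph,
        "trajectory": traj,
        "mesh": mesh,
        "cloud": cloud,
        "volume": vol,
        "report": report,
        "timings": timings,
        "distortion_model": model,
    }
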