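"""Joint pose + depth-calibration refinement (simplified SLAC).

After pose-graph optimization, residual inter-fragment misalignment often
has structure that rigid poses cannot absorb — in stereo depth cameras
the dominant mode is a radial depth distortion.  This module jointly
re-optimizes the fragment poses and a 2-coefficient multiplicative radial
depth-correction model

    d_corrected = d * (1 + a1 r^2 + a2 r^4),   r = image radius / corner radius

by alternating minimization of summed point-to-plane residuals over
mutual-nearest inter-fragment correspondences: (a) damped Gauss-Newton on
the fragment poses, (b) exact linear least squares on (a1, a2) — both
residual forms are linear in their block's unknowns, so each half-step is
non-increasing at fixed correspondences.  This is a deliberate,
documented simplification of control-grid SLAC: the same pipeline role
(drift/outlier reduction) with a model that is recoverable and testable
at desk scale.

``a1 = a2 = 0`` is the identity; the sanity bound keeps the correction
factor within [0.9, 1.1] over the image.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .camera import PinholeIntrinsics
from .io import RGBDFrame
from .pointcloud import PointCloud, estimate_normals
from .posegraph import PoseGraph
from .transforms import RigidTransform, se3_exp

__all__ = [
    "DistortionModel",
    "SlacConfig",
    "SlacResult",
    "apply_distortion_correction",
    "fit_inverse_model",
    "slac_optimize",
]


@dataclass(frozen=True)
class DistortionModel:
    a1: float = 0.0
    a2: float = 0.0

    def factor(self, r2: np.ndarray) -> np.ndarray:
        """Multiplicative depth factor at normalized radius^2 ``r2`` in [0, 1]."""
        return 1.0 + self.a1 * r2 + self.a2 * r2**2

    def validate(self) -> None:
        r2 = np.linspace(0.0, 1.0, 101)
        f = self.factor(r2)
        if f.min() < 0.9 or f.max() > 1.1:
            raise ValueError(
                f"distortion factor range [{f.min():.3f}, {f.max():.3f}] outside "
                "the sanity bound [0.9, 1.1]"
            )

    @property
    def is_identity(self) -> bool:
        return self.a1 == 0.0 and self.a2 == 0.0


def _radius2_grid(K: PinholeIntrinsics) -> np.ndarray:
    vv, uu = np.mgrid[0 : K.height, 0 : K.width]
    corners = [
        (0 - K.cx) ** 2 + (0 - K.cy) ** 2,
        (K.width - 1 - K.cx) ** 2 + (0 - K.cy) ** 2,
        (0 - K.cx) ** 2 + (K.height - 1 - K.cy) ** 2,
        (K.width - 1 - K.cx) ** 2 + (K.height - 1 - K.cy) ** 2,
    ]
    rmax2 = max(corners)
    return ((uu - K.cx) ** 2 + (vv - K.cy) ** 2) / rmax2


def apply_distortion_correction(
    frame: RGBDFrame, model: DistortionModel, K: PinholeIntrinsics
) -> RGBDFrame:
    """Rescale depth by the radial factor; gray untouched, invalid pixels stay 0."""
    model.validate()
    r2 = _radius2_grid(K)
    depth = frame.depth * model.factor(r2)
    depth[frame.depth == 0] = 0.0
    return RGBDFrame(frame.gray.copy(), depth, timestamp_index=frame.timestamp_index)


def fit_inverse_model(model: DistortionModel) -> DistortionModel:
    """Least-squares polynomial inverse: factor_inv(r) ~ 1 / factor(r) on [0, 1]."""
    r2 = np.linspace(0.0, 1.0, 201)
    target = 1.0 / model.factor(r2) - 1.0
    A = np.column_stack([r2, r2**2])
    coef, *_ = np.linalg.lstsq(A, target, rcond=None)
    return DistortionModel(a1=float(coef[0]), a2=float(coef[1]))


# ------------------------------------------------------------------ optimization

@dataclass
class SlacConfig:
    frame_stride: int = 4
    pixel_stride: int = 2
    max_points_per_fragment: int = 8000
    corr_dist: float = 0.015
    normal_k: int = 24
    outer_iterations: int = 5
    gn_iterations: int = 6
    tol: float = 1e-6
    freeze_model: bool = False
    coeff_bound: float = 0.1      # |a1| + |a2| cap (keeps the factor in [0.9, 1.1])


@dataclass
class SlacResult:
    graph: PoseGraph
    model: DistortionModel
    objective_history: list = field(default_factory=list)


class _FragmentSamples:
    """Per-fragment calibration samples: camera rays, depths, radii, local poses."""

    def __init__(self, fragment, frames, K: PinholeIntrinsics, cfg: SlacConfig):
        r2_grid = _radius2_grid(K)
        vv, uu = np.mgrid[0 : K.height : cfg.pixel_stride, 0 : K.width : cfg.pixel_stride]
        r2_s = r2_grid[:: cfg.pixel_stride, :: cfg.pixel_stride]
        by_index = {f.timestamp_index: f for f in frames}
        vs, ts, r2s = [], [], []
        for idx, local in list(fragment.trajectory)[:: cfg.frame_stride]:
            frame = by_index.get(idx)
            if frame is None:
                continue
            d = frame.depth[:: cfg.pixel_stride, :: cfg.pixel_stride]
            valid = d > 0
            if not np.any(valid):
                continue
            dirs = np.stack(
                [(uu[valid] - K.cx) / K.fx, (vv[valid] - K.cy) / K.fy,
                 np.ones(np.count_nonzero(valid))], axis=-1,
            )
            p_cam = dirs * d[valid][:, None]
            # fragment-frame point = R_local (factor * p_cam) + t_local
            vs.append(p_cam @ local.rotation.T)
            ts.append(np.broadcast_to(local.translation, (len(p_cam), 3)).copy())
            r2s.append(r2_s[valid])
        if not vs:
            self.v = np.empty((0, 3))
            self.t = np.empty((0, 3))
            self.r2 = np.empty(0)
            self.normals_frag = np.empty((0, 3))
            return
        v = np.vstack(vs)
        t = np.vstack(ts)
        r2 = np.concatenate(r2s)
        if len(v) > cfg.max_points_per_fragment:
            step = int(np.ceil(len(v) / cfg.max_points_per_fragment))
            v, t, r2 = v[::step], t[::step], r2[::step]
        self.v = v          # rotated camera points (scale with the radial factor)
        self.t = t          # local translations (unaffected by the factor)
        self.r2 = r2
        # normals in the fragment frame from the identity-correction geometry
        cloud = PointCloud(self.points_fragment(DistortionModel()))
        if len(cloud) >= cfg.normal_k:
            cloud = estimate_normals(cloud, k_neighbors=cfg.normal_k,
                                     viewpoint=(0.0, 0.0, 0.0))
            self.normals_frag = cloud.normals
        else:
            self.normals_frag = np.zeros_like(self.v)

    def points_fragment(self, model: DistortionModel) -> np.ndarray:
        return self.v * model.factor(self.r2)[:, None] + self.t

    def __len__(self):
        return len(self.r2)


def _pair_correspondences(samples_i, samples_j, X_i, X_j, model, cfg):
    """Mutual nearest neighbors between two fragments' world clouds."""
    w_i = X_i.apply(samples_i.points_fragment(model))
    w_j = X_j.apply(samples_j.points_fragment(model))
    if len(w_i) == 0 or len(w_j) == 0:
        return None
    tree_i = cKDTree(w_i)
    tree_j = cKDTree(w_j)
    d_ij, nn_ij = tree_j.query(w_i, distance_upper_bound=cfg.corr_dist)
    d_ji, nn_ji = tree_i.query(w_j, distance_upper_bound=cfg.corr_dist)
    ii = np.arange(len(w_i))
    ok = np.isfinite(d_ij)
    ii = ii[ok]
    jj = nn_ij[ok]
    mutual = nn_ji[jj] == ii
    ii, jj = ii[mutual], jj[mutual]
    if len(ii) == 0:
        return None
    return ii, jj


def slac_optimize(fragments, graph: PoseGraph, frames, K: PinholeIntrinsics,
                  cfg: SlacConfig | None = None) -> SlacResult:
    """Alternating pose / distortion-coefficient refinement.

    Returns updated fragment poses (same gauge: node 0 fixed) and the fitted
    correction model.  With ``freeze_model`` the coefficient step is skipped
    and this reduces to a dense pose-only polish of the pose-graph solution.
    """
    import copy

    cfg = cfg or SlacConfig()
    g = PoseGraph(nodes=list(graph.nodes), edges=[copy.copy(e) for e in graph.edges])
    samples = [_FragmentSamples(f, frames, K, cfg) for f in fragments]
    model = DistortionModel()
    history = []

    pair_list = [(e.i, e.j) for e in g.edges if e.line_weight > 0.25]
    if not pair_list:
        pair_list = [(i, i + 1) for i in range(len(fragments) - 1)]

    prev_obj = None
    for outer in range(cfg.outer_iterations):
        # fixed correspondence set for this alternation
        corrs = []
        for (i, j) in pair_list:
            pc = _pair_correspondences(samples[i], samples[j], g.nodes[i], g.nodes[j],
                                       model, cfg)
            if pc is not None:
                corrs.append((i, j, pc[0], pc[1]))
        if not corrs:
            warnings.warn("no inter-fragment correspondences; SLAC pass skipped")
            break

        def residuals(nodes, mdl):
            rows = []
            for (i, j, ii, jj) in corrs:
                w_i = nodes[i].apply(samples[i].points_fragment(mdl)[ii])
                w_j = nodes[j].apply(samples[j].points_fragment(mdl)[jj])
                n_w = samples[i].normals_frag[ii] @ nodes[i].rotation.T
                rows.append((np.einsum("kd,kd->k", w_i - w_j, n_w), i, j, ii, jj, w_i, w_j, n_w))
            return rows

        def objective(nodes, mdl):
            return sum(float(np.sum(r[0] ** 2)) for r in residuals(nodes, mdl))

        obj = objective(g.nodes, model)

        # (a) pose Gauss-Newton (node 0 fixed)
        n_nodes = len(g.nodes)
        free = list(range(1, n_nodes))
        idx_of = {node: 6 * k for k, node in enumerate(free)}
        lam = 1e-6
        for _ in range(cfg.gn_iterations):
            rows = residuals(g.nodes, model)
            dim = 6 * len(free)
            if dim == 0:
                break
            H = np.zeros((dim, dim))
            b = np.zeros(dim)
            for (r, i, j, ii, jj, w_i, w_j, n_w) in rows:
                J_i = np.column_stack([np.cross(w_i, n_w), n_w])
                J_j = -np.column_stack([np.cross(w_j, n_w), n_w])
                for node, J in ((i, J_i), (j, J_j)):
                    if node == 0:
                        continue
                    ia = idx_of[node]
                    b[ia : ia + 6] += J.T @ r
                    H[ia : ia + 6, ia : ia + 6] += J.T @ J
                if i != 0 and j != 0:
                    ia, ib = idx_of[i], idx_of[j]
                    H[ia : ia + 6, ib : ib + 6] += J_i.T @ J_j
                    H[ib : ib + 6, ia : ia + 6] += J_j.T @ J_i
            accepted = False
            for _try in range(7):
                delta = np.linalg.solve(
                    H + lam * np.diag(np.maximum(np.diag(H), 1e-12)) + 1e-12 * np.eye(dim), -b
                )
                new_nodes = list(g.nodes)
                for node, ia in idx_of.items():
                    new_nodes[node] = se3_exp(delta[ia : ia + 6]) @ g.nodes[node]
                new_obj = objective(new_nodes, model)
                if new_obj <= obj:
                    g.nodes = new_nodes
                    rel = (obj - new_obj) / max(obj, 1e-30)
                    obj = new_obj
                    lam = max(lam / 3.0, 1e-9)
                    accepted = True
                    break
                lam *= 10.0
            if not accepted or rel < cfg.tol:
                break

        # (b) distortion coefficients by exact linear least squares
        if not cfg.freeze_model:
            A_rows, b_rows = [], []
            for (i, j, ii, jj) in corrs:
                n_w = samples[i].normals_frag[ii] @ g.nodes[i].rotation.T
                v_i = samples[i].v[ii] @ g.nodes[i].rotation.T
                v_j = samples[j].v[jj] @ g.nodes[j].rotation.T
                base_i = g.nodes[i].apply(samples[i].v[ii] + samples[i].t[ii])
                base_j = g.nodes[j].apply(samples[j].v[jj] + samples[j].t[jj])
                const = np.einsum("kd,kd->k", base_i - base_j, n_w)
                nv_i = np.einsum("kd,kd->k", v_i, n_w)
                nv_j = np.einsum("kd,kd->k", v_j, n_w)
                r2_i, r2_j = samples[i].r2[ii], samples[j].r2[jj]
                A_rows.append(np.column_stack([
                    nv_i * r2_i - nv_j * r2_j,
                    nv_i * r2_i**2 - nv_j * r2_j**2,
                ]))
                b_rows.append(-const)
            A = np.vstack(A_rows)
            rhs = np.concatenate(b_rows)
            AtA = A.T @ A
            if np.linalg.cond(AtA) > 1e10:
                warnings.warn("distortion fit under-determined; keeping current model")
            else:
                coef = np.linalg.solve(AtA, A.T @ rhs)
                cand = DistortionModel(a1=float(coef[0]), a2=float(coef[1]))
                if abs(cand.a1) + abs(cand.a2) > cfg.coeff_bound:
                    warnings.warn("distortion fit outside sanity bound; keeping current model")
                else:
                    new_obj = objective(g.nodes, cand)
                    if new_obj <= obj:
                        model = cand
                        obj = new_obj

        history.append(obj / max(sum(len(c[2]) for c in corrs), 1))
        if prev_obj is not None and abs(prev_obj - history[-1]) <= cfg.tol * max(prev_obj, 1e-30):
            break
        prev_obj = history[-1]

    return SlacResult(graph=g, model=model, objective_history=history)
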