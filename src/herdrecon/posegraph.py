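"""Robust pose-graph optimization over fragment poses.

Nodes are world-from-fragment poses X_i; an edge (i, j) carries a relative
measurement T_ij (mapping fragment-j coordinates into fragment i's) with a
6x6 information matrix.  The residual of an edge is the se(3) log of the
measurement discrepancy, and the objective couples a line process over
loop-closure edges with the weighted squared residuals:

    E = sum_e  w_e ||log(T_e^-1 X_i^-1 X_j)||^2_Info  +  mu_lc sum_lc (sqrt(w_e) - 1)^2

Odometry edges keep w_e = 1; loop-closure weights get the closed-form
update w = (mu / (mu + r^2))^2, so grossly inconsistent loop closures are
switched off instead of dragging the solution.  Pose updates are damped
Gauss-Newton steps (Jacobians by forward differences on the local se(3)
increments — graphs here have at most a dozen nodes); node 0 is held
fixed as the gauge.  The objective never increases over an accepted
alternation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .transforms import RigidTransform, se3_exp, se3_log

__all__ = ["PoseGraphEdge", "PoseGraph", "optimize_pose_graph", "PoseGraphConfig"]


@dataclass
class PoseGraphEdge:
    i: int
    j: int
    transform: RigidTransform           # T_ij: maps j-frame points into i-frame
    information: np.ndarray = None      # 6x6 SPD
    kind: str = "odometry"              # "odometry" | "loop_closure"
    line_weight: float = 1.0

    def __post_init__(self):
        if self.information is None:
            self.information = np.eye(6)
        self.information = np.asarray(self.information, dtype=float)
        if self.information.shape != (6, 6):
            raise ValueError("information matrix must be 6x6")
        if not np.allclose(self.information, self.information.T, atol=1e-9):
            raise ValueError("information matrix must be symmetric")
        eigvals = np.linalg.eigvalsh(self.information)
        if eigvals.min() < -1e-9:
            raise ValueError("information matrix must be positive semidefinite")
        if self.kind not in ("odometry", "loop_closure"):
            raise ValueError(f"unknown edge kind {self.kind!r}")
        if self.kind == "odometry" and self.line_weight != 1.0:
            raise ValueError("odometry edges always carry line_weight 1")


@dataclass
class PoseGraph:
    nodes: list                                   # list[RigidTransform], world-from-fragment
    edges: list = field(default_factory=list)     # list[PoseGraphEdge]

    def validate_connected(self):
        n = len(self.nodes)
        parent = list(range(n))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for e in self.edges:
            ra, rb = find(e.i), find(e.j)
            if ra != rb:
                parent[ra] = rb
        roots = {find(k) for k in range(n)}
        if len(roots) > 1:
            comps = {}
            for k in range(n):
                comps.setdefault(find(k), []).append(k)
            raise ValueError(f"pose graph is disconnected: components {sorted(comps.values())}")


@dataclass
class PoseGraphConfig:
    max_outer_iterations: int = 16
    max_gn_iterations: int = 8
    convergence_tol: float = 1e-10
    mu_lc: float | None = None      # fixed line-process penalty; None -> annealed
    mu_division: float = 1.6        # graduated non-convexity: mu shrinks per outer iter

    # loop-closure weights below this after optimization count as pruned
    prune_threshold: float = 0.1


def _edge_residual(edge: PoseGraphEdge, nodes) -> np.ndarray:
    X_i = nodes[edge.i]
    X_j = nodes[edge.j]
    return se3_log(edge.transform.invert() @ X_i.invert() @ X_j)


def _objective(graph: PoseGraph, cfg: PoseGraphConfig, mu: float) -> float:
    total = 0.0
    for e in graph.edges:
        r = _edge_residual(e, graph.nodes)
        total += e.line_weight * float(r @ e.information @ r)
        if e.kind == "loop_closure":
            total += mu * (np.sqrt(e.line_weight) - 1.0) ** 2
    return total


def _gn_pose_step(graph: PoseGraph, cfg: PoseGraphConfig, mu: float, lam: float):
    """One damped Gauss-Newton step over all free node increments; returns new nodes."""
    n = len(graph.nodes)
    free = list(range(1, n))           # node 0 fixed (gauge)
    idx_of = {node: 6 * k for k, node in enumerate(free)}
    dim = 6 * len(free)
    H = np.zeros((dim, dim))
    b = np.zeros(dim)
    eps = 1e-7
    for e in graph.edges:
        w = e.line_weight
        if w <= 0:
            continue
        r0 = _edge_residual(e, graph.nodes)
        blocks = {}
        for node in (e.i, e.j):
            if node == 0:
                continue
            J = np.zeros((6, 6))
            for k in range(6):
                d = np.zeros(6)
                d[k] = eps
                nodes_pert = list(graph.nodes)
                nodes_pert[node] = se3_exp(d) @ graph.nodes[node]
                J[:, k] = (_edge_residual(e, nodes_pert) - r0) / eps
            blocks[node] = J
        info = w * e.information
        for a, Ja in blocks.items():
            ia = idx_of[a]
            b[ia : ia + 6] += Ja.T @ info @ r0
            for bnode, Jb in blocks.items():
                ib = idx_of[bnode]
                H[ia : ia + 6, ib : ib + 6] += Ja.T @ info @ Jb
    if dim == 0:
        return list(graph.nodes)
    H_d = H + lam * np.diag(np.maximum(np.diag(H), 1e-12)) + 1e-12 * np.eye(dim)
    delta = np.linalg.solve(H_d, -b)
    new_nodes = list(graph.nodes)
    for node, ia in idx_of.items():
        new_nodes[node] = se3_exp(delta[ia : ia + 6]) @ graph.nodes[node]
    return new_nodes


def optimize_pose_graph(graph: PoseGraph, cfg: PoseGraphConfig | None = None) -> PoseGraph:
    """Alternate line-process weight updates with damped pose Gauss-Newton.

    Returns a new graph with updated node poses and loop-closure
    ``line_weight`` values (odometry edges stay at 1); the combined objective
    is non-increasing over accepted steps and node 0 is left untouched.
    """
    cfg = cfg or PoseGraphConfig()
    graph.validate_connected()
    import copy

    g = PoseGraph(
        nodes=list(graph.nodes),
        edges=[copy.copy(e) for e in graph.edges],
    )
    def _odometry_cost_scale(nodes) -> float:
        costs = []
        for e in g.edges:
            if e.kind != "odometry":
                continue
            r = _edge_residual(e, nodes)
            costs.append(float(r @ e.information @ r))
        return float(np.median(costs)) if costs else 0.0

    if cfg.mu_lc is None:
        # graduated non-convexity: start with mu above the worst initial
        # inconsistency (every closure keeps weight ~1) and anneal toward the
        # residual scale of the odometry edges, the natural "consistent edge"
        # reference — gross outliers are switched off, good closures kept
        costs = []
        for e in g.edges:
            r = _edge_residual(e, g.nodes)
            costs.append(float(r @ e.information @ r))
        mu = max(10.0 * max(costs, default=1.0), 1e-8)
        anneal = True
    else:
        mu = cfg.mu_lc
        anneal = False

    obj = _objective(g, cfg, mu)
    for _ in range(cfg.max_outer_iterations):
        # (a) closed-form line-process weights for loop closures
        for e in g.edges:
            if e.kind != "loop_closure":
                continue
            r = _edge_residual(e, g.nodes)
            cost = float(r @ e.information @ r)
            e.line_weight = float((mu / (mu + cost)) ** 2)
        obj = _objective(g, cfg, mu)
        # (b) damped Gauss-Newton on poses
        lam = 1e-6
        for _ in range(cfg.max_gn_iterations):
            accepted = False
            for _try in range(7):
                new_nodes = _gn_pose_step(g, cfg, mu, lam)
                trial = PoseGraph(nodes=new_nodes, edges=g.edges)
                new_obj = _objective(trial, cfg, mu)
                if new_obj <= obj:
                    g.nodes = new_nodes
                    rel = (obj - new_obj) / max(obj, 1e-30)
                    obj = new_obj
                    lam = max(lam / 3.0, 1e-9)
                    accepted = True
                    break
                lam *= 10.0
            if not accepted or rel < cfg.convergence_tol:
                break
        if anneal:
            mu_floor = max(10.0 * _odometry_cost_scale(g.nodes), 1e-10)
            mu = max(mu / cfg.mu_division, mu_floor)
            obj = _objective(g, cfg, mu)
        if obj <= 1e-28:
            break
    return g
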