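"""Alternating closest-point / regularized cage optimization.

Fits the bound template to a frame's constraint points by repeating:
(1) associate every constraint point with its globally closest point on
the current deformed mesh (barycentric footpoint), then (2) update the
cage vertices by exactly minimizing

    alpha * sum_k ||p_k - p_k^c||^2
  + beta  * sum_j ||c_j - c_j^0||^2
  + gamma * sum_j ||L(c_j) - L(c_j^0)||^2

where p_k is a linear function of the cage through the barycentric weights
and the harmonic binding, and L is the degree-normalized graph Laplacian on
the cage's polygon edge graph. Defaults: alpha=1, beta=1, gamma=5, 20
iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.spatial import cKDTree

from ._geometry import closest_point_triangles
from .core_model import Cage, FrameState, Template, TriangleMesh, deform_mesh
from .curves import ConstraintPointSet
from .errors import ConstraintError, GeometryError, ParameterError

__all__ = [
    "ClosestPointAssociation",
    "FittingParameters",
    "FitDiagnostics",
    "closest_point_on_mesh",
    "closest_points_on_mesh",
    "graph_laplacian",
    "solve_cage_update",
    "fit_template_to_curves",
]

#: final/initial mean-residual ratio above which a fit is flagged
#: as non-converged (the inaccurate-association failure mode)
NONCONVERGENCE_RATIO = 0.25

#: a fit whose final mean residual is below this is never flagged, ratio
#: aside (guards frames that start essentially converged)
NONCONVERGENCE_ABS_TOL_MM = 0.1


@dataclass(frozen=True)
class ClosestPointAssociation:
    """Footpoints of constraint points on the mesh surface."""

    triangle_indices: np.ndarray  # (K,) int
    barycentric: np.ndarray  # (K, 3), >= 0, rows sum to 1
    footpoints: np.ndarray  # (K, 3) mm

    def __len__(self) -> int:
        return len(self.triangle_indices)


@dataclass(frozen=True)
class FittingParameters:
    """Cost weights and iteration count of the alternating fit."""

    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 5.0
    iterations: int = 20
    early_stop_tol: Optional[float] = None  # mean-residual change (mm), off by default

    def __post_init__(self):
        if self.alpha <= 0:
            raise ParameterError("alpha must be > 0 (data term)")
        if self.beta < 0 or self.gamma < 0:
            raise ParameterError("beta and gamma must be >= 0")
        if self.iterations < 1:
            raise ParameterError("iterations must be >= 1")


@dataclass
class FitDiagnostics:
    """Per-iteration residual statistics of one frame fit."""

    mean_residuals: List[float] = field(default_factory=list)
    max_residuals: List[float] = field(default_factory=list)
    objective_before: List[float] = field(default_factory=list)
    objective_after: List[float] = field(default_factory=list)
    final_mean_residual: float = np.nan
    final_max_residual: float = np.nan
    n_constraints: int = 0
    converged: bool = True

    @property
    def initial_mean_residual(self) -> float:
        return self.mean_residuals[0] if self.mean_residuals else np.nan

    def to_dict(self) -> dict:
        return {
            "mean_residuals_mm": list(map(float, self.mean_residuals)),
            "max_residuals_mm": list(map(float, self.max_residuals)),
            "objective_before": list(map(float, self.objective_before)),
            "objective_after": list(map(float, self.objective_after)),
            "final_mean_residual_mm": float(self.final_mean_residual),
            "final_max_residual_mm": float(self.final_max_residual),
            "n_constraints": int(self.n_constraints),
            "converged": bool(self.converged),
        }


def _check_mesh_nondegenerate(mesh: TriangleMesh):
    tv = mesh.triangle_positions
    areas = 0.5 * np.linalg.norm(
        np.cross(tv[:, 1] - tv[:, 0], tv[:, 2] - tv[:, 0]), axis=1
    )
    bad = np.flatnonzero(areas < 1e-14)
    if bad.size:
        raise GeometryError(f"zero-area triangle {int(bad[0])} in closest-point query")


def closest_points_on_mesh(
    mesh: TriangleMesh, queries: np.ndarray
) -> ClosestPointAssociation:
    """Exact globally-nearest surface points for a batch of queries.

    A KD-tree over mesh vertices supplies a per-query distance upper bound;
    only triangles whose bounding spheres can beat that bound are examined
    exactly. Equidistant triangles resolve to the lowest triangle index.
    """
    _check_mesh_nondegenerate(mesh)
    queries = np.atleast_2d(np.asarray(queries, dtype=float))
    tv = mesh.triangle_positions
    centroids = tv.mean(axis=1)
    circum = np.linalg.norm(tv - centroids[:, None, :], axis=2).max(axis=1)

    vtree = cKDTree(mesh.vertices)
    ub, _ = vtree.query(queries)  # distance to nearest vertex bounds the answer
    ctree = cKDTree(centroids)

    K = len(queries)
    tri_out = np.empty(K, dtype=np.int64)
    bary_out = np.empty((K, 3))
    foot_out = np.empty((K, 3))
    rmax = circum.max()
    for k in range(K):
        cand = ctree.query_ball_point(queries[k], ub[k] + rmax + 1e-12)
        cand = np.sort(np.asarray(cand, dtype=np.int64))
        d2, bary = closest_point_triangles(queries[k][None, :], tv[cand])
        j = int(np.argmin(d2[0]))  # first minimum -> lowest triangle index
        tri = int(cand[j])
        tri_out[k] = tri
        bary_out[k] = bary[0, j]
        foot_out[k] = bary[0, j] @ tv[tri]
    return ClosestPointAssociation(tri_out, bary_out, foot_out)


def closest_point_on_mesh(mesh: TriangleMesh, query: np.ndarray):
    """Single-query convenience wrapper; returns (triangle, barycentric, footpoint)."""
    assoc = closest_points_on_mesh(mesh, np.asarray(query, dtype=float)[None, :])
    return int(assoc.triangle_indices[0]), assoc.barycentric[0], assoc.footpoints[0]


def graph_laplacian(cage: Cage) -> sp.csr_matrix:
    """Degree-normalized combinatorial Laplacian on the polygon edge graph.

    ``(L c)_j = c_j - mean of c over the neighbours of j``; row sums are 0,
    so rigid translations are in the null space.
    """
    n = cage.n_vertices
    e = cage.edges
    deg = np.bincount(e.ravel(), minlength=n).astype(float)
    rows = np.concatenate([e[:, 0], e[:, 1]])
    cols = np.concatenate([e[:, 1], e[:, 0]])
    vals = -1.0 / deg[rows]
    L = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return sp.identity(n, format="csr") + L


def solve_cage_update(
    template: Template,
    cage_vertices: np.ndarray,
    assoc: ClosestPointAssociation,
    targets: ConstraintPointSet,
    params: FittingParameters,
    laplacian: Optional[sp.spmatrix] = None,
) -> np.ndarray:
    """Exact minimizer of the regularized quadratic cage objective.

    One sparse SPD system per coordinate axis, sharing a single
    factorization (the system matrix is axis-independent).
    """
    if len(assoc) != len(targets):
        raise ConstraintError(
            f"association ({len(assoc)}) and targets ({len(targets)}) differ"
        )
    if len(targets) == 0:
        raise ConstraintError("no constraint points")
    c0 = np.asarray(cage_vertices, dtype=float)
    pc = targets.points
    if not (np.isfinite(c0).all() and np.isfinite(pc).all()):
        raise ParameterError("non-finite input to cage update")

    A_bind = template.binding.weights  # (N_m, N_c)
    tris = template.mesh.triangles[assoc.triangle_indices]  # (K, 3)
    K = len(assoc)
    n_c = template.cage.n_vertices
    # S: (K, N_m) barycentric selection, B = S @ A_bind : footpoints = B @ c
    S = sp.csr_matrix(
        (
            assoc.barycentric.ravel(),
            (np.repeat(np.arange(K), 3), tris.ravel()),
        ),
        shape=(K, template.mesh.n_vertices),
    )
    B = S @ A_bind  # dense (K, N_c)
    B = np.asarray(B)

    L = graph_laplacian(template.cage) if laplacian is None else laplacian
    LtL = (L.T @ L).toarray()

    M = params.alpha * (B.T @ B) + params.beta * np.eye(n_c) + params.gamma * LtL
    rhs = (
        params.alpha * (B.T @ pc)
        + params.beta * c0
        + params.gamma * (LtL @ c0)
    )
    M_sp = sp.csc_matrix(M)
    solve = spla.factorized(M_sp)
    out = np.empty_like(c0)
    for ax in range(3):
        out[:, ax] = solve(rhs[:, ax])
    return out


def _objective(template, B, c, c0, pc, params, L):
    r = B @ c - pc
    reg = c - c0
    lap = L @ reg
    return (
        params.alpha * float((r * r).sum())
        + params.beta * float((reg * reg).sum())
        + params.gamma * float((lap * lap).sum())
    )


def fit_template_to_curves(
    template: Template,
    state: FrameState,
    constraints: ConstraintPointSet,
    params: FittingParameters = FittingParameters(),
):
    """Run the alternating fit from the frame's current cage.

    Returns ``(FrameState, FitDiagnostics)``. The association is recomputed
    from the freshly deformed mesh every iteration; residuals are recorded
    at association time plus once after the final update.
    """
    if len(constraints) == 0:
        raise ConstraintError("constraint point set is empty")
    cage_v = state.cage_vertices.copy()
    pc = constraints.points
    L = graph_laplacian(template.cage)
    diag = FitDiagnostics(n_constraints=len(constraints))

    for it in range(params.iterations):
        mesh = deform_mesh(template, cage_v)
        assoc = closest_points_on_mesh(mesh, pc)
        res = np.linalg.norm(assoc.footpoints - pc, axis=1)
        diag.mean_residuals.append(float(res.mean()))
        diag.max_residuals.append(float(res.max()))

        tris = template.mesh.triangles[assoc.triangle_indices]
        K = len(assoc)
        S = sp.csr_matrix(
            (assoc.barycentric.ravel(), (np.repeat(np.arange(K), 3), tris.ravel())),
            shape=(K, template.mesh.n_vertices),
        )
        B = np.asarray(S @ template.binding.weights)
        diag.objective_before.append(_objective(template, B, cage_v, cage_v, pc, params, L))
        new_cage = solve_cage_update(template, cage_v, assoc, constraints, params, L)
        diag.objective_after.append(_objective(template, B, new_cage, cage_v, pc, params, L))
        if params.early_stop_tol is not None and it > 0:
            if abs(diag.mean_residuals[-1] - diag.mean_residuals[-2]) < params.early_stop_tol:
                cage_v = new_cage
                break
        cage_v = new_cage

    mesh = deform_mesh(template, cage_v)
    assoc = closest_points_on_mesh(mesh, pc)
    res = np.linalg.norm(assoc.footpoints - pc, axis=1)
    diag.final_mean_residual = float(res.mean())
    diag.final_max_residual = float(res.max())
    initial = diag.mean_residuals[0]
    diag.converged = (
        diag.final_mean_residual <= NONCONVERGENCE_ABS_TOL_MM
        or diag.final_mean_residual <= NONCONVERGENCE_RATIO * initial
    )
    return replace(state, cage_vertices=cage_v), diag
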