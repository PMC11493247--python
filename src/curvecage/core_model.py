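"""Domain types: meshes, cages, harmonic bindings, templates, frame states.

The deformable template is a watertight triangle mesh bound to an enclosing
cage; deformed mesh vertices are always a weighted sum of cage vertices
(``v_i = sum_j a_ji c_j``), so the cage is the single deformation handle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from ._geometry import is_watertight, require_clean_mesh
from .errors import BindingError, ParameterError, TopologyError

__all__ = [
    "TriangleMesh",
    "Cage",
    "HarmonicBinding",
    "Template",
    "FrameState",
    "SimilarityTransform",
    "deform_mesh",
    "apply_alignment",
    "set_cage_vertices",
]


@dataclass(frozen=True)
class TriangleMesh:
    """Triangle mesh in world millimetres."""

    vertices: np.ndarray  # (N_m, 3) float
    triangles: np.ndarray  # (M, 3) int
    name: str = "mesh"

    def __post_init__(self):
        v = np.ascontiguousarray(np.asarray(self.vertices, dtype=float))
        t = np.ascontiguousarray(np.asarray(self.triangles, dtype=np.int64))
        if v.ndim != 2 or v.shape[1] != 3:
            raise ParameterError("vertices must be (N, 3)")
        if t.ndim != 2 or t.shape[1] != 3:
            raise ParameterError("triangles must be (M, 3)")
        if len(v) < 4:
            raise ParameterError("a mesh needs at least 4 vertices")
        if t.size and (t.min() < 0 or t.max() >= len(v)):
            raise TopologyError("triangle index out of range")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "triangles", t)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def triangle_positions(self) -> np.ndarray:
        """(M, 3, 3) vertex positions per triangle."""
        return self.vertices[self.triangles]

    def validate_closed(self, check_self_intersection: bool = True) -> None:
        """Template-grade validation: watertight and self-intersection free."""
        if check_self_intersection:
            require_clean_mesh(self.vertices, self.triangles, self.name)
        elif not is_watertight(self.triangles):
            raise TopologyError(f"{self.name} is not watertight")

    def with_vertices(self, vertices: np.ndarray) -> "TriangleMesh":
        return TriangleMesh(vertices, self.triangles, self.name)

    def bounds(self) -> np.ndarray:
        return np.array([self.vertices.min(axis=0), self.vertices.max(axis=0)])


def _triangulate_fan(faces: Sequence[Sequence[int]]) -> np.ndarray:
    tris = []
    for f in faces:
        for k in range(1, len(f) - 1):
            tris.append((f[0], f[k], f[k + 1]))
    return np.asarray(tris, dtype=np.int64)


def _polygon_edges(faces: Sequence[Sequence[int]]) -> np.ndarray:
    edges = set()
    for f in faces:
        for k in range(len(f)):
            a, b = f[k], f[(k + 1) % len(f)]
            edges.add((min(a, b), max(a, b)))
    return np.asarray(sorted(edges), dtype=np.int64)


@dataclass(frozen=True)
class Cage:
    """Coarse closed control polyhedron enclosing a template mesh.

    Faces may be polygons; they are fan-triangulated internally for
    geometric queries, while the Laplacian uses the authored polygon
    edge graph.
    """

    vertices: np.ndarray  # (N_c, 3)
    faces: tuple  # tuple of tuples of vertex indices (polygons)
    name: str = "cage"
    triangles: np.ndarray = field(init=False, repr=False)
    edges: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        v = np.ascontiguousarray(np.asarray(self.vertices, dtype=float))
        if v.ndim != 2 or v.shape[1] != 3:
            raise ParameterError("cage vertices must be (N, 3)")
        if len(v) < 8:
            raise ParameterError("a cage needs at least 8 vertices")
        faces = tuple(tuple(int(i) for i in f) for f in self.faces)
        flat = [i for f in faces for i in f]
        if min(flat) < 0 or max(flat) >= len(v):
            raise TopologyError("cage face index out of range")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", faces)
        tris = _triangulate_fan(faces)
        if not is_watertight(tris):
            raise TopologyError(f"{self.name} is not closed (watertight)")
        object.__setattr__(self, "triangles", tris)
        object.__setattr__(self, "edges", _polygon_edges(faces))
        deg = np.bincount(self.edges.ravel(), minlength=len(v))
        if np.any(deg == 0):
            raise TopologyError("cage has an isolated vertex")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def with_vertices(self, vertices: np.ndarray) -> "Cage":
        return Cage(vertices, self.faces, self.name)

    def bounds(self) -> np.ndarray:
        return np.array([self.vertices.min(axis=0), self.vertices.max(axis=0)])


@dataclass(frozen=True)
class HarmonicBinding:
    """Harmonic-coordinate weight matrix ``a_ji`` (stored as (N_m, N_c)).

    Rows are a partition of unity; weights are non-negative up to the
    discretization tolerance recorded in ``provenance``.
    """

    weights: np.ndarray  # (N_m, N_c)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        w = np.ascontiguousarray(np.asarray(self.weights, dtype=float))
        if w.ndim != 2:
            raise BindingError("weights must be a 2-D matrix")
        row = w.sum(axis=1)
        if np.max(np.abs(row - 1.0)) > 1e-3:
            raise BindingError("binding rows must sum to 1 within 1e-3")
        if w.min() < -1e-3:
            raise BindingError("binding weights must be >= -1e-3")
        object.__setattr__(self, "weights", w)

    @property
    def n_mesh(self) -> int:
        return self.weights.shape[0]

    @property
    def n_cage(self) -> int:
        return self.weights.shape[1]


@dataclass(frozen=True)
class Template:
    """Rest mesh + rest cage + harmonic binding."""

    mesh: TriangleMesh
    cage: Cage
    binding: HarmonicBinding

    def __post_init__(self):
        if self.binding.n_mesh != self.mesh.n_vertices:
            raise BindingError(
                f"binding rows ({self.binding.n_mesh}) != mesh vertices "
                f"({self.mesh.n_vertices})"
            )
        if self.binding.n_cage != self.cage.n_vertices:
            raise BindingError(
                f"binding columns ({self.binding.n_cage}) != cage vertices "
                f"({self.cage.n_vertices})"
            )
        if self.cage.n_vertices > self.mesh.n_vertices:
            # a cage is meant to be a coarse control structure; tolerated
            # (tiny oracle instances legitimately break this) but flagged
            import logging

            logging.getLogger("curvecage").warning(
                "cage has more vertices (%d) than the mesh (%d)",
                self.cage.n_vertices, self.mesh.n_vertices,
            )


@dataclass(frozen=True)
class SimilarityTransform:
    """Uniform-scale rigid transform ``x -> scale * R x + translation``."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    scale: float = 1.0
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        r = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if self.scale <= 0:
            raise ParameterError("similarity scale must be positive")
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-8):
            raise ParameterError("rotation must be orthonormal")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)
        object.__setattr__(self, "scale", float(self.scale))

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls()

    @classmethod
    def from_axis_angle(
        cls, axis, angle_rad: float, scale: float = 1.0, translation=(0, 0, 0)
    ) -> "SimilarityTransform":
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        kx, ky, kz = axis
        K = np.array([[0, -kz, ky], [kz, 0, -kx], [-ky, kx, 0]])
        R = np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)
        return cls(rotation=R, scale=scale, translation=np.asarray(translation, float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.scale * (np.asarray(points, float) @ self.rotation.T) + self.translation


@dataclass(frozen=True)
class FrameState:
    """Per-frame cage configuration: alignment transform + cage vertices."""

    frame_index: int
    cage_vertices: np.ndarray
    alignment: SimilarityTransform = field(default_factory=SimilarityTransform)

    def __post_init__(self):
        if self.frame_index < 0:
            raise ParameterError("frame index must be >= 0")
        v = np.ascontiguousarray(np.asarray(self.cage_vertices, dtype=float))
        object.__setattr__(self, "cage_vertices", v)


def deform_mesh(template: Template, cage_vertices: np.ndarray) -> TriangleMesh:
    """Evaluate the bound mesh at the given cage configuration.

    Output vertex ``i`` is ``sum_j a_ji c_j``; topology is that of the rest
    mesh, bit-identical.
    """
    c = np.asarray(cage_vertices, dtype=float)
    if c.shape != (template.cage.n_vertices, 3):
        raise BindingError(
            f"expected cage vertices of shape {(template.cage.n_vertices, 3)}, "
            f"got {c.shape}"
        )
    return template.mesh.with_vertices(template.binding.weights @ c)


def apply_alignment(template: Template, transform: SimilarityTransform) -> Cage:
    """Bake a similarity alignment into the rest cage.

    The mesh follows through :func:`deform_mesh`; alignment never touches
    mesh vertices directly.
    """
    return template.cage.with_vertices(transform.apply(template.cage.vertices))


def set_cage_vertices(
    state: FrameState, edits: Mapping[int, Sequence[float]]
) -> FrameState:
    """Manual cage-vertex edits (traditional free-form-deformation mode)."""
    if not edits:
        return state
    verts = state.cage_vertices.copy()
    for idx, pos in edits.items():
        idx = int(idx)
        if idx < 0 or idx >= len(verts):
            raise IndexError(f"cage vertex index {idx} out of range")
        verts[idx] = np.asarray(pos, dtype=float)
    return replace(state, cage_vertices=verts)
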