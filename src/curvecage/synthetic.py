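"""Deterministic synthetic phantoms: templates, motion, curves, labels.

Everything needed to exercise the pipeline without real scan data: a
parametric watertight template (sphere / ellipsoid / capsule / bent tube)
inside a box-lattice cage, a smooth ground-truth cage motion whose target
meshes are exactly cage-representable, constraint curves sampled from
ground-truth surfaces (optionally jittered like imprecise clicks), and
voxelized ground-truth label volumes.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ._geometry import points_in_mesh
from .core_model import (
    Cage,
    SimilarityTransform,
    Template,
    TriangleMesh,
    deform_mesh,
)
from .curves import CrossSectionPlane, CurveConstraint, SharedCurve, save_curves_json
from .errors import CurveCageError, GeometryError, ParameterError
from .harmonic import bind_template
from .mesh_io import save_cage, save_mesh
from .pipeline import LabelVolume, ReferenceGrid, save_grid_json, voxelize_mesh

__all__ = [
    "PhantomSpec",
    "make_template",
    "make_bound_template",
    "make_ground_truth_sequence",
    "cross_section_loops",
    "sample_constraint_curves",
    "rasterize_phantom_labels",
    "dice",
    "icosphere",
    "box_lattice_cage",
    "write_fixture_set",
]


# ---------------------------------------------------------------------------
# parametric shapes
# ---------------------------------------------------------------------------

_ICO_T = (1.0 + np.sqrt(5.0)) / 2.0
_ICO_VERTS = np.array(
    [
        [-1, _ICO_T, 0], [1, _ICO_T, 0], [-1, -_ICO_T, 0], [1, -_ICO_T, 0],
        [0, -1, _ICO_T], [0, 1, _ICO_T], [0, -1, -_ICO_T], [0, 1, -_ICO_T],
        [_ICO_T, 0, -1], [_ICO_T, 0, 1], [-_ICO_T, 0, -1], [-_ICO_T, 0, 1],
    ],
    dtype=float,
)
_ICO_FACES = np.array(
    [
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
    ],
    dtype=np.int64,
)


def icosphere(radius: float = 1.0, subdivisions: int = 3) -> TriangleMesh:
    """Subdivided icosahedron projected to the sphere (watertight)."""
    verts = _ICO_VERTS / np.linalg.norm(_ICO_VERTS, axis=1, keepdims=True)
    faces = _ICO_FACES.copy()
    for _ in range(subdivisions):
        edge_mid: Dict[Tuple[int, int], int] = {}
        new_faces = []
        verts_list = list(verts)

        def midpoint(a: int, b: int) -> int:
            key = (min(a, b), max(a, b))
            if key not in edge_mid:
                m = verts_list[a] + verts_list[b]
                m = m / np.linalg.norm(m)
                edge_mid[key] = len(verts_list)
                verts_list.append(m)
            return edge_mid[key]

        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        verts = np.asarray(verts_list)
        faces = np.asarray(new_faces, dtype=np.int64)
    return TriangleMesh(verts * radius, faces, name="icosphere")


def _ellipsoid(semi_axes, subdivisions: int) -> TriangleMesh:
    s = icosphere(1.0, subdivisions)
    return TriangleMesh(
        s.vertices * np.asarray(semi_axes, float), s.triangles, name="ellipsoid"
    )


def _capsule(radius: float, half_length: float, subdivisions: int) -> TriangleMesh:
    """Sphere split at the equator, caps shifted apart along z."""
    s = icosphere(radius, subdivisions)
    v = s.vertices.copy()
    v[:, 2] += np.where(v[:, 2] >= 0, half_length, -half_length)
    return TriangleMesh(v, s.triangles, name="capsule")


def _bent_tube(
    radius: float, half_length: float, bend_angle_rad: float, subdivisions: int
) -> TriangleMesh:
    """Capsule bent around the y axis by the given total angle."""
    cap = _capsule(radius, half_length, subdivisions)
    v = cap.vertices.copy()
    total_len = 2.0 * (half_length + radius)
    if bend_angle_rad <= 0:
        return TriangleMesh(v, cap.triangles, name="bent_tube")
    rb = total_len / bend_angle_rad  # bend radius
    if rb <= radius:
        raise ParameterError("bend too tight: tube would self-intersect")
    theta = v[:, 2] / rb
    x, z = v[:, 0].copy(), v[:, 2].copy()
    v[:, 0] = (rb + x) * np.cos(theta) - rb
    v[:, 2] = (rb + x) * np.sin(theta)
    return TriangleMesh(v, cap.triangles, name="bent_tube")


def box_lattice_cage(
    bounds_lo, bounds_hi, subdivisions=(2, 2, 2), name: str = "cage"
) -> Cage:
    """Axis-aligned box cage with ``subdivisions`` vertices per axis.

    Only lattice-surface vertices are kept; faces are outward-oriented
    quads, so (2, 2, 2) is the plain 8-vertex box.
    """
    nx, ny, nz = (int(s) for s in subdivisions)
    if min(nx, ny, nz) < 2:
        raise ParameterError("lattice subdivisions must be >= 2 per axis")
    lo = np.asarray(bounds_lo, float)
    hi = np.asarray(bounds_hi, float)
    axes = [np.linspace(lo[a], hi[a], n) for a, n in enumerate((nx, ny, nz))]

    index: Dict[Tuple[int, int, int], int] = {}
    verts: List[np.ndarray] = []

    def vid(i, j, k) -> int:
        key = (i, j, k)
        if key not in index:
            index[key] = len(verts)
            verts.append(np.array([axes[0][i], axes[1][j], axes[2][k]]))
        return index[key]

    faces: List[Tuple[int, ...]] = []
    # -x / +x sides
    for i, flip in ((0, True), (nx - 1, False)):
        for j in range(ny - 1):
            for k in range(nz - 1):
                q = [vid(i, j, k), vid(i, j + 1, k), vid(i, j + 1, k + 1), vid(i, j, k + 1)]
                faces.append(tuple(reversed(q)) if flip else tuple(q))
    # -y / +y
    for j, flip in ((0, False), (ny - 1, True)):
        for i in range(nx - 1):
            for k in range(nz - 1):
                q = [vid(i, j, k), vid(i + 1, j, k), vid(i + 1, j, k + 1), vid(i, j, k + 1)]
                faces.append(tuple(reversed(q)) if flip else tuple(q))
    # -z / +z
    for k, flip in ((0, True), (nz - 1, False)):
        for i in range(nx - 1):
            for j in range(ny - 1):
                q = [vid(i, j, k), vid(i + 1, j, k), vid(i + 1, j + 1, k), vid(i, j + 1, k)]
                faces.append(tuple(reversed(q)) if flip else tuple(q))
    return Cage(np.asarray(verts), tuple(faces), name=name)


# ---------------------------------------------------------------------------
# phantom specification
# ---------------------------------------------------------------------------


@dataclass
class PhantomSpec:
    """Seed-deterministic recipe for a full synthetic fixture set."""

    shape: str = "sphere"  # sphere | ellipsoid | capsule | bent_tube
    size_mm: Tuple[float, ...] = (20.0,)
    subdivisions: int = 3
    cage_subdivisions: Tuple[int, int, int] = (3, 3, 3)
    cage_clearance: float = 0.15  # fraction of the mesh bounding box
    frames: int = 5
    translation_amplitude_mm: Tuple[float, float, float] = (4.0, 0.0, 2.0)
    rotation_amplitude_rad: float = 0.15
    scale_amplitude: float = 0.08
    cage_offset_amplitude_mm: float = 1.5
    seed: int = 0
    curve_planes: Tuple[Tuple[str, float], ...] = (("XY", 0.0), ("YZ", 0.0), ("ZX", 0.0))
    points_per_curve: int = 8
    jitter_mm: float = 0.0
    shared_keyframes: Tuple[int, ...] = ()  # frames treated as shared-curve keyframes

    def to_dict(self) -> dict:
        return {
            "shape": self.shape,
            "size_mm": list(self.size_mm),
            "subdivisions": self.subdivisions,
            "cage_subdivisions": list(self.cage_subdivisions),
            "cage_clearance": self.cage_clearance,
            "frames": self.frames,
            "translation_amplitude_mm": list(self.translation_amplitude_mm),
            "rotation_amplitude_rad": self.rotation_amplitude_rad,
            "scale_amplitude": self.scale_amplitude,
            "cage_offset_amplitude_mm": self.cage_offset_amplitude_mm,
            "seed": self.seed,
            "curve_planes": [list(p) for p in self.curve_planes],
            "points_per_curve": self.points_per_curve,
            "jitter_mm": self.jitter_mm,
            "shared_keyframes": list(self.shared_keyframes),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        kw = dict(d)
        for key in ("size_mm", "cage_subdivisions", "translation_amplitude_mm",
                    "shared_keyframes"):
            if key in kw:
                kw[key] = tuple(kw[key])
        if "curve_planes" in kw:
            kw["curve_planes"] = tuple((p[0], float(p[1])) for p in kw["curve_planes"])
        return cls(**kw)


def make_template(spec: PhantomSpec) -> Tuple[TriangleMesh, Cage]:
    """Watertight phantom mesh plus enclosing box-lattice cage (unbound)."""
    if spec.shape == "sphere":
        mesh = icosphere(spec.size_mm[0], spec.subdivisions)
    elif spec.shape == "ellipsoid":
        mesh = _ellipsoid(spec.size_mm[:3], spec.subdivisions)
    elif spec.shape == "capsule":
        mesh = _capsule(spec.size_mm[0], spec.size_mm[1], spec.subdivisions)
    elif spec.shape == "bent_tube":
        angle = spec.size_mm[2] if len(spec.size_mm) > 2 else 1.2
        mesh = _bent_tube(spec.size_mm[0], spec.size_mm[1], angle, spec.subdivisions)
    else:
        raise ParameterError(f"unknown phantom shape {spec.shape!r}")
    lo, hi = mesh.bounds()
    pad = spec.cage_clearance * (hi - lo)
    if np.any(pad <= 0.04 * (hi - lo)):
        raise ParameterError("cage clearance must exceed 5% of the mesh extent")
    cage = box_lattice_cage(lo - pad, hi + pad, spec.cage_subdivisions)
    inside = points_in_mesh(mesh.vertices, cage.vertices, cage.triangles)
    if not inside.all():
        raise GeometryError("generated cage fails to enclose the phantom mesh")
    return mesh, cage


def make_bound_template(spec: PhantomSpec, resolution: int = 32) -> Template:
    mesh, cage = make_template(spec)
    return bind_template(mesh, cage, resolution)


def make_ground_truth_sequence(
    template: Template, spec: PhantomSpec
) -> Tuple[List[np.ndarray], List[TriangleMesh]]:
    """Smooth per-frame target cages and the meshes they induce.

    Targets are produced through the template's own cage, so a perfect fit
    is representable; the deformation is a slow similarity ramp plus
    seeded low-frequency per-vertex cage offsets.
    """
    rng = np.random.default_rng(spec.seed)
    n_c = template.cage.n_vertices
    directions = rng.normal(size=(n_c, 3))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_c)

    cages: List[np.ndarray] = []
    meshes: List[TriangleMesh] = []
    centroid = template.cage.vertices.mean(axis=0)
    for t in range(spec.frames):
        s = t / (spec.frames - 1) if spec.frames > 1 else 0.0
        ramp = np.sin(np.pi * s)
        xf = SimilarityTransform.from_axis_angle(
            (0.0, 1.0, 0.0),
            spec.rotation_amplitude_rad * ramp,
            scale=1.0 + spec.scale_amplitude * ramp,
            translation=np.asarray(spec.translation_amplitude_mm) * s,
        )
        verts = xf.apply(template.cage.vertices - centroid) + centroid
        wobble = spec.cage_offset_amplitude_mm * np.sin(
            2.0 * np.pi * s + phases
        )[:, None] * directions
        verts = verts + wobble * ramp
        cages.append(verts)
        mesh = deform_mesh(template, verts)
        tri_cage = template.cage.with_vertices(verts)
        inside = points_in_mesh(mesh.vertices, tri_cage.vertices, tri_cage.triangles)
        if not inside.all():
            raise GeometryError(
                f"frame {t}: ground-truth deformation ejects the mesh from the cage"
            )
        meshes.append(mesh)
    return cages, meshes


# ---------------------------------------------------------------------------
# curve sampling from ground-truth surfaces
# ---------------------------------------------------------------------------


def cross_section_loops(mesh: TriangleMesh, plane: CrossSectionPlane) -> List[np.ndarray]:
    """Closed intersection loops of the mesh with an axis-aligned plane.

    Returns each loop as an ordered (n, 3) polyline (not repeated at the
    end). Requires a watertight mesh so every cut triangle chains up.
    """
    axis_of = {"XY": 2, "YZ": 0, "ZX": 1}
    w_axis = axis_of[plane.axis]
    sd = mesh.vertices[:, w_axis] - plane.offset
    # nudge exact-zero vertices off the plane, deterministically
    scale = max(np.ptp(mesh.vertices, axis=0).max(), 1.0)
    sd = np.where(np.abs(sd) < 1e-12 * scale, 1e-12 * scale, sd)

    tris = mesh.triangles
    s = sd[tris]
    crossing = ~(np.all(s > 0, axis=1) | np.all(s < 0, axis=1))
    segments: List[Tuple[Tuple[int, int], Tuple[int, int]]] = []
    seg_points: Dict[Tuple[int, int], np.ndarray] = {}
    for tri in tris[crossing]:
        pts_on_edges = []
        for a, b in ((0, 1), (1, 2), (2, 0)):
            va, vb = tri[a], tri[b]
            da, db = sd[va], sd[vb]
            if (da > 0) != (db > 0):
                tpar = da / (da - db)
                p = mesh.vertices[va] + tpar * (mesh.vertices[vb] - mesh.vertices[va])
                key = (min(va, vb), max(va, vb))
                seg_points[key] = p
                pts_on_edges.append(key)
        if len(pts_on_edges) == 2:
            segments.append((pts_on_edges[0], pts_on_edges[1]))

    # chain edge-keys into loops
    adjacency: Dict[Tuple[int, int], List[Tuple[int, int]]] = {}
    for a, b in segments:
        adjacency.setdefault(a, []).append(b)
        adjacency.setdefault(b, []).append(a)
    visited = set()
    loops: List[np.ndarray] = []
    for start in adjacency:
        if start in visited:
            continue
        loop = [start]
        visited.add(start)
        current = start
        while True:
            nxt = [n for n in adjacency[current] if n not in visited]
            if not nxt:
                break
            current = nxt[0]
            visited.add(current)
            loop.append(current)
        if len(loop) >= 3:
            loops.append(np.asarray([seg_points[k] for k in loop]))
    loops.sort(key=lambda lp: -_loop_length(lp))
    return loops


def _loop_length(loop: np.ndarray) -> float:
    d = np.diff(np.vstack([loop, loop[0]]), axis=0)
    return float(np.linalg.norm(d, axis=1).sum())


def _subsample_loop(loop: np.ndarray, count: int) -> np.ndarray:
    closed = np.vstack([loop, loop[0]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    positions = np.linspace(0.0, s[-1], count, endpoint=False)
    out = np.empty((count, 3))
    for c in range(3):
        out[:, c] = np.interp(positions, s, closed[:, c])
    return out


def sample_constraint_curves(
    mesh: TriangleMesh,
    planes: Sequence[CrossSectionPlane],
    points_per_curve: int = 8,
    jitter_mm: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    frame: Optional[int] = None,
    id_prefix: str = "gt",
) -> List[CurveConstraint]:
    """Sample closed constraint curves from a target surface.

    Takes the largest cross-section loop per plane, subsamples it at equal
    arc length to the requested control-point count, and adds bounded
    in-plane jitter (imprecise-click model).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    out = []
    for n, plane in enumerate(planes):
        loops = cross_section_loops(mesh, plane)
        if not loops:
            raise CurveCageError(
                f"plane {plane.axis}@{plane.offset} misses the target mesh"
            )
        cp3 = _subsample_loop(loops[0], points_per_curve)
        cp2 = plane.project(cp3)
        if jitter_mm > 0:
            angle = rng.uniform(0, 2 * np.pi, size=len(cp2))
            radius = jitter_mm * np.sqrt(rng.uniform(0, 1, size=len(cp2)))
            cp2 = cp2 + radius[:, None] * np.stack(
                [np.cos(angle), np.sin(angle)], axis=1
            )
        out.append(
            CurveConstraint(
                id=f"{id_prefix}_{plane.axis}{n}" + (f"_f{frame}" if frame is not None else ""),
                plane=plane,
                control_points=cp2,
                closed=True,
                frame=frame,
            )
        )
    return out


def rasterize_phantom_labels(
    meshes: Sequence[TriangleMesh], grid: ReferenceGrid, label: int = 1
) -> List[LabelVolume]:
    return [voxelize_mesh(m, grid, label=label, frame=t) for t, m in enumerate(meshes)]


def dice(a: LabelVolume, b: LabelVolume) -> float:
    """Dice overlap coefficient of two label volumes on the same grid."""
    ma = a.mask > 0
    mb = b.mask > 0
    denom = ma.sum() + mb.sum()
    if denom == 0:
        return 1.0
    return 2.0 * float(np.logical_and(ma, mb).sum()) / float(denom)


# ---------------------------------------------------------------------------
# fixture-set emission (CLI `curvecage synth`)
# ---------------------------------------------------------------------------


def write_fixture_set(
    spec: PhantomSpec,
    out_dir: str,
    binding_resolution: int = 32,
    grid: Optional[ReferenceGrid] = None,
    write_labels: bool = True,
) -> dict:
    """Emit template, cage, curves.json, grid.json, ground truth + manifest."""
    os.makedirs(out_dir, exist_ok=True)
    template = make_bound_template(spec, binding_resolution)
    cages, gt_meshes = make_ground_truth_sequence(template, spec)
    rng = np.random.default_rng(spec.seed + 1)
    planes = [CrossSectionPlane(a, o) for a, o in spec.curve_planes]

    curves: List[CurveConstraint] = []
    shared: List[SharedCurve] = []
    if spec.shared_keyframes:
        per_plane_keyframes: List[Dict[int, np.ndarray]] = [dict() for _ in planes]
        for t in spec.shared_keyframes:
            cs = sample_constraint_curves(
                gt_meshes[t], planes, spec.points_per_curve, spec.jitter_mm, rng
            )
            for i, c in enumerate(cs):
                per_plane_keyframes[i][t] = c.control_points
        shared = [
            SharedCurve(f"shared_{p.axis}{i}", p, per_plane_keyframes[i])
            for i, p in enumerate(planes)
        ]
    else:
        for t in range(spec.frames):
            curves += sample_constraint_curves(
                gt_meshes[t], planes, spec.points_per_curve, spec.jitter_mm, rng,
                frame=t,
            )

    save_mesh(os.path.join(out_dir, "template_mesh.obj"), template.mesh)
    save_cage(os.path.join(out_dir, "template_cage.obj"), template.cage)
    save_curves_json(os.path.join(out_dir, "curves.json"), spec.frames, curves, shared)
    for t, m in enumerate(gt_meshes):
        save_mesh(os.path.join(out_dir, f"gt_frame{t:03d}.obj"), m)

    if grid is None:
        lo = np.min([m.bounds()[0] for m in gt_meshes], axis=0) - 3.0
        hi = np.max([m.bounds()[1] for m in gt_meshes], axis=0) + 3.0
        spacing = np.ones(3)
        dims = tuple(int(np.ceil(e)) + 1 for e in (hi - lo))
        grid = ReferenceGrid(dims, spacing, lo)
    save_grid_json(os.path.join(out_dir, "grid.json"), grid)
    if write_labels:
        import nibabel as nib

        for t, lab in enumerate(rasterize_phantom_labels(gt_meshes, grid)):
            img = nib.Nifti1Image(lab.mask.astype(np.uint8), grid.affine)
            nib.save(img, os.path.join(out_dir, f"gt_frame{t:03d}.nii"))
    manifest = {
        "spec": spec.to_dict(),
        "binding_resolution": binding_resolution,
        "binding_provenance": template.binding.provenance,
        "files": sorted(set(os.listdir(out_dir)) | {"manifest.json"}),
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest
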