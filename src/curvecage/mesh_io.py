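"""ASCII OBJ and PLY mesh reading/writing.

Only the geometric subset is handled (positions + faces); normals, texture
coordinates and colors are ignored on read and never written.
"""

from __future__ import annotations

import os
from typing import List, Sequence, Tuple

import numpy as np

from .core_model import Cage, TriangleMesh
from .errors import ParameterError

__all__ = [
    "read_mesh_file",
    "write_mesh_file",
    "load_mesh",
    "load_cage",
    "save_mesh",
    "save_cage",
]


def _read_obj(path: str) -> Tuple[np.ndarray, List[List[int]]]:
    verts, faces = [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "v":
                verts.append([float(x) for x in parts[1:4]])
            elif parts[0] == "f":
                face = []
                for token in parts[1:]:
                    idx = int(token.split("/")[0])
                    face.append(idx - 1 if idx > 0 else len(verts) + idx)
                faces.append(face)
    return np.asarray(verts, dtype=float), faces


def _read_ply(path: str) -> Tuple[np.ndarray, List[List[int]]]:
    with open(path) as fh:
        if fh.readline().strip() != "ply":
            raise ParameterError(f"{path}: not a PLY file")
        fmt = fh.readline().split()
        if len(fmt) < 2 or fmt[1] != "ascii":
            raise ParameterError(f"{path}: only ASCII PLY is supported")
        n_vert = n_face = 0
        element = None
        vert_props: List[str] = []
        for line in fh:
            parts = line.split()
            if not parts or parts[0] == "comment":
                continue
            if parts[0] == "element":
                element = parts[1]
                if element == "vertex":
                    n_vert = int(parts[2])
                elif element == "face":
                    n_face = int(parts[2])
            elif parts[0] == "property" and element == "vertex":
                vert_props.append(parts[-1])
            elif parts[0] == "end_header":
                break
        ix = {p: i for i, p in enumerate(vert_props)}
        if not all(k in ix for k in ("x", "y", "z")):
            raise ParameterError(f"{path}: vertex element lacks x/y/z")
        verts = np.empty((n_vert, 3), dtype=float)
        for i in range(n_vert):
            vals = fh.readline().split()
            verts[i] = (float(vals[ix["x"]]), float(vals[ix["y"]]), float(vals[ix["z"]]))
        faces = []
        for _ in range(n_face):
            vals = fh.readline().split()
            n = int(vals[0])
            faces.append([int(v) for v in vals[1 : 1 + n]])
    return verts, faces


def read_mesh_file(path: str) -> Tuple[np.ndarray, List[List[int]]]:
    """Read an ASCII OBJ/PLY file into (vertices, polygon faces)."""
    ext = os.path.splitext(path)[1].lower()
    if ext == ".obj":
        return _read_obj(path)
    if ext == ".ply":
        return _read_ply(path)
    raise ParameterError(f"unsupported mesh format: {ext} (use .obj or .ply)")


def write_mesh_file(path: str, vertices: np.ndarray, faces: Sequence[Sequence[int]]):
    """Write vertices + polygon faces as ASCII OBJ or PLY by extension."""
    ext = os.path.splitext(path)[1].lower()
    vertices = np.asarray(vertices, dtype=float)
    if ext == ".obj":
        with open(path, "w") as fh:
            for v in vertices:
                fh.write(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
            for f in faces:
                fh.write("f " + " ".join(str(int(i) + 1) for i in f) + "\n")
    elif ext == ".ply":
        with open(path, "w") as fh:
            fh.write("ply\nformat ascii 1.0\n")
            fh.write(f"element vertex {len(vertices)}\n")
            fh.write("property float x\nproperty float y\nproperty float z\n")
            fh.write(f"element face {len(faces)}\n")
            fh.write("property list uchar int vertex_indices\nend_header\n")
            for v in vertices:
                fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
            for f in faces:
                fh.write(f"{len(f)} " + " ".join(str(int(i)) for i in f) + "\n")
    else:
        raise ParameterError(f"unsupported mesh format: {ext} (use .obj or .ply)")


def load_mesh(path: str, validate: bool = True) -> TriangleMesh:
    """Load a template mesh; validates watertightness and self-intersection."""
    verts, faces = read_mesh_file(path)
    tris = []
    for f in faces:
        for k in range(1, len(f) - 1):
            tris.append((f[0], f[k], f[k + 1]))
    mesh = TriangleMesh(verts, np.asarray(tris, dtype=np.int64),
                        name=os.path.basename(path))
    if validate:
        mesh.validate_closed()
    return mesh


def load_cage(path: str) -> Cage:
    verts, faces = read_mesh_file(path)
    return Cage(verts, tuple(tuple(f) for f in faces), name=os.path.basename(path))


def save_mesh(path: str, mesh: TriangleMesh) -> None:
    write_mesh_file(path, mesh.vertices, mesh.triangles.tolist())


def save_cage(path: str, cage: Cage) -> None:
    write_mesh_file(path, cage.vertices, cage.faces)
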