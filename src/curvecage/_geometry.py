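"""Low-level vectorized mesh geometry kernels.

Everything here operates on raw ``(N, 3)`` float arrays and ``(M, 3)`` int
index arrays; the typed wrappers live in :mod:`curvecage.core_model`.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .errors import GeometryError, TopologyError

__all__ = [
    "closest_point_triangles",
    "edge_counts",
    "is_watertight",
    "points_in_mesh",
    "self_intersections",
    "triangle_aabb_overlap",
]


def closest_point_triangles(points: np.ndarray, tri_xyz: np.ndarray):
    """Closest point on each triangle for each query point.

    Parameters
    ----------
    points : (K, 3) array
    tri_xyz : (M, 3, 3) array of triangle vertex positions

    Returns
    -------
    dist2 : (K, M) squared distances
    bary : (K, M, 3) barycentric coordinates of the footpoints
    """
    a = tri_xyz[:, 0][None, :, :]  # (1,M,3)
    b = tri_xyz[:, 1][None, :, :]
    c = tri_xyz[:, 2][None, :, :]
    p = points[:, None, :]  # (K,1,3)

    ab = b - a
    ac = c - a
    ap = p - a

    d1 = np.einsum("kmi,kmi->km", np.broadcast_arrays(ab, ap)[0], ap)
    d2 = np.einsum("kmi,kmi->km", np.broadcast_arrays(ac, ap)[0], ap)
    bp = p - b
    d3 = np.einsum("kmi,kmi->km", np.broadcast_arrays(ab, bp)[0], bp)
    d4 = np.einsum("kmi,kmi->km", np.broadcast_arrays(ac, bp)[0], bp)
    cp = p - c
    d5 = np.einsum("kmi,kmi->km", np.broadcast_arrays(ab, cp)[0], cp)
    d6 = np.einsum("kmi,kmi->km", np.broadcast_arrays(ac, cp)[0], cp)

    K, M = d1.shape
    u = np.empty((K, M))
    v = np.empty((K, M))

    # region vertex A
    mask_a = (d1 <= 0) & (d2 <= 0)
    # region vertex B
    mask_b = (d3 >= 0) & (d4 <= d3)
    # region vertex C
    mask_c = (d6 >= 0) & (d5 <= d6)
    # region edge AB
    vc = d1 * d4 - d3 * d2
    mask_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    # region edge AC
    vb = d5 * d2 - d1 * d6
    mask_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    # region edge BC
    va = d3 * d6 - d5 * d4
    mask_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)

    with np.errstate(divide="ignore", invalid="ignore"):
        t_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
        t_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
        denom_bc = (d4 - d3) + (d5 - d6)
        t_bc = np.where(denom_bc != 0, (d4 - d3) / denom_bc, 0.0)
        denom = va + vb + vc
        v_in = np.where(denom != 0, vb / denom, 1.0 / 3.0)
        w_in = np.where(denom != 0, vc / denom, 1.0 / 3.0)

    # fill interior first, then override by priority of the region cascade
    u_int = 1.0 - v_in - w_in
    u[:] = u_int
    v[:] = v_in
    w = np.empty_like(u)
    w[:] = w_in

    def _set(mask, uu, vv):
        u[mask] = uu if np.isscalar(uu) else uu[mask]
        v[mask] = vv if np.isscalar(vv) else vv[mask]
        w[mask] = 1.0
        w[mask] -= u[mask] + v[mask]

    _set(mask_bc, 0.0, 1.0 - t_bc)
    _set(mask_ac, 1.0 - t_ac, 0.0)
    _set(mask_ab, 1.0 - t_ab, t_ab)
    _set(mask_c, 0.0, 0.0)
    _set(mask_b, 0.0, 1.0)
    _set(mask_a, 1.0, 0.0)

    bary = np.stack([u, v, w], axis=-1)
    np.clip(bary, 0.0, 1.0, out=bary)
    bary /= bary.sum(axis=-1, keepdims=True)

    foot = np.einsum("km,mi->kmi", bary[:, :, 0], tri_xyz[:, 0])
    foot += np.einsum("km,mi->kmi", bary[:, :, 1], tri_xyz[:, 1])
    foot += np.einsum("km,mi->kmi", bary[:, :, 2], tri_xyz[:, 2])
    diff = foot - p
    dist2 = np.einsum("kmi,kmi->km", diff, diff)
    return dist2, bary


def edge_counts(triangles: np.ndarray):
    """Undirected edge -> incidence count over a triangle list."""
    e = np.concatenate(
        [triangles[:, [0, 1]], triangles[:, [1, 2]], triangles[:, [2, 0]]]
    )
    e = np.sort(e, axis=1)
    uniq, counts = np.unique(e, axis=0, return_counts=True)
    return uniq, counts


def is_watertight(triangles: np.ndarray) -> bool:
    """Every undirected edge shared by exactly two triangles, and every
    directed edge used exactly once (consistent orientation)."""
    if len(triangles) == 0:
        return False
    _, counts = edge_counts(np.asarray(triangles))
    if not np.all(counts == 2):
        return False
    d = np.concatenate(
        [triangles[:, [0, 1]], triangles[:, [1, 2]], triangles[:, [2, 0]]]
    )
    _, dcounts = np.unique(d, axis=0, return_counts=True)
    return bool(np.all(dcounts == 1))


def points_in_mesh(
    points: np.ndarray,
    vertices: np.ndarray,
    triangles: np.ndarray,
    *,
    _eps_scale: float = 1.0,
) -> np.ndarray:
    """Even-odd inside test with +x rays.

    Rays are deterministically perturbed in (y, z) by an irrational
    sub-nanometre offset to avoid edge/vertex hits; rows that still produce
    a near-degenerate hit are retried with a larger offset.
    """
    points = np.asarray(points, dtype=float)
    tv = vertices[triangles]  # (M,3,3)
    scale = max(np.ptp(vertices, axis=0).max(), 1.0)
    eps = np.array([np.sqrt(2.0), np.sqrt(3.0)]) * 1e-9 * scale * _eps_scale
    py = points[:, 1] + eps[0]
    pz = points[:, 2] + eps[1]

    ay, az = tv[:, 0, 1], tv[:, 0, 2]
    by, bz = tv[:, 1, 1], tv[:, 1, 2]
    cy, cz = tv[:, 2, 1], tv[:, 2, 2]
    area2 = (by - ay) * (cz - az) - (bz - az) * (cy - ay)  # (M,)

    degenerate_rows = np.zeros(len(points), dtype=bool)
    ymin = tv[:, :, 1].min(axis=1)
    ymax = tv[:, :, 1].max(axis=1)
    zmin = tv[:, :, 2].min(axis=1)
    zmax = tv[:, :, 2].max(axis=1)

    crossings = np.zeros(len(points), dtype=np.int64)
    tiny = 1e-13
    for m in range(len(triangles)):
        if abs(area2[m]) < tiny * scale * scale:
            continue  # ray lies (almost) in the triangle plane: measure zero
        sel = (
            (py >= ymin[m] - 0.0)
            & (py <= ymax[m])
            & (pz >= zmin[m])
            & (pz <= zmax[m])
        )
        if not sel.any():
            continue
        qy, qz = py[sel], pz[sel]
        w0 = ((by[m] - qy) * (cz[m] - qz) - (bz[m] - qz) * (cy[m] - qy)) / area2[m]
        w1 = ((cy[m] - qy) * (az[m] - qz) - (cz[m] - qz) * (ay[m] - qy)) / area2[m]
        w2 = 1.0 - w0 - w1
        hit = (w0 > 0) & (w1 > 0) & (w2 > 0)
        near = (np.abs(w0) < 1e-7) | (np.abs(w1) < 1e-7) | (np.abs(w2) < 1e-7)
        if near.any():
            idx = np.flatnonzero(sel)
            degenerate_rows[idx[near]] = True
        if not hit.any():
            continue
        xhit = (
            w0[hit] * tv[m, 0, 0] + w1[hit] * tv[m, 1, 0] + w2[hit] * tv[m, 2, 0]
        )
        idx = np.flatnonzero(sel)[hit]
        crossings[idx] += (xhit > points[idx, 0]).astype(np.int64)

    inside = (crossings % 2) == 1
    if degenerate_rows.any() and _eps_scale < 1e6:
        redo = points[degenerate_rows]
        inside[degenerate_rows] = points_in_mesh(
            redo, vertices, triangles, _eps_scale=_eps_scale * 977.0
        )
    return inside


def triangle_aabb_overlap(tri_xyz: np.ndarray, centers: np.ndarray, half: np.ndarray):
    """Separating-axis triangle vs axis-aligned-box overlap test.

    Parameters
    ----------
    tri_xyz : (3, 3) one triangle
    centers : (K, 3) box centers
    half : (3,) box half extents

    Returns
    -------
    (K,) bool overlap mask
    """
    v = tri_xyz[None, :, :] - centers[:, None, :]  # (K,3,3)
    hx, hy, hz = half

    out = np.ones(len(centers), dtype=bool)
    # axis tests: box face normals
    for ax, h in ((0, hx), (1, hy), (2, hz)):
        mn = v[:, :, ax].min(axis=1)
        mx = v[:, :, ax].max(axis=1)
        out &= ~((mn > h) | (mx < -h))
    if not out.any():
        return out

    e = np.array(
        [tri_xyz[1] - tri_xyz[0], tri_xyz[2] - tri_xyz[1], tri_xyz[0] - tri_xyz[2]]
    )  # (3,3)
    # triangle plane test
    n = np.cross(e[0], e[1])
    d = np.einsum("ki,i->k", v[:, 0, :], n)
    r = hx * abs(n[0]) + hy * abs(n[1]) + hz * abs(n[2])
    out &= np.abs(d) <= r
    if not out.any():
        return out

    # 9 cross-axis tests
    half_arr = np.array([hx, hy, hz])
    for i in range(3):  # edge
        for ax in range(3):  # box axis
            axis = np.zeros(3)
            axis[ax] = 1.0
            a = np.cross(e[i], axis)
            if np.allclose(a, 0.0):
                continue
            proj = np.einsum("kji,i->kj", v, a)  # (K,3)
            mn = proj.min(axis=1)
            mx = proj.max(axis=1)
            r = np.dot(half_arr, np.abs(a))
            out &= ~((mn > r) | (mx < -r))
    return out


def _tri_tri_intersect(t1: np.ndarray, t2: np.ndarray) -> bool:
    """Möller-style triangle-triangle intersection (proper crossings only)."""

    def _plane_side(tri, other):
        n = np.cross(tri[1] - tri[0], tri[2] - tri[0])
        d = -np.dot(n, tri[0])
        s = other @ n + d
        return n, d, s

    n1, d1, s2 = _plane_side(t1, t2)
    if np.all(s2 > 1e-12) or np.all(s2 < -1e-12):
        return False
    n2, d2, s1 = _plane_side(t2, t1)
    if np.all(s1 > 1e-12) or np.all(s1 < -1e-12):
        return False
    direction = np.cross(n1, n2)
    if np.linalg.norm(direction) < 1e-14:
        return False  # coplanar pairs ignored (handled by edge sharing rules)

    def _interval(tri, s):
        # project onto the intersection line, find the crossing interval
        proj = tri @ direction
        pos = []
        for i in range(3):
            j = (i + 1) % 3
            if (s[i] > 0) != (s[j] > 0) and abs(s[i] - s[j]) > 1e-300:
                t = s[i] / (s[i] - s[j])
                pos.append(proj[i] + t * (proj[j] - proj[i]))
        if len(pos) < 2:
            return None
        return min(pos), max(pos)

    i1 = _interval(t1, s1)
    i2 = _interval(t2, s2)
    if i1 is None or i2 is None:
        return False
    lo = max(i1[0], i2[0])
    hi = min(i1[1], i2[1])
    return hi - lo > 1e-12


def self_intersections(vertices: np.ndarray, triangles: np.ndarray, limit: int = 1):
    """Return up to ``limit`` pairs of non-adjacent intersecting triangles."""
    tv = vertices[triangles]
    lo = tv.min(axis=1)
    hi = tv.max(axis=1)
    centers = 0.5 * (lo + hi)
    radius = 0.5 * np.linalg.norm(hi - lo, axis=1)
    tree = cKDTree(centers)
    rmax = radius.max()
    pairs = tree.query_pairs(2.0 * rmax, output_type="ndarray")
    found = []
    for i, j in pairs:
        if np.any((lo[i] > hi[j]) | (lo[j] > hi[i])):
            continue
        if len(set(triangles[i]) & set(triangles[j])) > 0:
            continue  # adjacent triangles touch by construction
        if _tri_tri_intersect(tv[i], tv[j]):
            found.append((int(i), int(j)))
            if len(found) >= limit:
                break
    return found


def require_clean_mesh(vertices: np.ndarray, triangles: np.ndarray, name: str = "mesh"):
    """Watertightness + self-intersection gate used at template load time."""
    if not is_watertight(triangles):
        raise TopologyError(f"{name} is not watertight")
    areas = 0.5 * np.linalg.norm(
        np.cross(
            vertices[triangles[:, 1]] - vertices[triangles[:, 0]],
            vertices[triangles[:, 2]] - vertices[triangles[:, 0]],
        ),
        axis=1,
    )
    bad = np.flatnonzero(areas <= 0)
    if bad.size:
        raise GeometryError(f"{name} has zero-area triangle {int(bad[0])}")
    hits = self_intersections(vertices, triangles, limit=1)
    if hits:
        raise GeometryError(f"{name} self-intersects at triangle pair {hits[0]}")
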