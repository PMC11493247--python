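"""Planar constraint curves: interpolation, resampling, temporal sharing.

Control points on axis-aligned cross-sections are interpolated with
curvature-extremum quadratic splines ("κ-curves": each control point is the
curvature maximum of its quadratic Bézier segment, found by fixed-point
iteration), densely sampled, and resampled at equal arc-length intervals
into the constraint points that drive the cage fit. A shared curve is
duplicated across all frames with control points linearly interpolated
between its keyframes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import ConstraintError, CurveError, ParameterError

__all__ = [
    "CrossSectionPlane",
    "CurveConstraint",
    "SharedCurve",
    "ConstraintPointSet",
    "interpolate_curve",
    "resample_equal_interval",
    "realize_shared_curve",
    "collect_frame_constraints",
    "load_curves_json",
    "save_curves_json",
]

_PLANE_AXES = {"XY": (0, 1, 2), "YZ": (1, 2, 0), "ZX": (2, 0, 1)}


@dataclass(frozen=True)
class CrossSectionPlane:
    """Axis-aligned cross-section: one of the XY / YZ / ZX planes.

    In-plane (u, v) axes are the plane's two world axes in the order the
    name spells them (XY -> (x, y), YZ -> (y, z), ZX -> (z, x)); ``offset``
    positions the plane along the remaining axis.
    """

    axis: str
    offset: float = 0.0

    def __post_init__(self):
        if self.axis not in _PLANE_AXES:
            raise ParameterError(f"plane axis must be XY, YZ or ZX, got {self.axis!r}")
        object.__setattr__(self, "offset", float(self.offset))

    def lift(self, uv: np.ndarray) -> np.ndarray:
        """Map (n, 2) in-plane points to (n, 3) world points."""
        uv = np.atleast_2d(np.asarray(uv, dtype=float))
        ua, va, wa = _PLANE_AXES[self.axis]
        out = np.empty((len(uv), 3))
        out[:, ua] = uv[:, 0]
        out[:, va] = uv[:, 1]
        out[:, wa] = self.offset
        return out

    def project(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        ua, va, _ = _PLANE_AXES[self.axis]
        return np.stack([xyz[:, ua], xyz[:, va]], axis=1)


@dataclass(frozen=True)
class CurveConstraint:
    """Ordered planar control points defining one constraint curve."""

    id: str
    plane: CrossSectionPlane
    control_points: np.ndarray  # (n, 2) in-plane mm
    closed: bool = True
    frame: Optional[int] = None  # None for curves not pinned to a frame

    def __post_init__(self):
        cp = np.atleast_2d(np.asarray(self.control_points, dtype=float))
        if cp.ndim != 2 or cp.shape[1] != 2:
            raise CurveError("control points must be (n, 2)")
        if len(cp) < 3:
            raise CurveError(
                f"curve {self.id!r}: needs >= 3 control points, got {len(cp)}"
            )
        d = np.linalg.norm(np.diff(cp, axis=0), axis=1)
        if self.closed:
            d = np.append(d, np.linalg.norm(cp[0] - cp[-1]))
        if np.any(d < 1e-12):
            raise CurveError(f"curve {self.id!r}: duplicate consecutive control points")
        if len(np.unique(cp.round(decimals=9), axis=0)) != len(cp):
            raise CurveError(f"curve {self.id!r}: control points must be distinct")
        object.__setattr__(self, "control_points", cp)

    def control_points_3d(self) -> np.ndarray:
        return self.plane.lift(self.control_points)


@dataclass(frozen=True)
class SharedCurve:
    """A curve duplicated to every frame; keyframes hold user-set shapes."""

    id: str
    plane: CrossSectionPlane
    keyframes: Dict[int, np.ndarray]  # frame -> (n, 2)
    closed: bool = True

    def __post_init__(self):
        if not self.keyframes:
            raise CurveError(f"shared curve {self.id!r}: needs >= 1 keyframe")
        kf = {}
        counts = set()
        for t, cp in self.keyframes.items():
            cp = np.atleast_2d(np.asarray(cp, dtype=float))
            counts.add(len(cp))
            kf[int(t)] = cp
        if len(counts) != 1:
            raise CurveError(
                f"shared curve {self.id!r}: keyframe control-point counts differ "
                f"({sorted(counts)})"
            )
        object.__setattr__(self, "keyframes", kf)


@dataclass(frozen=True)
class ConstraintPointSet:
    """Equal-interval resampled constraint points for one frame."""

    points: np.ndarray  # (N_p, 3) mm
    sources: Tuple[str, ...] = ()
    per_curve_slices: Tuple[Tuple[str, int, int], ...] = ()

    def __post_init__(self):
        p = np.atleast_2d(np.asarray(self.points, dtype=float))
        object.__setattr__(self, "points", p)

    def __len__(self) -> int:
        return len(self.points)


# ---------------------------------------------------------------------------
# curvature-extremum quadratic spline (κ-curve) construction
# ---------------------------------------------------------------------------


def _tri_area(a, b, c):
    """Unsigned 2D triangle areas; inputs (n, 2)."""
    return 0.5 * np.abs(
        (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1])
        - (b[:, 1] - a[:, 1]) * (c[:, 0] - a[:, 0])
    )


def _max_curvature_parameter(c0, c2, p):
    """Root in [0, 1] of the cubic placing p at the curvature extremum.

    For a quadratic Bézier through p with endpoints c0, c2, the parameter t
    at which p can sit at maximum curvature satisfies
    ``|c2-c0|^2 t^3 + 3<c2-c0, c0-p> t^2 + <3c0-2p-c2, c0-p> t - |c0-p|^2 = 0``.
    """
    n = len(p)
    e = c2 - c0
    q = c0 - p
    a3 = np.einsum("ij,ij->i", e, e)
    a2 = 3.0 * np.einsum("ij,ij->i", e, q)
    a1 = np.einsum("ij,ij->i", 3 * c0 - 2 * p - c2, q)
    a0 = -np.einsum("ij,ij->i", q, q)
    t_out = np.full(n, 0.5)
    for i in range(n):
        coeffs = np.array([a3[i], a2[i], a1[i], a0[i]])
        nz = np.flatnonzero(np.abs(coeffs) > 1e-14)
        if nz.size == 0:
            continue  # fully degenerate: keep 0.5
        roots = np.roots(coeffs[nz[0]:])
        real = roots[np.abs(roots.imag) < 1e-8].real
        ok = real[(real > -1e-9) & (real < 1 + 1e-9)]
        if ok.size:
            # the construction admits a single root in [0,1]; clamp jitter
            t_out[i] = float(np.clip(ok[np.argmin(np.abs(ok - 0.5))], 1e-9, 1 - 1e-9))
    return t_out


def _kappa_control_points(points: np.ndarray, closed: bool,
                          tol: float = 1e-6, max_iter: int = 50):
    """Fixed-point iteration for the middle Bézier control points.

    Returns per-segment quadratic control triples (c0, b, c2) as three
    (n_seg, 2) arrays.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if closed:
        n_seg = n
        p_seg = pts
    else:
        n_seg = n - 2
        p_seg = pts[1:-1]
        if n_seg < 1:
            raise CurveError("open curve needs >= 3 control points")

    b = p_seg.copy()
    n_lam = n_seg if closed else n_seg - 1
    lam = np.full(max(n_lam, 0), 0.5)

    def endpoints(b, lam):
        """Segment endpoints from middle points and junction ratios."""
        if closed:
            bn = np.roll(b, -1, axis=0)
            joins = (1 - lam[:, None]) * b + lam[:, None] * bn  # junction i|i+1
            c2 = joins
            c0 = np.roll(joins, 1, axis=0)
        else:
            c0 = np.empty_like(b)
            c2 = np.empty_like(b)
            c0[0] = pts[0]
            c2[-1] = pts[-1]
            if n_lam > 0:
                joins = (1 - lam[:, None]) * b[:-1] + lam[:, None] * b[1:]
                c2[:-1] = joins
                c0[1:] = joins
        return c0, c2

    for _ in range(max_iter):
        c0, c2 = endpoints(b, lam)
        # step 1: junction ratios equalizing endpoint curvature
        if n_lam > 0:
            if closed:
                b_i, b_n = b, np.roll(b, -1, axis=0)
                left = c0
                right = np.roll(c2, -1, axis=0)
            else:
                b_i, b_n = b[:-1], b[1:]
                left = c0[:-1]
                right = c2[1:]
            d1 = _tri_area(left, b_i, b_n)
            d2 = _tri_area(b_i, b_n, right)
            s1, s2 = np.sqrt(d1), np.sqrt(d2)
            denom = s1 + s2
            lam = np.where(denom > 1e-14, s1 / np.where(denom > 0, denom, 1.0), 0.5)
            c0, c2 = endpoints(b, lam)

        # step 2: curvature-extremum parameters
        t = _max_curvature_parameter(c0, c2, p_seg)

        # step 3: global linear solve so each segment passes through its point
        omt = 1.0 - t
        A = np.zeros((n_seg, n_seg))
        rhs = p_seg.copy()
        for i in range(n_seg):
            if closed:
                lam_prev = lam[(i - 1) % n_seg]
                lam_next = lam[i]
                A[i, (i - 1) % n_seg] += omt[i] ** 2 * (1 - lam_prev)
                A[i, i] += omt[i] ** 2 * lam_prev + 2 * t[i] * omt[i] \
                    + t[i] ** 2 * (1 - lam_next)
                A[i, (i + 1) % n_seg] += t[i] ** 2 * lam_next
            else:
                if i == 0:
                    rhs[i] = rhs[i] - omt[i] ** 2 * pts[0]
                    A[i, i] += 2 * t[i] * omt[i]
                else:
                    lam_prev = lam[i - 1]
                    A[i, i - 1] += omt[i] ** 2 * (1 - lam_prev)
                    A[i, i] += omt[i] ** 2 * lam_prev + 2 * t[i] * omt[i]
                if i == n_seg - 1:
                    rhs[i] = rhs[i] - t[i] ** 2 * pts[-1]
                else:
                    lam_next = lam[i]
                    A[i, i] += t[i] ** 2 * (1 - lam_next)
                    A[i, i + 1] += t[i] ** 2 * lam_next
        b_new = np.linalg.solve(A, rhs)
        delta = np.abs(b_new - b).max()
        b = b_new
        if delta < tol:
            break

    c0, c2 = endpoints(b, lam)
    return c0, b, c2


def _catmull_rom_centripetal(points: np.ndarray, closed: bool, samples: int):
    """Centripetal Catmull-Rom fallback (debug curve model)."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if closed:
        idx = lambda i: pts[i % n]
        n_seg = n
    else:
        idx = lambda i: pts[int(np.clip(i, 0, n - 1))]
        n_seg = n - 1
    out = []
    for i in range(n_seg):
        P0, P1, P2, P3 = idx(i - 1), idx(i), idx(i + 1), idx(i + 2)

        def tj(ti, a, bpt):
            return ti + np.linalg.norm(bpt - a) ** 0.5

        t0 = 0.0
        t1 = tj(t0, P0, P1)
        t2 = tj(t1, P1, P2)
        t3 = tj(t2, P2, P3)
        if t1 == t0 or t2 == t1 or t3 == t2:
            seg = np.linspace(P1, P2, samples, endpoint=False)
            out.append(seg)
            continue
        t = np.linspace(t1, t2, samples, endpoint=False)[:, None]
        A1 = (t1 - t) / (t1 - t0) * P0 + (t - t0) / (t1 - t0) * P1
        A2 = (t2 - t) / (t2 - t1) * P1 + (t - t1) / (t2 - t1) * P2
        A3 = (t3 - t) / (t3 - t2) * P2 + (t - t2) / (t3 - t2) * P3
        B1 = (t2 - t) / (t2 - t0) * A1 + (t - t0) / (t2 - t0) * A2
        B2 = (t3 - t) / (t3 - t1) * A2 + (t - t1) / (t3 - t1) * A3
        C = (t2 - t) / (t2 - t1) * B1 + (t - t1) / (t2 - t1) * B2
        out.append(C)
    poly = np.concatenate(out)
    if not closed:
        poly = np.vstack([poly, pts[-1]])
    return poly


def interpolate_curve(
    constraint: CurveConstraint,
    samples_per_segment: int = 32,
    model: str = "kappa",
) -> np.ndarray:
    """Densely sample the smooth interpolating curve as a 3D polyline.

    The curve passes through every control point in order; closed curves
    wrap. ``model`` selects the curvature-extremum quadratic spline
    (default) or the centripetal Catmull-Rom fallback.
    """
    if samples_per_segment < 2:
        raise ParameterError("samples_per_segment must be >= 2")
    cp = constraint.control_points
    if model == "catmull-rom":
        poly2 = _catmull_rom_centripetal(cp, constraint.closed, samples_per_segment)
    elif model == "kappa":
        c0, b, c2 = _kappa_control_points(cp, constraint.closed)
        t = np.linspace(0.0, 1.0, samples_per_segment, endpoint=False)
        w0 = (1 - t) ** 2
        w1 = 2 * t * (1 - t)
        w2 = t**2
        segs = (
            w0[None, :, None] * c0[:, None, :]
            + w1[None, :, None] * b[:, None, :]
            + w2[None, :, None] * c2[:, None, :]
        )  # (n_seg, samples, 2)
        poly2 = segs.reshape(-1, 2)
        if not constraint.closed:
            poly2 = np.vstack([poly2, c2[-1]])
    else:
        raise ParameterError(f"unknown curve model {model!r}")
    return constraint.plane.lift(poly2)


def resample_equal_interval(
    polyline: np.ndarray, interval: float, closed: bool = True,
    source_id: str = "curve",
) -> ConstraintPointSet:
    """Resample a polyline at arc-length positions 0, d, 2d, ...

    For closed polylines the wrap segment is included in the total length
    and the final sample is dropped when it lands within d/2 of the start.
    """
    if interval <= 0:
        raise ParameterError("resampling interval must be > 0")
    poly = np.atleast_2d(np.asarray(polyline, dtype=float))
    if closed and np.linalg.norm(poly[0] - poly[-1]) > 1e-12:
        poly = np.vstack([poly, poly[0]])
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= interval:
        logging.getLogger("curvecage").warning(
            "resampling interval %.3g mm >= curve length %.3g mm for %r; "
            "returning endpoints only", interval, total, source_id,
        )
        pts = np.vstack([poly[0], poly[-1]]) if not closed else poly[[0]]
        return ConstraintPointSet(pts, (source_id,),
                                  ((source_id, 0, len(pts)),))
    n = int(np.floor(total / interval + 1e-9))
    positions = interval * np.arange(n + 1)
    positions = positions[positions <= total + 1e-9]
    if closed and total - positions[-1] < 0.5 * interval:
        positions = positions[:-1]
    out = np.empty((len(positions), 3))
    for c in range(3):
        out[:, c] = np.interp(positions, s, poly[:, c])
    return ConstraintPointSet(out, (source_id,), ((source_id, 0, len(out)),))


def realize_shared_curve(
    shared: SharedCurve, t: int, total_frames: int
) -> CurveConstraint:
    """Materialize a shared curve at frame t.

    Keyframes are returned verbatim; between two keyframes control points
    are blended pointwise-linearly; outside the keyframe range the nearest
    keyframe is held constant.
    """
    if not (0 <= t < total_frames):
        raise ParameterError(f"frame {t} outside [0, {total_frames})")
    keys = sorted(shared.keyframes)
    if t in shared.keyframes:
        cp = shared.keyframes[t]
    elif t <= keys[0]:
        cp = shared.keyframes[keys[0]]
    elif t >= keys[-1]:
        cp = shared.keyframes[keys[-1]]
    else:
        i = int(np.searchsorted(keys, t)) - 1
        t0, t1 = keys[i], keys[i + 1]
        w = (t - t0) / (t1 - t0)
        cp = (1.0 - w) * shared.keyframes[t0] + w * shared.keyframes[t1]
    return CurveConstraint(
        id=f"{shared.id}@{t}", plane=shared.plane, control_points=cp,
        closed=shared.closed, frame=t,
    )


def collect_frame_constraints(
    curves: Sequence[CurveConstraint],
    shared_curves: Sequence[SharedCurve],
    t: int,
    total_frames: int,
    interval: float = 1.0,
    samples_per_segment: int = 32,
    model: str = "kappa",
) -> ConstraintPointSet:
    """Assemble the resampled constraint-point set for one frame."""
    frame_curves: List[CurveConstraint] = [
        c for c in curves if c.frame == t
    ] + [realize_shared_curve(s, t, total_frames) for s in shared_curves]
    if not frame_curves:
        raise ConstraintError(f"no constraint curves apply to frame {t}")
    chunks = []
    sources = []
    slices = []
    offset = 0
    for c in frame_curves:
        poly = interpolate_curve(c, samples_per_segment, model=model)
        ps = resample_equal_interval(poly, interval, c.closed, source_id=c.id)
        chunks.append(ps.points)
        sources.append(c.id)
        slices.append((c.id, offset, offset + len(ps)))
        offset += len(ps)
    return ConstraintPointSet(
        np.concatenate(chunks), tuple(sources), tuple(slices)
    )


# ---------------------------------------------------------------------------
# JSON schema
# ---------------------------------------------------------------------------


def _plane_to_json(p: CrossSectionPlane) -> dict:
    return {"axis": p.axis, "offset_mm": p.offset}


def _plane_from_json(d: dict) -> CrossSectionPlane:
    return CrossSectionPlane(d["axis"], d["offset_mm"])


def save_curves_json(
    path: str,
    frames: int,
    curves: Sequence[CurveConstraint],
    shared_curves: Sequence[SharedCurve] = (),
) -> None:
    doc = {
        "frames": int(frames),
        "curves": [
            {
                "id": c.id,
                "plane": _plane_to_json(c.plane),
                "closed": bool(c.closed),
                "frame": int(c.frame) if c.frame is not None else None,
                "control_points_mm": np.asarray(c.control_points).tolist(),
            }
            for c in curves
        ],
        "shared_curves": [
            {
                "id": s.id,
                "plane": _plane_to_json(s.plane),
                "closed": bool(s.closed),
                "keyframes": {
                    str(t): np.asarray(cp).tolist()
                    for t, cp in sorted(s.keyframes.items())
                },
            }
            for s in shared_curves
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_curves_json(path: str):
    """Returns (frames, curves, shared_curves)."""
    with open(path) as fh:
        doc = json.load(fh)
    frames = int(doc["frames"])
    curves = [
        CurveConstraint(
            id=c["id"],
            plane=_plane_from_json(c["plane"]),
            control_points=np.asarray(c["control_points_mm"], dtype=float),
            closed=bool(c.get("closed", True)),
            frame=c.get("frame"),
        )
        for c in doc.get("curves", [])
    ]
    shared = [
        SharedCurve(
            id=s["id"],
            plane=_plane_from_json(s["plane"]),
            closed=bool(s.get("closed", True)),
            keyframes={
                int(t): np.asarray(cp, dtype=float)
                for t, cp in s["keyframes"].items()
            },
        )
        for s in doc.get("shared_curves", [])
    ]
    return frames, curves, shared
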