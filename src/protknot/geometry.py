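"""Polygonal-curve geometry.

A protein backbone is treated as an open polygonal curve through its Cα
atoms.  This module provides the geometric primitives every topological
computation rests on:

* :class:`PolygonalCurve` — ordered 3D vertices, open or closed;
* :func:`kmt_reduce` — topology-preserving chain simplification by
  triangle elision (the KMT algorithm);
* :func:`sphere_directions` — quasi-uniform (Fibonacci lattice) or random
  direction sets on the unit sphere;
* :func:`project_to_diagram` — generic planar projection producing a
  crossing :class:`Diagram` (an endpoint-aware extended Gauss code with
  enough planar geometry retained to evaluate state-sum invariants);
* :func:`close_curve` — single-point stochastic closure through a point on
  a large sphere surrounding the structure.

All coordinates are in ångströms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError

__all__ = [
    "PolygonalCurve",
    "Diagram",
    "Crossing",
    "kmt_reduce",
    "sphere_directions",
    "project_to_diagram",
    "close_curve",
]

# Relative tolerance for intersection predicates (squared-length scale).
_EPS = 1e-9


@dataclass
class PolygonalCurve:
    """An ordered polygonal curve in 3-space.

    Parameters
    ----------
    vertices:
        ``(n, 3)`` float array.  For a closed curve the first vertex is
        *not* repeated at the end; the closing segment is implicit.
    closed:
        Whether the last vertex connects back to the first.
    """

    vertices: np.ndarray
    closed: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 3:
            raise GeometryError("vertices must be an (n, 3) array")
        if not np.all(np.isfinite(v)):
            raise GeometryError("vertices must be finite")
        n_min = 3 if self.closed else 2
        if len(v) < n_min:
            raise GeometryError(
                f"{'closed' if self.closed else 'open'} curve needs >= {n_min} vertices"
            )
        if self.closed and np.allclose(v[0], v[-1]):
            v = v[:-1]
            if len(v) < 3:
                raise GeometryError("closed curve needs >= 3 distinct vertices")
        # collapse consecutive duplicates
        keep = np.ones(len(v), dtype=bool)
        keep[1:] = np.linalg.norm(np.diff(v, axis=0), axis=1) > 1e-12
        v = v[keep]
        if len(v) < n_min:
            raise GeometryError("curve degenerate after removing duplicate vertices")
        self.vertices = v

    def __len__(self) -> int:
        return len(self.vertices)

    @property
    def n_segments(self) -> int:
        return len(self.vertices) if self.closed else len(self.vertices) - 1

    def segment(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        v = self.vertices
        return v[i], v[(i + 1) % len(v)]

    @property
    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    @property
    def radius(self) -> float:
        """Maximal distance of a vertex from the centroid."""
        return float(np.linalg.norm(self.vertices - self.centroid, axis=1).max())

    def mirrored(self) -> "PolygonalCurve":
        """Point reflection through the origin (mirror image)."""
        return PolygonalCurve(-self.vertices, closed=self.closed)

    def reversed(self) -> "PolygonalCurve":
        return PolygonalCurve(self.vertices[::-1].copy(), closed=self.closed)


@dataclass(frozen=True)
class Crossing:
    """One crossing of a planar diagram, in traversal order of first visit."""

    cid: int
    sign: int  # +1 / -1, right-hand rule w.r.t. the projection direction


@dataclass
class Diagram:
    """A planar crossing diagram (extended Gauss code + planar geometry).

    ``code`` lists the 2n crossing encounters in traversal order as
    ``(cid, is_over, sign)``.  ``n_endpoints`` is 0 for a closed-curve
    diagram and 2 for an open one.  The projected polyline and the
    positions of the crossings along it are retained so that state-sum
    invariants (Kauffman/Turaev brackets) can resolve which closed state
    loops enclose the open arc — the planar refinement.
    """

    code: list[tuple[int, bool, int]]
    n_endpoints: int
    points2d: np.ndarray = field(repr=False)  # projected polyline, (n, 2)
    closed: bool = False
    # per-encounter planar data, same order as ``code``:
    # (segment index, parameter in (0,1), x, y)
    encounters: list[tuple[int, float, float, float]] = field(default_factory=list, repr=False)
    direction: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_crossings(self) -> int:
        return len(self.code) // 2

    @property
    def writhe(self) -> int:
        return sum(sign for _, over, sign in self.code if over)

    def mirror(self) -> "Diagram":
        """Invert every crossing (over<->under, sign negated).  Involution."""
        code = [(cid, not over, -sign) for cid, over, sign in self.code]
        return Diagram(
            code=code,
            n_endpoints=self.n_endpoints,
            points2d=self.points2d,
            closed=self.closed,
            encounters=list(self.encounters),
            direction=None if self.direction is None else -self.direction,
        )


# --------------------------------------------------------------------------
# KMT reduction
# --------------------------------------------------------------------------


def _segments_hit_triangle(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    p: np.ndarray,
    q: np.ndarray,
    strict: np.ndarray,
    tol: float,
) -> bool:
    """True if any segment p[i]->q[i] meets the closed triangle (a, b, c).

    Segments flagged ``strict`` share a corner with the triangle; for those
    only a crossing through the *open* triangle interior counts.  The test
    is conservative: near-degenerate configurations count as hits, so the
    caller declines to elide the vertex.
    """
    if len(p) == 0:
        return False
    n = np.cross(b - a, c - a)
    n2 = float(n @ n)
    scale = max(
        float(((b - a) ** 2).sum()), float(((c - a) ** 2).sum()), 1e-30
    )
    if n2 < (tol * scale) ** 2:
        # degenerate (collinear) triangle: sweep region is the segment a-c;
        # be conservative and report a hit so the vertex is kept, unless the
        # middle vertex lies on segment a-c (handled by the caller).
        return True
    d0 = (p - a) @ n
    d1 = (q - a) @ n
    eps = tol * np.sqrt(n2 * scale)
    coplanar = (np.abs(d0) < eps) & (np.abs(d1) < eps)
    if np.any(coplanar & ~strict):
        # a whole segment lies (numerically) in the triangle plane: only a
        # hit if it comes near the triangle; conservative bounding check
        idx = np.nonzero(coplanar & ~strict)[0]
        lo = np.minimum.reduce([a, b, c]) - np.sqrt(tol * scale)
        hi = np.maximum.reduce([a, b, c]) + np.sqrt(tol * scale)
        for i in idx:
            slo = np.minimum(p[i], q[i])
            shi = np.maximum(p[i], q[i])
            if np.all(slo <= hi) and np.all(shi >= lo):
                return True
    crossing = (d0 > eps) & (d1 < -eps) | (d0 < -eps) & (d1 > eps)
    # boundary-touching transversal pieces for non-strict segments
    touching = ((np.abs(d0) <= eps) | (np.abs(d1) <= eps)) & ~coplanar & ~strict
    cand = np.nonzero(crossing | touching)[0]
    if len(cand) == 0:
        return False
    denom = d0[cand] - d1[cand]
    denom = np.where(np.abs(denom) < 1e-300, 1e-300, denom)
    t = d0[cand] / denom
    x = p[cand] + t[:, None] * (q[cand] - p[cand])
    # barycentric coordinates w.r.t. (a, b, c)
    v0 = b - a
    v1 = c - a
    v2 = x - a
    d00 = v0 @ v0
    d01 = v0 @ v1
    d11 = v1 @ v1
    den = d00 * d11 - d01 * d01
    if den <= 0:
        return True
    d20 = v2 @ v0
    d21 = v2 @ v1
    u = (d11 * d20 - d01 * d21) / den
    w = (d00 * d21 - d01 * d20) / den
    bar_eps = 1e-9
    inside_closed = (u >= -bar_eps) & (w >= -bar_eps) & (u + w <= 1 + bar_eps)
    inside_open = (u > bar_eps) & (w > bar_eps) & (u + w < 1 - bar_eps)
    is_strict = strict[cand]
    return bool(np.any(np.where(is_strict, inside_open, inside_closed)))


def kmt_reduce(
    curve: PolygonalCurve,
    preserve_endpoints: bool = True,
    tol: float = _EPS,
    direction: np.ndarray | None = None,
) -> PolygonalCurve:
    """Simplify a polygonal curve by repeated triangle elision (KMT).

    A vertex ``v_i`` is deleted when the triangle ``(v_{i-1}, v_i,
    v_{i+1})`` is intersected by no other segment of the curve, which
    preserves the knot type of a closed curve.  Sweeps run until a fixed
    point is reached, so the operation is idempotent.

    For an *open* curve analyzed as a knotoid the projection direction
    matters: an elision triangle whose projection sweeps across an
    endpoint changes the knotoid type even though the 3D curve is only
    isotoped.  Pass ``direction`` to additionally forbid triangles that
    intersect the lines through the two endpoints parallel to the
    projection direction (the endpoint "pillars"), which makes the
    reduction knotoid-safe for that direction.

    For open curves the terminal vertices are never elided via the
    triangle move; with ``preserve_endpoints=False`` a terminal vertex is
    additionally dropped when it is collinear with its two successors
    (curve unchanged as a point set).
    """
    pts = np.asarray(curve.vertices, dtype=float).copy()
    closed = curve.closed
    min_keep = 3 if closed else 2

    pillars: np.ndarray | None = None
    if direction is not None and not closed:
        d = np.asarray(direction, dtype=float)
        d = d / np.linalg.norm(d)
        span = 4.0 * (curve.radius + 1.0)
        pillars = np.array(
            [
                [pts[0] - span * d, pts[0] + span * d],
                [pts[-1] - span * d, pts[-1] + span * d],
            ]
        )

    changed = True
    while changed and len(pts) > min_keep:
        changed = False
        i = 0 if closed else 1
        while len(pts) > min_keep and i < (len(pts) if closed else len(pts) - 1):
            n = len(pts)
            im1 = (i - 1) % n
            ip1 = (i + 1) % n
            a, b, c = pts[im1], pts[i], pts[ip1]
            # collinear middle vertex on segment a-c: always safe to drop
            ab = b - a
            ac = c - a
            cr = np.cross(ac, ab)
            ac2 = float(ac @ ac)
            if ac2 > 0 and float(cr @ cr) < (tol * ac2) ** 2:
                s = float(ab @ ac) / ac2
                if -tol <= s <= 1 + tol:
                    pts = np.delete(pts, i, axis=0)
                    changed = True
                    continue
            # gather all other segments
            n_seg = n if closed else n - 1
            seg_idx = np.arange(n_seg)
            adjacent = {im1 % n_seg if closed else im1, i % n_seg if closed else i}
            mask = np.array([j not in adjacent for j in seg_idx], dtype=bool)
            p = pts[seg_idx[mask]]
            q = pts[(seg_idx[mask] + 1) % n]
            # segments sharing a triangle corner need strict interior test
            tri_verts = {im1, i, ip1}
            strict = np.array(
                [
                    (j in tri_verts) or (((j + 1) % n) in tri_verts)
                    for j in seg_idx[mask]
                ],
                dtype=bool,
            )
            if pillars is not None:
                p = np.vstack([p, pillars[:, 0]])
                q = np.vstack([q, pillars[:, 1]])
                # a pillar through a triangle corner (endpoint adjacent to the
                # elision triangle) only counts on a strict interior crossing
                end_in_tri = [0 in tri_verts, (len(pts) - 1) in tri_verts]
                strict = np.concatenate([strict, np.array(end_in_tri)])
            if not _segments_hit_triangle(a, b, c, p, q, strict, tol):
                pts = np.delete(pts, i, axis=0)
                changed = True
            else:
                i += 1
        if not closed and not preserve_endpoints and len(pts) > 2:
            # drop terminal vertices that are collinear with their neighbours
            for end in (0, len(pts) - 1):
                if len(pts) <= 2:
                    break
                trio = pts[:3] if end == 0 else pts[-3:]
                d1 = trio[1] - trio[0]
                d2 = trio[2] - trio[1]
                cr = np.cross(d1, d2)
                if float(cr @ cr) < (tol * max(float(d1 @ d1), 1e-30)) ** 2 and d1 @ d2 > 0:
                    pts = np.delete(pts, 0 if end == 0 else len(pts) - 1, axis=0)
                    changed = True
    return PolygonalCurve(pts, closed=closed)


# --------------------------------------------------------------------------
# Direction sampling
# --------------------------------------------------------------------------


def sphere_directions(n: int, seed: int | None = None) -> np.ndarray:
    """``n`` unit vectors on S².

    With ``seed=None`` a deterministic quasi-uniform Fibonacci lattice is
    returned; with an integer seed, uniform random directions.
    """
    if n < 1:
        raise GeometryError("need n >= 1 directions")
    if seed is None:
        i = np.arange(n, dtype=float)
        z = 1.0 - 2.0 * (i + 0.5) / n
        phi = i * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
        r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
        dirs = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    else:
        rng = np.random.default_rng(seed)
        v = rng.normal(size=(n, 3))
        dirs = v / np.linalg.norm(v, axis=1, keepdims=True)
    return dirs


# --------------------------------------------------------------------------
# Projection
# --------------------------------------------------------------------------


def _orthonormal_basis(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = d / np.linalg.norm(d)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(d @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(d, helper)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return u, v


_JITTER_AXES = [
    np.array([1.0, 0.0, 0.0]),
    np.array([0.0, 1.0, 0.0]),
    np.array([0.0, 0.0, 1.0]),
]


def _rotate(vec: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    c, s = np.cos(angle), np.sin(angle)
    return (
        vec * c
        + np.cross(axis, vec) * s
        + axis * float(axis @ vec) * (1 - c)
    )


class _Degenerate(Exception):
    pass


def _find_crossings(
    p2: np.ndarray, depth: np.ndarray, closed: bool, rel_eps: float
) -> list[tuple[int, float, int, float, bool, int, float, float]]:
    """All transverse crossings of the projected polyline with itself.

    Returns tuples ``(seg_i, t_i, seg_j, t_j, i_over, sign, x, y)`` for
    each crossing (seg_i < seg_j).  Raises ``_Degenerate`` when the
    projection is not generic.
    """
    n_pts = len(p2)
    n_seg = n_pts if closed else n_pts - 1
    scale = float(np.abs(np.diff(p2, axis=0)).max() + 1e-30)
    eps = rel_eps

    starts = p2[np.arange(n_seg)]
    ends = p2[(np.arange(n_seg) + 1) % n_pts]
    r = ends - starts
    seg_len = np.linalg.norm(r, axis=1)
    if np.any(seg_len < 1e-7 * scale):
        raise _Degenerate("segment parallel to projection direction")

    out = []
    for i in range(n_seg - 1):
        lo = i + 2
        hi = n_seg
        if closed and i == 0:
            hi = n_seg - 1
        if lo >= hi:
            continue
        js = np.arange(lo, hi)
        ri = r[i]
        cs = starts[js]
        s = r[js]
        denom = ri[0] * s[:, 1] - ri[1] * s[:, 0]
        qp = cs - starts[i]
        tnum = qp[:, 0] * s[:, 1] - qp[:, 1] * s[:, 0]
        unum = qp[:, 0] * ri[1] - qp[:, 1] * ri[0]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = tnum / denom
            u = unum / denom
        parallel = np.abs(denom) < 1e-12 * seg_len[i] * seg_len[js]
        inside = (~parallel) & (t > 0) & (t < 1) & (u > 0) & (u < 1)
        near = (~parallel) & (t > -eps) & (t < 1 + eps) & (u > -eps) & (u < 1 + eps)
        # near-miss at segment ends, or parallel overlapping segments -> not generic
        risky = near & ~(
            (t > eps) & (t < 1 - eps) & (u > eps) & (u < 1 - eps)
        )
        if np.any(risky):
            raise _Degenerate("crossing too close to a segment endpoint")
        for k in np.nonzero(inside)[0]:
            j = int(js[k])
            ti, tj = float(t[k]), float(u[k])
            di = depth[i] + ti * (depth[(i + 1) % n_pts] - depth[i])
            dj = depth[j] + tj * (depth[(j + 1) % n_pts] - depth[j])
            if abs(di - dj) < 1e-7 * (1.0 + abs(di) + abs(dj)):
                raise _Degenerate("coincident depths at crossing")
            x, y = starts[i] + ti * ri
            cr = ri[0] * s[k][1] - ri[1] * s[k][0]
            i_over = di > dj
            # sign of cross(d_over, d_under), right-hand rule
            if i_over:
                sgn = 1 if cr > 0 else -1
            else:
                sgn = 1 if -cr > 0 else -1
            out.append((i, ti, j, tj, bool(i_over), int(sgn), float(x), float(y)))
    # triple-point / coincident-crossing check: parameters on the same
    # segment must be well separated
    per_seg: dict[int, list[float]] = {}
    for i, ti, j, tj, *_ in out:
        per_seg.setdefault(i, []).append(ti)
        per_seg.setdefault(j, []).append(tj)
    for ts in per_seg.values():
        ts.sort()
        for a, b in zip(ts, ts[1:]):
            if b - a < 1e-9:
                raise _Degenerate("triple point")
    return out


def project_to_diagram(
    curve: PolygonalCurve,
    direction: np.ndarray,
    max_retries: int = 10,
) -> Diagram:
    """Project a curve along ``direction`` onto a plane, producing a
    crossing diagram.

    Degenerate projections (crossings at segment endpoints, coincident
    depths, triple points) are retried after rotating the direction by a
    deterministic 1e-6 rad jitter about a fixed axis sequence, up to
    ``max_retries`` times.
    """
    d = np.asarray(direction, dtype=float)
    nrm = np.linalg.norm(d)
    if not np.isfinite(nrm) or nrm == 0:
        raise GeometryError("direction must be a nonzero vector")
    d = d / nrm

    last_err = "unknown"
    for attempt in range(max_retries + 1):
        u, v = _orthonormal_basis(d)
        p2 = np.column_stack([curve.vertices @ u, curve.vertices @ v])
        depth = curve.vertices @ d
        try:
            raw = _find_crossings(p2, depth, curve.closed, rel_eps=1e-7)
        except _Degenerate as exc:
            last_err = str(exc)
            axis = _JITTER_AXES[attempt % 3]
            d = _rotate(d, axis, 1e-6 * (attempt + 1))
            continue
        # traversal order: encounters sorted by (segment, parameter)
        events = []  # (seg, t, pair_key, is_over, sign, x, y)
        for idx, (i, ti, j, tj, i_over, sgn, x, y) in enumerate(raw):
            events.append((i, ti, idx, i_over, sgn, x, y))
            events.append((j, tj, idx, not i_over, sgn, x, y))
        events.sort(key=lambda e: (e[0], e[1]))
        cid_of: dict[int, int] = {}
        code: list[tuple[int, bool, int]] = []
        encs: list[tuple[int, float, float, float]] = []
        for seg, t, key, over, sgn, x, y in events:
            if key not in cid_of:
                cid_of[key] = len(cid_of)
            code.append((cid_of[key], over, sgn))
            encs.append((seg, t, x, y))
        return Diagram(
            code=code,
            n_endpoints=0 if curve.closed else 2,
            points2d=p2,
            closed=curve.closed,
            encounters=encs,
            direction=d,
        )
    raise GeometryError(
        f"projection along {direction} degenerate after {max_retries} retries: {last_err}"
    )


# --------------------------------------------------------------------------
# Stochastic closure
# --------------------------------------------------------------------------


def closure_sphere(curve: PolygonalCurve, factor: float = 100.0) -> tuple[np.ndarray, float]:
    """Centre and radius of the closure sphere for an open curve."""
    c = curve.centroid
    return c, max(factor * curve.radius, 1.0)


def close_curve(curve: PolygonalCurve, closure_point: np.ndarray) -> PolygonalCurve:
    """Close an open curve through a single far-away point.

    Both termini are joined by straight segments to ``closure_point``,
    which must lie outside the curve's bounding sphere (it is normally
    sampled on a sphere of radius 100x the curve's extent, which makes
    the choice of closure scheme immaterial).
    """
    if curve.closed:
        raise GeometryError("curve is already closed")
    cp = np.asarray(closure_point, dtype=float)
    if cp.shape != (3,):
        raise GeometryError("closure point must be a 3-vector")
    if np.linalg.norm(cp - curve.centroid) <= curve.radius:
        raise GeometryError("closure point lies inside the curve's bounding sphere")
    return PolygonalCurve(np.vstack([curve.vertices, cp]), closed=True)
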