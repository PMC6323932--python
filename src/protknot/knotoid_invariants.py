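"""Planar knotoid classification via the Turaev loop bracket.

A knotoid diagram is the generic planar projection of an open 3D curve
with over/under information at each crossing.  Its type is preserved by
Reidemeister moves that avoid the two endpoints; because the ambient
surface is the *plane* (not the sphere), a state loop that encircles the
open arc cannot be isotoped away, and tracking such loops refines the
classification ("planar" knotoids carry more information than spherical
ones).

The invariant computed here is a writhe-normalized bracket state sum in
Z[A^±1, u^±1]:

* every crossing is smoothed the A-way or the B-way (2^n states); a
  state contributes A^(#A − #B);
* each closed state loop that does **not** enclose the open arc
  contributes the usual δ = −A² − A⁻²;
* each loop that **does** enclose the arc contributes the loop variable
  ``u``;
* the result is multiplied by (−A³)^(−w) where w is the diagram writhe,
  making it invariant under endpoint-avoiding R1/R2/R3 moves, with
  bracket(trivial arc) = 1.

Classification matches the bracket against a packaged table of reference
diagrams through three crossings (k0.1, k2.1, k3.1, k3.2 and mirrors,
suffix ``m``); anything beyond the table is reported ``unknown``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from itertools import product

import numpy as np

from .errors import TopologyError
from .geometry import Diagram, PolygonalCurve, project_to_diagram
from .laurent import Laurent

__all__ = [
    "KnotoidType",
    "loop_bracket",
    "classify_knotoid",
    "mirror_diagram",
    "load_knotoid_table",
    "UNKNOWN_KNOTOID",
    "TRIVIAL_KNOTOID",
]

# state-sum cost guard: 2^n states
_MAX_BRACKET_CROSSINGS = 16


@dataclass(frozen=True)
class KnotoidType:
    """A named knotoid type, e.g. ``k2.1``, ``k2.1m``, ``k0.1``, ``unknown``."""

    base: str
    mirror_suffix: bool = False

    @property
    def name(self) -> str:
        return self.base + ("m" if self.mirror_suffix else "")

    @property
    def is_trivial(self) -> bool:
        return self.base == "k0.1"

    def __str__(self) -> str:
        return self.name


UNKNOWN_KNOTOID = KnotoidType("unknown")
TRIVIAL_KNOTOID = KnotoidType("k0.1")

_DELTA = Laurent({(2, 0): -1, (-2, 0): -1})  # -A^2 - A^-2
_U = Laurent.monomial(1, 0, 1)


def mirror_diagram(diagram: Diagram) -> Diagram:
    """All over/under assignments and signs inverted (an involution)."""
    return diagram.mirror()


def _winding_number(poly: np.ndarray, pt: np.ndarray) -> int:
    """Winding number of a closed polygon around a point."""
    d = poly - pt
    ang = np.arctan2(d[:, 1], d[:, 0])
    dang = np.diff(np.concatenate([ang, ang[:1]]))
    dang = (dang + np.pi) % (2 * np.pi) - np.pi
    return int(round(dang.sum() / (2 * np.pi)))


def _build_edges(diagram: Diagram):
    """Cut the projected open polyline at its crossing points.

    Returns ``edges`` (list of 2D polylines) and per-crossing incidences
    ``{cid: [(in_edge, out_edge), (in_edge, out_edge)]}`` in traversal
    order of the two visits.
    """
    pts = diagram.points2d
    encs = diagram.encounters
    n_enc = len(encs)
    cut_pts = [np.array([x, y]) for _, _, x, y in encs]

    edges: list[np.ndarray] = []
    start = pts[0]
    prev_seg, prev_pt = 0, start
    for k in range(n_enc):
        seg, _, x, y = encs[k]
        mid = pts[prev_seg + 1: seg + 1]
        edges.append(np.vstack([prev_pt[None, :], mid, cut_pts[k][None, :]]))
        prev_seg, prev_pt = seg, cut_pts[k]
    mid = pts[prev_seg + 1:]
    edges.append(np.vstack([prev_pt[None, :], mid]))

    visits: dict[int, list[tuple[int, int]]] = {}
    for k, (cid, _, _) in enumerate(diagram.code):
        visits.setdefault(cid, []).append((k, k + 1))  # (in_edge, out_edge)
    return edges, visits


def loop_bracket(diagram: Diagram, max_crossings: int = _MAX_BRACKET_CROSSINGS) -> Laurent:
    """Turaev loop bracket of an open (knotoid) diagram, in Z[A^±1, u^±1]."""
    if diagram.n_endpoints != 2:
        raise TopologyError("loop bracket is defined for open diagrams only "
                            "(use alexander/homfly for closed curves)")
    n = diagram.n_crossings
    if n > max_crossings:
        raise TopologyError(f"diagram has {n} crossings (> {max_crossings}); "
                            "state sum too large")
    if n == 0:
        return Laurent.const(1, arity=2)

    edges, visits = _build_edges(diagram)
    n_edges = len(edges)
    cids = sorted(visits)
    signs = {cid: s for cid, _, s in diagram.code}
    testpoint = diagram.points2d[0]

    total = Laurent({}, arity=2)
    for choice in product((True, False), repeat=n):  # True = A-smoothing
        # connection map between edge ends: (edge, end) -> (edge, end)
        # end 0 = start of edge, end 1 = end of edge
        conn: dict[tuple[int, int], tuple[int, int]] = {}
        a_count = 0
        for cid, is_a in zip(cids, choice):
            (in1, out1), (in2, out2) = visits[cid]
            oriented = is_a if signs[cid] > 0 else not is_a
            if is_a:
                a_count += 1
            if oriented:
                pairs = [((in1, 1), (out2, 0)), ((in2, 1), (out1, 0))]
            else:
                pairs = [((in1, 1), (in2, 1)), ((out1, 0), (out2, 0))]
            for x, y in pairs:
                conn[x] = y
                conn[y] = x
        # trace components
        visited = [False] * n_edges
        # the open arc: walk from edge 0
        pos = (0, 1)
        visited[0] = True
        while pos in conn:
            nxt_edge, nxt_end = conn[pos]
            visited[nxt_edge] = True
            pos = (nxt_edge, 1 - nxt_end)
        weight = Laurent.monomial(1, 2 * a_count - n, 0)
        for e0 in range(n_edges):
            if visited[e0]:
                continue
            # trace the closed loop through e0, collecting its polygon
            loop_pts = [edges[e0]]
            visited[e0] = True
            pos = (e0, 1)
            while True:
                nxt_edge, nxt_end = conn[pos]
                if nxt_edge == e0 and nxt_end == 0:
                    break
                visited[nxt_edge] = True
                geom = edges[nxt_edge]
                loop_pts.append(geom if nxt_end == 0 else geom[::-1])
                pos = (nxt_edge, 1 - nxt_end)
            poly = np.vstack(loop_pts)
            if _winding_number(poly, testpoint) != 0:
                weight = weight * _U
            else:
                weight = weight * _DELTA
        total = total + weight
    w = diagram.writhe
    norm = Laurent.monomial((-1) ** (w % 2), -3 * w, 0)
    return norm * total


# --------------------------------------------------------------------------
# Classification table
# --------------------------------------------------------------------------


@lru_cache(maxsize=1)
def load_knotoid_table() -> dict:
    """Packaged reference diagrams and their brackets.

    Each entry ships a small 3D polyline whose projection along +z is the
    reference diagram; brackets (and those of the mirrors, suffix ``m``)
    are computed on load and checked for pairwise separation.
    """
    text = resources.files("protknot.data").joinpath("knotoid_table.json").read_text()
    data = json.loads(text)
    z_axis = np.array([0.0, 0.0, 1.0])
    by_bracket: dict[Laurent, KnotoidType] = {}
    entries = {}
    for entry in data["knotoids"]:
        name = entry["name"]
        curve = PolygonalCurve(np.asarray(entry["xyz"], dtype=float), closed=False)
        diag = project_to_diagram(curve, z_axis)
        if diag.n_crossings != entry["crossings"]:
            raise ValueError(
                f"reference diagram {name}: expected {entry['crossings']} "
                f"crossings, got {diag.n_crossings}"
            )
        br = loop_bracket(diag)
        types = [(KnotoidType(name), br)]
        if entry.get("chiral", True):
            types.append((KnotoidType(name, mirror_suffix=True),
                          loop_bracket(mirror_diagram(diag))))
        for ktype, b in types:
            if b in by_bracket and by_bracket[b].name != ktype.name:
                raise ValueError(
                    f"knotoid table not separated by the loop bracket: "
                    f"{ktype.name} vs {by_bracket[b].name}"
                )
            by_bracket[b] = ktype
        entries[name] = {"curve": curve, "bracket": br}
    return {"by_bracket": by_bracket, "entries": entries}


def classify_knotoid(
    diagram: Diagram,
    max_crossings: int = _MAX_BRACKET_CROSSINGS,
) -> KnotoidType:
    """Name the knotoid type of an open diagram via its loop bracket.

    Returns ``unknown`` for brackets beyond the packaged table (entries
    through three crossings) or diagrams too large for the state sum.
    """
    if diagram.n_crossings == 0:
        return TRIVIAL_KNOTOID
    try:
        br = loop_bracket(diagram, max_crossings=max_crossings)
    except TopologyError:
        return UNKNOWN_KNOTOID
    if br == Laurent.const(1, arity=2):
        return TRIVIAL_KNOTOID
    return load_knotoid_table()["by_bracket"].get(br, UNKNOWN_KNOTOID)
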