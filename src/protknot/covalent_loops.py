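"""Closed loops through backbone segments and covalent/ionic bridges.

A bridge (disulfide, ion-mediated, or user-declared) joins two
non-sequential residues, so the backbone plus its bridges forms a graph
in which genuinely *closed* loops exist.  Such loops have a unique —
deterministic — knot type, in contrast to the stochastic-closure
("probabilistic") analysis of open chains; a protein can be unknotted
along its backbone yet carry a knotted covalent loop.

Loops are written in a compact notation in which ``-c-`` separates the
endpoints of a backbone segment and ``-b-`` marks a bridge; the final
bridge closing the loop is implicit.  For example ``4-c-11-b-23-c-21``
is the loop backbone(4→11), bridge(11–23), backbone(23→21, traversed
backwards), implicit bridge(21–4); a lone bridge is written ``17-b-29``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError, ParseError, TopologyError
from .geometry import PolygonalCurve, kmt_reduce, project_to_diagram, sphere_directions
from .knot_invariants import KnotType, classify_knot
from .structure_io import Bridge, ChainModel, extract_backbone

__all__ = [
    "CovalentLoop",
    "DeterministicKnotResult",
    "BridgedPath",
    "enumerate_covalent_loops",
    "loop_knot_type",
    "bridged_open_paths",
    "format_loop_notation",
    "parse_loop_notation",
    "build_loop",
]

DEFAULT_MAX_BRIDGES = 2


@dataclass
class CovalentLoop:
    """A closed alternating path of backbone segments and bridges."""

    elements: list[tuple[str, int, int]]  # ("chain"|"bridge", res_i, res_j), closed walk
    curve: PolygonalCurve  # closed geometry (Cα polyline + straight bridge segments)
    notation: str

    @property
    def n_bridges(self) -> int:
        return sum(1 for kind, _, _ in self.elements if kind == "bridge")

    @property
    def length_residues(self) -> int:
        n = 0
        for kind, a, b in self.elements:
            if kind == "chain":
                n += abs(b - a) + 1
        return n

    def __eq__(self, other):
        if not isinstance(other, CovalentLoop):
            return NotImplemented
        return _canonical_elements(self.elements) == _canonical_elements(other.elements)

    def __hash__(self):
        return hash(_canonical_elements(self.elements))


@dataclass
class DeterministicKnotResult:
    loop: CovalentLoop
    knot_type: KnotType


@dataclass
class BridgedPath:
    """An N→C open path through the segment/bridge graph."""

    elements: list[tuple[str, int, int]]
    curve: PolygonalCurve  # open
    notation: str

    @property
    def n_bridges(self) -> int:
        return sum(1 for kind, _, _ in self.elements if kind == "bridge")


def _canonical_elements(elements) -> tuple:
    """Orientation- and rotation-independent key for a closed walk."""
    variants = []
    for seq in (elements, [(k, b, a) for k, a, b in reversed(elements)]):
        m = len(seq)
        for s in range(m):
            variants.append(tuple(seq[s:] + seq[:s]))
    return min(variants)


# --------------------------------------------------------------------------
# Geometry assembly
# --------------------------------------------------------------------------


def _index_map(residue_ids: list[int]) -> dict[int, int]:
    return {r: i for i, r in enumerate(residue_ids)}


def _walk_geometry(
    elements: list[tuple[str, int, int]],
    vertices: np.ndarray,
    idx: dict[int, int],
    closed: bool,
) -> PolygonalCurve:
    pts: list[np.ndarray] = []
    for kind, a, b in elements:
        ia, ib = idx[a], idx[b]
        if kind == "chain":
            piece = vertices[ia: ib + 1] if ia <= ib else vertices[ib: ia + 1][::-1]
        else:  # bridge: straight Cα–Cα segment
            piece = vertices[[ia, ib]]
        if pts:
            piece = piece[1:]
        pts.append(piece)
    arr = np.vstack(pts)
    if closed:
        arr = arr[:-1]  # the walk returns to its start
    return PolygonalCurve(arr, closed=closed)


def build_loop(
    chain: ChainModel,
    elements: list[tuple[str, int, int]],
) -> CovalentLoop:
    """Assemble a CovalentLoop (geometry + notation) from a closed walk."""
    curve, residue_ids = extract_backbone(chain)
    idx = _index_map(residue_ids)
    geom = _walk_geometry(elements, curve.vertices, idx, closed=True)
    return CovalentLoop(elements=list(elements), curve=geom,
                        notation=format_loop_notation(elements))


# --------------------------------------------------------------------------
# Enumeration
# --------------------------------------------------------------------------


def _segment_graph(chain: ChainModel, include_termini: bool):
    """Nodes (special residues) and edges of the backbone/bridge graph.

    Edges are ``(kind, a, b)`` with backbone edges between sequence-
    consecutive special residues.
    """
    nodes = set()
    for br in chain.bridges:
        nodes.update((br.res_a, br.res_b))
    seq = chain.seq_indices
    if include_termini:
        nodes.update((seq[0], seq[-1]))
    nodes = sorted(nodes)
    edges: list[tuple[str, int, int]] = []
    for a, b in zip(nodes, nodes[1:]):
        edges.append(("chain", a, b))
    for br in chain.bridges:
        edges.append(("bridge", br.res_a, br.res_b))
    return nodes, edges


def enumerate_covalent_loops(
    chain: ChainModel,
    max_bridges: int = DEFAULT_MAX_BRIDGES,
) -> list[CovalentLoop]:
    """All simple cycles through the segment/bridge graph using 1 to
    ``max_bridges`` bridge edges.

    Loops never involve the chain termini (an open end cannot close a
    covalent loop).  Consecutive backbone edges in a cycle are merged so
    that segments and bridges alternate in the notation.
    """
    if max_bridges < 1:
        raise ValueError("max_bridges must be >= 1")
    if not chain.bridges:
        return []
    nodes, edges = _segment_graph(chain, include_termini=False)
    adjacency: dict[int, list[tuple[int, str, int, int]]] = {n: [] for n in nodes}
    for ei, (kind, a, b) in enumerate(edges):
        adjacency[a].append((ei, kind, a, b))
        adjacency[b].append((ei, kind, b, a))

    cycles: dict[tuple, list[tuple[str, int, int]]] = {}

    def dfs(start, node, used_edges, visited, walk, n_bridges):
        for ei, kind, _, nxt in adjacency[node]:
            if ei in used_edges:
                continue
            nb = n_bridges + (kind == "bridge")
            if nb > max_bridges:
                continue
            if nxt == start:
                if len(walk) >= 1 and nb >= 1:
                    cyc = walk + [(kind, node, nxt)]
                    key = _canonical_elements(cyc)
                    cycles.setdefault(key, cyc)
                continue
            if nxt in visited:
                continue
            dfs(start, nxt, used_edges | {ei}, visited | {nxt},
                walk + [(kind, node, nxt)], nb)

    for start in nodes:
        dfs(start, start, frozenset(), {start}, [], 0)

    out = []
    curve, residue_ids = extract_backbone(chain)
    idx = _index_map(residue_ids)
    for cyc in cycles.values():
        merged = _merge_chain_runs(cyc)
        try:
            geom = _walk_geometry(merged, curve.vertices, idx, closed=True)
        except GeometryError:
            continue  # degenerate 2-vertex ring (bridge between neighbours)
        out.append(
            CovalentLoop(elements=merged, curve=geom,
                         notation=format_loop_notation(merged))
        )
    out.sort(key=lambda lp: lp.notation)
    return out


def _merge_chain_runs(elements: list[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    """Merge consecutive backbone edges (cyclically) into single segments."""
    elems = list(elements)
    changed = True
    while changed and len(elems) > 1:
        changed = False
        m = len(elems)
        for p in range(m):
            q = (p + 1) % m
            (k1, a1, b1), (k2, a2, b2) = elems[p], elems[q]
            if k1 == "chain" and k2 == "chain" and b1 == a2:
                merged = ("chain", a1, b2)
                if q > p:
                    elems = elems[:p] + [merged] + elems[q + 1:]
                else:  # wraparound
                    elems = [merged] + elems[1:p]
                changed = True
                break
    # canonical orientation/start: begin at the chain segment with the
    # smallest start residue (e.g. "4-c-11-b-23-c-21")
    candidates = []
    for seq in (elems, [(k, b, a) for k, a, b in reversed(elems)]):
        for i, (k, a, b) in enumerate(seq):
            if k == "chain":
                cand = seq[i:] + seq[:i]
                candidates.append((cand[0][1], cand[0][2], tuple(cand)))
    if candidates:
        elems = list(min(candidates)[2])
    return elems


# --------------------------------------------------------------------------
# Deterministic knot type
# --------------------------------------------------------------------------


def loop_knot_type(loop: CovalentLoop, homfly_limit: int = 30) -> DeterministicKnotResult:
    """The unique knot type of a closed covalent loop."""
    if not loop.curve.closed:
        raise TopologyError("loop geometry is not closed")
    red = kmt_reduce(loop.curve)
    ktype = None
    for d in sphere_directions(8, seed=None):
        try:
            diag = project_to_diagram(red, d)
            ktype = classify_knot(diag, homfly_limit=homfly_limit)
            break
        except Exception:
            continue
    if ktype is None:
        raise TopologyError(f"could not project loop {loop.notation}")
    return DeterministicKnotResult(loop=loop, knot_type=ktype)


# --------------------------------------------------------------------------
# Bridged open paths
# --------------------------------------------------------------------------


def bridged_open_paths(
    chain: ChainModel,
    max_bridges: int = DEFAULT_MAX_BRIDGES,
) -> list[BridgedPath]:
    """All simple N-terminus → C-terminus paths using <= ``max_bridges``
    bridges (the plain backbone is always included)."""
    curve, residue_ids = extract_backbone(chain)
    idx = _index_map(residue_ids)
    nterm, cterm = residue_ids[0], residue_ids[-1]
    if not chain.bridges:
        return [
            BridgedPath(
                elements=[("chain", nterm, cterm)],
                curve=curve,
                notation=format_loop_notation([("chain", nterm, cterm)], open_path=True),
            )
        ]
    nodes, edges = _segment_graph(chain, include_termini=True)
    adjacency: dict[int, list[tuple[int, str, int, int]]] = {n: [] for n in nodes}
    for ei, (kind, a, b) in enumerate(edges):
        adjacency[a].append((ei, kind, a, b))
        adjacency[b].append((ei, kind, b, a))

    paths: list[list[tuple[str, int, int]]] = []

    def dfs(node, visited, walk, n_bridges):
        if node == cterm:
            if walk:
                paths.append(list(walk))
            return
        for ei, kind, _, nxt in adjacency[node]:
            if nxt in visited:
                continue
            nb = n_bridges + (kind == "bridge")
            if nb > max_bridges:
                continue
            dfs(nxt, visited | {nxt}, walk + [(kind, node, nxt)], nb)

    dfs(nterm, {nterm}, [], 0)
    out = []
    for walk in paths:
        merged = _merge_chain_runs_open(walk)
        geom = _walk_geometry(merged, curve.vertices, idx, closed=False)
        out.append(
            BridgedPath(
                elements=merged,
                curve=geom,
                notation=format_loop_notation(merged, open_path=True),
            )
        )
    out.sort(key=lambda p: (p.n_bridges, p.notation))
    return out


def _merge_chain_runs_open(elements):
    elems = list(elements)
    out = []
    for el in elems:
        if out and out[-1][0] == "chain" and el[0] == "chain" and out[-1][2] == el[1]:
            out[-1] = ("chain", out[-1][1], el[2])
        else:
            out.append(el)
    return out


# --------------------------------------------------------------------------
# Notation
# --------------------------------------------------------------------------


def format_loop_notation(
    elements: list[tuple[str, int, int]] | CovalentLoop,
    open_path: bool = False,
) -> str:
    """Render a walk as e.g. ``4-c-11-b-23-c-21`` (closing bridge implicit)
    or a lone bridge as ``17-b-29``."""
    if isinstance(elements, CovalentLoop):
        elements = elements.elements
    if not elements:
        raise ValueError("empty walk")
    elems = list(elements)
    if not open_path and len(elems) > 1 and elems[-1][0] == "bridge":
        elems = elems[:-1]  # the closing bridge is implicit
    sep = {"chain": "-c-", "bridge": "-b-"}
    parts = [str(elems[0][1])]
    for kind, a, b in elems:
        parts.append(sep[kind])
        parts.append(str(b))
    return "".join(parts)


def parse_loop_notation(text: str, chain: ChainModel | None = None):
    """Parse loop/bridge notation.

    ``"i-b-j"`` alone gives a :class:`Bridge`; anything longer gives a
    :class:`CovalentLoop` when ``chain`` is supplied (the closing bridge
    back to the start is implied), otherwise the element list.
    """
    tokens = text.strip().split("-")
    if len(tokens) < 3 or len(tokens) % 2 == 0:
        raise ParseError(f"malformed notation {text!r}: expected i-c-j-b-k-...")
    nums = []
    seps = []
    for pos, tok in enumerate(tokens):
        if pos % 2 == 0:
            try:
                nums.append(int(tok))
            except ValueError:
                raise ParseError(
                    f"malformed notation {text!r} at position {pos}: "
                    f"{tok!r} is not a residue index"
                ) from None
        else:
            if tok not in ("c", "b"):
                raise ParseError(
                    f"malformed notation {text!r} at position {pos}: "
                    f"separator must be 'c' or 'b', got {tok!r}"
                )
            seps.append(tok)
    elements = [
        ("chain" if s == "c" else "bridge", a, b)
        for s, a, b in zip(seps, nums, nums[1:])
    ]
    if len(elements) == 1 and elements[0][0] == "bridge":
        return Bridge("disulfide", elements[0][1], elements[0][2])
    if nums[-1] != nums[0]:
        elements.append(("bridge", nums[-1], nums[0]))  # implicit closure
    if chain is None:
        return elements
    return build_loop(chain, elements)
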