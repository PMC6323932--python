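"""Cystine-knot motifs: a covalent loop of two disulfides pierced by a third.

Three disulfide bridges form a cysteine knot when two of them close a
covalent loop (two backbone segments + two bridges) through which the
third bridge passes.  The motif is *not* a mathematical knot — every
covalent cycle within it is unknotted — but it is a topologically
complex, highly stabilizing arrangement found in growth factors,
protease inhibitors ("knottins"), and cyclotides.

"Pierced" is made precise geometrically: the loop polygon is spanned by
a fan of triangles from its centroid, and the signed count of
transversal segment–triangle intersections of the candidate bridge with
that surface must be ±1 (the count is a topological quantity once the
crossing is transversal, checked by apex perturbation).  No sequence-
distance filter is applied: motifs are reported independent of their
span.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .covalent_loops import (
    CovalentLoop,
    enumerate_covalent_loops,
    format_loop_notation,
    loop_knot_type,
)
from .errors import GeometryError
from .geometry import PolygonalCurve
from .structure_io import Bridge, ChainModel

__all__ = [
    "CysteineKnotMotif",
    "piercing_number",
    "detect_cysteine_knots",
    "classify_ck_class",
    "verify_ck_loops_unknotted",
]

CYCLIZATION_DISTANCE = 5.0  # Å between terminal Cα atoms


@dataclass
class CysteineKnotMotif:
    loop_bridges: tuple[Bridge, Bridge]
    piercing_bridge: Bridge
    loop: CovalentLoop
    loop_notation: str
    piercing_notation: str
    piercing_sign: int
    ck_class: str = "unclassified"
    multiple_piercing: bool = False


# --------------------------------------------------------------------------
# Piercing test
# --------------------------------------------------------------------------


def _segment_triangle_signed(p, q, a, b, c, eps):
    """+1/-1 for a transversal crossing, 0 for a miss, None when degenerate."""
    d = q - p
    e1 = b - a
    e2 = c - a
    n = np.cross(e1, e2)
    denom = float(d @ n)
    scale = float(np.linalg.norm(d) * np.linalg.norm(n))
    if scale == 0.0:
        return None
    if abs(denom) < eps * scale:
        # segment parallel to the triangle plane; degenerate if it comes close
        dist = abs(float((p - a) @ n)) / (np.linalg.norm(n) + 1e-300)
        return None if dist < eps * np.linalg.norm(d) else 0
    t = float((a - p) @ n) / denom
    if t < -eps or t > 1 + eps:
        return 0
    x = p + t * d
    # barycentric
    v2 = x - a
    d00 = float(e1 @ e1)
    d01 = float(e1 @ e2)
    d11 = float(e2 @ e2)
    den = d00 * d11 - d01 * d01
    if den <= 0:
        return None
    d20 = float(v2 @ e1)
    d21 = float(v2 @ e2)
    u = (d11 * d20 - d01 * d21) / den
    w = (d00 * d21 - d01 * d20) / den
    if u < -eps or w < -eps or u + w > 1 + eps:
        return 0
    if (
        u < eps or w < eps or u + w > 1 - eps
        or t < eps or t > 1 - eps
    ):
        return None  # grazing the triangle boundary or segment end: retry
    return 1 if denom > 0 else -1


def piercing_number(
    loop: PolygonalCurve,
    segment: tuple[np.ndarray, np.ndarray],
    eps: float = 1e-9,
    max_retries: int = 5,
) -> int:
    """Signed number of transversal crossings of ``segment`` through a
    triangulated surface spanning ``loop``.

    The surface is the centroid-fan triangulation of the loop polygon;
    degenerate incidences trigger a deterministic jitter of the fan apex
    (up to ``max_retries`` times).
    """
    if not loop.closed:
        raise GeometryError("piercing_number requires a closed loop")
    p = np.asarray(segment[0], dtype=float)
    q = np.asarray(segment[1], dtype=float)
    verts = loop.vertices
    apex0 = verts.mean(axis=0)
    scale = max(loop.radius, 1.0)
    for attempt in range(max_retries + 1):
        jitter = np.array(
            [np.sin(1.0 + 7 * attempt), np.cos(2.0 + 5 * attempt), np.sin(3.0 + 3 * attempt)]
        ) * (0.0 if attempt == 0 else 1e-3 * scale * attempt)
        apex = apex0 + jitter
        total = 0
        ok = True
        for i in range(len(verts)):
            a = verts[i]
            b = verts[(i + 1) % len(verts)]
            s = _segment_triangle_signed(p, q, apex, a, b, eps)
            if s is None:
                ok = False
                break
            total += s
        if ok:
            return total
    raise GeometryError("piercing test degenerate after apex retries")


# --------------------------------------------------------------------------
# Motif detection
# --------------------------------------------------------------------------


def _two_bridge_loop(chain: ChainModel, b1: Bridge, b2: Bridge) -> CovalentLoop | None:
    """The unique loop closed by exactly these two bridges, if it exists."""
    tmp = replace(chain, bridges=[b1, b2])
    loops = [lp for lp in enumerate_covalent_loops(tmp, max_bridges=2) if lp.n_bridges == 2]
    return loops[0] if loops else None


def detect_cysteine_knots(chain: ChainModel, classify: bool = True) -> list[CysteineKnotMotif]:
    """All cysteine-knot motifs among the chain's disulfide bridges.

    Every unordered triple of disulfides is tested with each of the three
    choices of piercing bridge; a motif is emitted when the remaining two
    bridges close a loop pierced exactly once (|signed crossings| = 1).
    An odd count >= 3 is reported as a motif flagged ``multiple_piercing``.
    """
    disulfides = [b for b in chain.bridges if b.kind == "disulfide"]
    ca = {r.seq_index: np.asarray(r.ca_xyz) for r in chain.residues}
    motifs: list[CysteineKnotMotif] = []
    n = len(disulfides)
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(j + 1, n):
                triple = (disulfides[i], disulfides[j], disulfides[k])
                res = {t.res_a for t in triple} | {t.res_b for t in triple}
                if len(res) != 6:
                    continue  # bridges must be pairwise disjoint in residues
                for p_idx in range(3):
                    piercer = triple[p_idx]
                    loopers = tuple(t for q, t in enumerate(triple) if q != p_idx)
                    loop = _two_bridge_loop(chain, *loopers)
                    if loop is None:
                        continue
                    seg = (ca[piercer.res_a], ca[piercer.res_b])
                    try:
                        pn = piercing_number(loop.curve, seg)
                    except GeometryError:
                        continue
                    if pn == 0 or pn % 2 == 0:
                        continue
                    motif = CysteineKnotMotif(
                        loop_bridges=loopers,
                        piercing_bridge=piercer,
                        loop=loop,
                        loop_notation=loop.notation,
                        piercing_notation=format_loop_notation(
                            [("bridge", piercer.res_a, piercer.res_b)], open_path=True
                        ),
                        piercing_sign=1 if pn > 0 else -1,
                        multiple_piercing=abs(pn) >= 3,
                    )
                    if classify:
                        motif.ck_class = classify_ck_class(motif, chain)
                    motifs.append(motif)
    return motifs


# --------------------------------------------------------------------------
# Classification
# --------------------------------------------------------------------------


def _is_cyclized(chain: ChainModel) -> bool:
    for b in chain.bridges:
        seq = chain.seq_indices
        if b.kind == "amide" and {b.res_a, b.res_b} == {seq[0], seq[-1]}:
            return True
    first = np.asarray(chain.residues[0].ca_xyz)
    last = np.asarray(chain.residues[-1].ca_xyz)
    return float(np.linalg.norm(first - last)) <= CYCLIZATION_DISTANCE


def classify_ck_class(motif: CysteineKnotMotif, chain: ChainModel) -> str:
    """Assign growth_factor / inhibitor / cyclic / other.

    The six cysteines are ranked 1..6 by sequence.  A head-to-tail
    cyclized chain gives ``cyclic``.  Otherwise the class follows which
    bridge pierces: the canonical 1–4/2–5 loop threaded by 3–6 is the
    growth-factor arrangement; a 2–5/3–6 loop threaded by 1–4 is the
    inhibitor arrangement; any other permutation is ``other``.
    """
    if _is_cyclized(chain):
        return "cyclic"
    cys = sorted(
        {b.res_a for b in (*motif.loop_bridges, motif.piercing_bridge)}
        | {b.res_b for b in (*motif.loop_bridges, motif.piercing_bridge)}
    )
    rank = {r: i + 1 for i, r in enumerate(cys)}
    loop_ranks = {
        (rank[b.res_a], rank[b.res_b]) for b in motif.loop_bridges
    }
    pierce_ranks = (rank[motif.piercing_bridge.res_a], rank[motif.piercing_bridge.res_b])
    if loop_ranks == {(1, 4), (2, 5)} and pierce_ranks == (3, 6):
        return "growth_factor"
    if loop_ranks == {(2, 5), (3, 6)} and pierce_ranks == (1, 4):
        return "inhibitor"
    return "other"


def verify_ck_loops_unknotted(
    motif: CysteineKnotMotif, chain: ChainModel
) -> list[tuple[str, str]]:
    """Classify every covalent cycle within the motif's three bridges.

    Returns the (notation, knot type) pairs of any non-trivial cycle —
    empty for a true cysteine knot, whose circular covalent paths are all
    unknotted; a non-empty report means the structure also carries a
    deterministic knot.
    """
    seen = {}
    for b in (*motif.loop_bridges, motif.piercing_bridge):
        seen[(b.kind, b.res_a, b.res_b)] = b
    tmp = replace(chain, bridges=list(seen.values()))
    bad = []
    for loop in enumerate_covalent_loops(tmp, max_bridges=3):
        result = loop_knot_type(loop)
        if not result.knot_type.is_trivial:
            bad.append((loop.notation, result.knot_type.name))
    return bad
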