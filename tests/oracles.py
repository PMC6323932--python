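"""Independent brute-force oracles used only by the tests.

These deliberately avoid the code paths of the package: the knot
determinant comes from a Kauffman-bracket state sum evaluated at
A = e^{i pi/4} (where |V(-1)| equals |Delta(-1)|) instead of the
Alexander incidence matrix, planar crossings are counted by direct
segment-pair intersection, and segment–triangle piercing is recounted by
solving the 3x3 linear system per triangle.
"""

from __future__ import annotations

from itertools import product

import numpy as np


# --------------------------------------------------------------------------
# Kauffman-bracket determinant from an extended Gauss code
# --------------------------------------------------------------------------


def _count_loops(code, choice):
    """Loops of a fully smoothed closed diagram.

    ``code`` is the traversal list (cid, is_over, sign); ``choice`` maps
    cid -> True for the A smoothing.  For a positive crossing the A
    smoothing is the oriented one; negative, the disoriented one.
    """
    m = len(code)
    pos_of = {}
    for p, (cid, over, sign) in enumerate(code):
        pos_of.setdefault(cid, []).append(p)
    # directed traversal: state (edge p, direction +1/-1); edge p runs from
    # encounter p to p+1 (mod m).  Arriving at an encounter, the smoothing
    # decides where to continue.
    def step(edge, direction):
        enc = (edge + 1) % m if direction == +1 else edge
        cid, over, sign = code[enc]
        p1, p2 = pos_of[cid]
        other = p2 if enc == p1 else p1
        oriented = choice[cid] if sign > 0 else not choice[cid]
        if oriented:
            # continue along the other strand, same direction
            return (other, +1) if direction == +1 else ((other - 1) % m, -1)
        # disoriented: reverse onto the other strand
        return ((other - 1) % m, -1) if direction == +1 else (other, +1)

    unvisited = set(range(m))
    loops = 0
    while unvisited:
        start = unvisited.pop()
        state = (start, +1)
        while True:
            state = step(*state)
            edge, _ = state
            if edge == start and state[1] == +1:
                break
            unvisited.discard(edge)
        loops += 1
    return loops


def kauffman_determinant(diagram) -> int:
    """|V(-1)| via the bracket state sum — equals the knot determinant."""
    code = list(diagram.code)
    if not code:
        return 1
    cids = sorted({c for c, _, _ in code})
    writhe = sum(s for c, o, s in code if o)
    A = np.exp(1j * np.pi / 4)
    delta = -(A ** 2) - (A ** -2)
    total = 0j
    for bits in product((True, False), repeat=len(cids)):
        choice = dict(zip(cids, bits))
        a = sum(bits)
        b = len(cids) - a
        loops = _count_loops(code, choice)
        total += (A ** (a - b)) * (delta ** (loops - 1))
    f = ((-A ** 3) ** (-writhe)) * total
    return int(round(abs(f)))


# --------------------------------------------------------------------------
# Planar crossing count by direct segment-pair intersection
# --------------------------------------------------------------------------


def brute_crossing_count(points3d: np.ndarray, direction: np.ndarray, closed: bool) -> int:
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    h = np.array([1.0, 0, 0]) if abs(d[0]) < 0.9 else np.array([0.0, 1, 0])
    u = np.cross(d, h); u /= np.linalg.norm(u)
    v = np.cross(d, u)
    p2 = np.column_stack([points3d @ u, points3d @ v])
    n = len(p2)
    nseg = n if closed else n - 1
    count = 0
    for i in range(nseg):
        for j in range(i + 2, nseg):
            if closed and i == 0 and j == nseg - 1:
                continue
            a, b = p2[i], p2[(i + 1) % n]
            c, e = p2[j], p2[(j + 1) % n]
            r, s = b - a, e - c
            den = r[0] * s[1] - r[1] * s[0]
            if abs(den) < 1e-12:
                continue
            q = c - a
            t = (q[0] * s[1] - q[1] * s[0]) / den
            w = (q[0] * r[1] - q[1] * r[0]) / den
            if 0 < t < 1 and 0 < w < 1:
                count += 1
    return count


# --------------------------------------------------------------------------
# Segment–triangle piercing, independent formulation
# --------------------------------------------------------------------------


def brute_piercing(loop_vertices: np.ndarray, apex: np.ndarray, p: np.ndarray, q: np.ndarray):
    """Signed piercing count of segment pq through the apex-fan surface,
    by solving p + t(q-p) = apex + u(a-apex) + w(b-apex) per triangle.
    Returns None when any incidence is too close to call."""
    total = 0
    nv = len(loop_vertices)
    for i in range(nv):
        a = loop_vertices[i]
        b = loop_vertices[(i + 1) % nv]
        mat = np.column_stack([q - p, -(a - apex), -(b - apex)])
        if abs(np.linalg.det(mat)) < 1e-12:
            continue
        t, u, w = np.linalg.solve(mat, apex - p)
        eps = 1e-9
        strict = (eps < t < 1 - eps) and u > eps and w > eps and u + w < 1 - eps
        loose = (-eps < t < 1 + eps) and u > -eps and w > -eps and u + w < 1 + eps
        if loose and not strict:
            return None  # grazing: ambiguous for the oracle
        if strict:
            normal = np.cross(a - apex, b - apex)
            total += 1 if float((q - p) @ normal) > 0 else -1
    return total


# --------------------------------------------------------------------------
# Exhaustive cycle enumeration in a segment/bridge graph
# --------------------------------------------------------------------------


def brute_cycles(nodes, edges, max_bridges) -> set[frozenset]:
    """All simple cycles (as frozensets of edge indices) with 1..max_bridges
    bridge edges, by exhaustive DFS over the edge list."""
    adjacency = {n: [] for n in nodes}
    for ei, (kind, a, b) in enumerate(edges):
        adjacency[a].append((ei, kind, b))
        adjacency[b].append((ei, kind, a))
    found: set[frozenset] = set()

    def walk(start, node, used, visited, nb):
        for ei, kind, nxt in adjacency[node]:
            if ei in used:
                continue
            nb2 = nb + (kind == "bridge")
            if nb2 > max_bridges:
                continue
            if nxt == start:
                if nb2 >= 1:
                    found.add(frozenset(used | {ei}))
                continue
            if nxt in visited:
                continue
            walk(start, nxt, used | {ei}, visited | {nxt}, nb2)

    for n in nodes:
        walk(n, n, set(), {n}, 0)
    return found
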