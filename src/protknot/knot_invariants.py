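"""Polynomial invariants of closed-curve diagrams and knot-type naming.

The Alexander polynomial Δ(t) is computed from the crossing/arc incidence
matrix of the Wirtinger presentation (Fox calculus): one row per crossing,
one column per arc, delete one row and one column, take the determinant,
and normalize so that the lowest degree is 0 and Δ(1) = +1.  |Δ(−1)| is
the knot determinant.

The HOMFLY-PT polynomial P(a, z) is computed by skein recursion

    a·P(L+) − a⁻¹·P(L−) = z·P(L0)

resolving, at each step, the first crossing (in traversal order) whose
first visit passes *under* — switching it moves the diagram toward a
descending (therefore trivial) one, smoothing it removes a crossing, so
the recursion terminates.  Diagrams are held as extended Gauss codes;
combinatorial Reidemeister I/II reductions and memoization keep the
recursion tractable for the small diagrams that survive KMT reduction.

Knot types are named against a packaged table of prime knots through 7
crossings keyed by the Alexander coefficient vector, with chirality
(suffix ``+``/``-``) resolved by HOMFLY-PT only: the suffix is ``+`` when
the HOMFLY-PT terms are weighted toward positive powers of ``a`` (the
right-handed torus knots come out ``+`` under this convention).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from importlib import resources

from .errors import TopologyError
from .geometry import Diagram
from .laurent import Laurent

__all__ = [
    "KnotType",
    "alexander",
    "alexander_determinant",
    "homfly",
    "classify_knot",
    "load_knot_table",
    "UNKNOWN",
    "COMPOSITE",
]

# A code component is a tuple of encounters (cid, over: bool, sign: int);
# a code is a tuple of components (HOMFLY recursion creates multi-component
# links even though classification inputs are single closed curves).
Component = tuple[tuple[int, bool, int], ...]
Code = tuple[Component, ...]


@dataclass(frozen=True)
class KnotType:
    """A named knot type, e.g. ``3_1+``, ``0_1``, ``composite``, ``unknown``."""

    base: str
    chirality: str = ""  # "", "+", "-"

    @property
    def name(self) -> str:
        return self.base + self.chirality

    @property
    def is_trivial(self) -> bool:
        return self.base == "0_1"

    def __str__(self) -> str:
        return self.name


UNKNOWN = KnotType("unknown")
COMPOSITE = KnotType("composite")
TRIVIAL = KnotType("0_1")


# --------------------------------------------------------------------------
# Gauss-code plumbing
# --------------------------------------------------------------------------


def diagram_code(diagram: Diagram) -> Code:
    if diagram.n_endpoints != 0:
        raise TopologyError("need a closed diagram (use the knotoid invariants for open ones)")
    return (tuple(diagram.code),)


def _relabel(code: Code) -> Code:
    """Renumber crossing ids by order of first appearance (canonical-ish)."""
    mapping: dict[int, int] = {}
    out = []
    for comp in code:
        cc = []
        for cid, over, sign in comp:
            if cid not in mapping:
                mapping[cid] = len(mapping)
            cc.append((mapping[cid], over, sign))
        out.append(tuple(cc))
    return tuple(out)


def _remove_crossings(code: Code, cids: set[int]) -> Code:
    return tuple(
        tuple(e for e in comp if e[0] not in cids) for comp in code
    )


def reduce_code(code: Code) -> Code:
    """Apply combinatorial Reidemeister I and II moves until stable."""
    changed = True
    while changed:
        changed = False
        # R1: the two encounters of a crossing are cyclically adjacent
        for comp in code:
            m = len(comp)
            for p in range(m):
                if m >= 2 and comp[p][0] == comp[(p + 1) % m][0]:
                    code = _remove_crossings(code, {comp[p][0]})
                    changed = True
                    break
            if changed:
                break
        if changed:
            continue
        # R2: crossings x, y adjacent over/over on one strand and
        # under/under on another, with opposite signs (a bigon, not a clasp)
        adj: dict[frozenset[int], list[tuple[bool, bool]]] = {}
        sign_of: dict[int, int] = {}
        for comp in code:
            m = len(comp)
            for p in range(m):
                cid, over, sign = comp[p]
                sign_of[cid] = sign
                q = (p + 1) % m
                if m < 2:
                    continue
                cid2, over2, _ = comp[q]
                if cid != cid2:
                    adj.setdefault(frozenset((cid, cid2)), []).append((over, over2))
        for pair, patterns in adj.items():
            if len(pair) != 2:
                continue
            x, y = tuple(pair)
            if sign_of[x] != -sign_of[y]:
                continue
            has_over = any(a and b for a, b in patterns)
            has_under = any((not a) and (not b) for a, b in patterns)
            if has_over and has_under:
                code = _remove_crossings(code, {x, y})
                changed = True
                break
    return _relabel(code)


def _smooth(code: Code, cid: int) -> Code:
    """Oriented (skein L0) smoothing of crossing ``cid``."""
    locs = []
    for ci, comp in enumerate(code):
        for p, e in enumerate(comp):
            if e[0] == cid:
                locs.append((ci, p))
    (c1, p1), (c2, p2) = locs
    if c1 == c2:
        comp = code[c1]
        if p1 > p2:
            p1, p2 = p2, p1
        inner = comp[p1 + 1:p2]
        outer = comp[p2 + 1:] + comp[:p1]
        rest = tuple(c for i, c in enumerate(code) if i != c1)
        return rest + (inner, outer)
    else:
        a, b = code[c1], code[c2]
        merged = a[:p1] + b[p2 + 1:] + b[:p2] + a[p1 + 1:]
        rest = tuple(c for i, c in enumerate(code) if i not in (c1, c2))
        return rest + (merged,)


def _switch(code: Code, cid: int) -> Code:
    return tuple(
        tuple(
            (c, (not o) if c == cid else o, -s if c == cid else s)
            for c, o, s in comp
        )
        for comp in code
    )


def _first_bad(code: Code) -> tuple[int, int] | None:
    """First crossing (id, sign) whose first visit is an under-pass."""
    seen: set[int] = set()
    for comp in code:
        for cid, over, sign in comp:
            if cid in seen:
                continue
            seen.add(cid)
            if not over:
                return cid, sign
    return None


_DELTA = Laurent({(1, -1): 1, (-1, -1): -1})  # (a - a^-1)/z


class _CrossingLimit(Exception):
    pass


def _homfly_rec(code: Code, memo: dict[Code, Laurent], limit: int) -> Laurent:
    code = reduce_code(code)
    n = sum(len(c) for c in code) // 2
    if n > limit:
        raise _CrossingLimit(n)
    if n == 0:
        return _DELTA ** (len(code) - 1) if len(code) > 1 else Laurent.const(1, arity=2)
    cached = memo.get(code)
    if cached is not None:
        return cached
    bad = _first_bad(code)
    if bad is None:
        # descending diagram: an unlink
        out = _DELTA ** (len(code) - 1)
    else:
        cid, sign = bad
        p_sw = _homfly_rec(_switch(code, cid), memo, limit)
        p_sm = _homfly_rec(_smooth(code, cid), memo, limit)
        if sign > 0:
            out = (
                Laurent.monomial(1, -2, 0) * p_sw
                + Laurent.monomial(1, -1, 1) * p_sm
            )
        else:
            out = (
                Laurent.monomial(1, 2, 0) * p_sw
                - Laurent.monomial(1, 1, 1) * p_sm
            )
    memo[code] = out
    return out


def homfly(diagram: Diagram | Code, max_crossings: int = 30) -> Laurent | None:
    """HOMFLY-PT polynomial P(a, z) of a closed diagram (unknot -> 1).

    Returns ``None`` when the reduced diagram still exceeds
    ``max_crossings`` (callers fall back to Alexander-only naming).
    """
    code = diagram_code(diagram) if isinstance(diagram, Diagram) else diagram
    try:
        return _homfly_rec(reduce_code(code), {}, max_crossings)
    except _CrossingLimit:
        return None


def mirror_code(code: Code) -> Code:
    return tuple(
        tuple((c, not o, -s) for c, o, s in comp) for comp in code
    )


# --------------------------------------------------------------------------
# Alexander polynomial
# --------------------------------------------------------------------------


def _int_det(m: list[list[int]]) -> int:
    """Fraction-free (Bareiss) determinant of an integer matrix."""
    n = len(m)
    if n == 0:
        return 1
    m = [row[:] for row in m]
    sign = 1
    prev = 1
    for k in range(n - 1):
        if m[k][k] == 0:
            for r in range(k + 1, n):
                if m[r][k] != 0:
                    m[k], m[r] = m[r], m[k]
                    sign = -sign
                    break
            else:
                return 0
        for i in range(k + 1, n):
            for j in range(k + 1, n):
                m[i][j] = (m[i][j] * m[k][k] - m[i][k] * m[k][j]) // prev
        prev = m[k][k]
    return sign * m[n - 1][n - 1]


def alexander(diagram: Diagram | Code) -> Laurent:
    """Alexander polynomial Δ(t), normalized to lowest degree 0, Δ(1) = 1."""
    code = diagram_code(diagram) if isinstance(diagram, Diagram) else diagram
    code = reduce_code(code)
    if len(code) != 1:
        raise TopologyError("Alexander polynomial requires a single-component diagram")
    comp = code[0]
    n = len(comp) // 2
    if n <= 1:
        return Laurent.const(1)

    # arc labels: arcs are delimited by under-passes; n crossings -> n arcs
    rows_at = []  # (cid, sign, over_arc or None, under_in, under_out)
    arc = 0
    over_arc: dict[int, int] = {}
    unders: dict[int, tuple[int, int]] = {}
    signs: dict[int, int] = {}
    for cid, over, sign in comp:
        signs[cid] = sign
        if over:
            over_arc[cid] = arc % n
        else:
            unders[cid] = (arc, (arc + 1) % n)
            arc += 1
    assert arc == n

    # rows: entries are degree<=1 polynomials c0 + c1*t
    mat0 = [[0] * n for _ in range(n)]
    mat1 = [[0] * n for _ in range(n)]
    for k, cid in enumerate(sorted(signs)):
        o = over_arc[cid]
        i, j = unders[cid]
        if signs[cid] > 0:
            # over: 1 - t, under_in: t, under_out: -1
            mat0[k][o] += 1
            mat1[k][o] -= 1
            mat1[k][i] += 1
            mat0[k][j] -= 1
        else:
            # over: t - 1, under_in: 1, under_out: -t
            mat0[k][o] -= 1
            mat1[k][o] += 1
            mat0[k][i] += 1
            mat1[k][j] -= 1

    # delete last row and column; evaluate determinant at integer points and
    # interpolate exactly (degree <= n-1)
    size = n - 1
    deg = size
    xs = list(range(2, 2 + deg + 1))
    ys = []
    for x in xs:
        m = [
            [mat0[r][c] + mat1[r][c] * x for c in range(size)]
            for r in range(size)
        ]
        ys.append(_int_det(m))
    coeffs = _lagrange_int(xs, ys)
    poly = Laurent({(e,): c for e, c in enumerate(coeffs)})
    if not poly:
        raise TopologyError("vanishing Alexander determinant — invalid diagram")
    lo, _ = poly.degree_span(0)
    poly = poly.shift(0, -lo)
    at1 = poly.substitute(0, 1)
    if at1 == -1:
        poly = -poly
    elif at1 != 1:
        raise TopologyError(f"Alexander normalization failed (Delta(1) = {at1})")
    return poly


def _lagrange_int(xs: list[int], ys: list[int]) -> list[int]:
    """Exact Lagrange interpolation with integer result."""
    k = len(xs)
    coeffs = [Fraction(0)] * k
    for i in range(k):
        # basis polynomial for node i
        basis = [Fraction(1)]
        denom = Fraction(1)
        for j in range(k):
            if j == i:
                continue
            # multiply basis by (x - xs[j])
            nxt = [Fraction(0)] * (len(basis) + 1)
            for d, c in enumerate(basis):
                nxt[d] -= c * xs[j]
                nxt[d + 1] += c
            basis = nxt
            denom *= xs[i] - xs[j]
        w = Fraction(ys[i]) / denom
        for d, c in enumerate(basis):
            coeffs[d] += c * w
    out = []
    for c in coeffs:
        if c.denominator != 1:
            raise TopologyError("non-integer Alexander coefficients")
        out.append(int(c))
    while len(out) > 1 and out[-1] == 0:
        out.pop()
    return out


def alexander_determinant(diagram: Diagram | Code) -> int:
    """|Δ(−1)| — the knot determinant."""
    return int(abs(alexander(diagram).substitute(0, -1)))


# --------------------------------------------------------------------------
# Classification
# --------------------------------------------------------------------------


@lru_cache(maxsize=1)
def load_knot_table() -> dict[tuple[int, ...], dict]:
    """The packaged invariant table, keyed by Alexander coefficients."""
    text = resources.files("protknot.data").joinpath("knot_table.json").read_text()
    data = json.loads(text)
    table: dict[tuple[int, ...], dict] = {}
    for entry in data["knots"]:
        key = tuple(entry["alexander"])
        if key in table:
            raise ValueError(f"knot table not separated by Alexander: {entry['name']}")
        table[key] = entry
    return table


def _chirality_suffix(p: Laurent) -> str:
    """``+`` when HOMFLY-PT weight sits at positive powers of a."""
    score = sum(k[0] * abs(c) for k, c in p.terms.items())
    if score > 0:
        return "+"
    if score < 0:
        return "-"
    return ""


def classify_knot(
    diagram: Diagram | Code,
    homfly_limit: int = 30,
    resolve_chirality: bool = True,
) -> KnotType:
    """Name the knot type of a closed diagram.

    The Alexander coefficient vector is matched against the packaged table
    of prime knots through 7 crossings; chirality of chiral matches is
    resolved with HOMFLY-PT when the reduced diagram is small enough.  An
    Alexander polynomial that factors as a product of two table entries is
    reported as ``composite``; anything else unmatched is ``unknown``.
    """
    code = diagram_code(diagram) if isinstance(diagram, Diagram) else diagram
    code = reduce_code(code)
    try:
        poly = alexander(code)
    except TopologyError:
        return UNKNOWN
    key = poly.coeffs_1d()
    table = load_knot_table()
    entry = table.get(key)
    if entry is not None:
        if not entry["chiral"] or not resolve_chirality:
            return KnotType(entry["name"])
        p = homfly(code, max_crossings=homfly_limit)
        if p is None:
            return KnotType(entry["name"])
        pm = p.invert_variable(0)
        if p == pm:
            return KnotType(entry["name"])
        return KnotType(entry["name"], _chirality_suffix(p))
    # composite: product of two (possibly equal) table polynomials
    polys = {
        name_key: Laurent({(e,): c for e, c in enumerate(name_key)})
        for name_key in table
        if name_key != (1,)
    }
    keys = list(polys)
    for i, k1 in enumerate(keys):
        for k2 in keys[i:]:
            prod = polys[k1] * polys[k2]
            if prod.coeffs_1d() == key:
                return COMPOSITE
    return UNKNOWN
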