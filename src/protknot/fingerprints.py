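"""Knotting and knotoid fingerprints: subchain-resolved topology.

The fingerprint of a chain is a lower-triangular matrix over subchains
(start, end): each cell records the dominant knot (or knotoid) type of
that subchain together with its probability, the whole chain sitting in
the matrix corner.  Fingerprints reveal structure invisible at the
whole-chain level: a *slipknot* is a chain that is trivial as a whole but
contains a knotted subchain, and a *slipknotoid* is the knotoid
analogue.  The *core* is the shortest subchain sharing the whole chain's
type; the residues outside it form the N- and C-tails.

Cells are evaluated on a stride grid (full per-residue resolution is
quadratically expensive) with the dominant-type sampling reduced per
cell and the whole-chain corner recomputed at full sampling; the core
boundary is then refined to single-residue precision by bisection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, TopologyError
from .geometry import PolygonalCurve
from .probabilistic import dominant_type, knot_spectrum, knotoid_distribution

__all__ = [
    "FingerprintMatrix",
    "CoreAnnotation",
    "EntanglementLabels",
    "knot_fingerprint",
    "knotoid_fingerprint",
    "locate_core",
    "classify_entanglement",
    "fingerprint_to_tsv",
]

MIN_SUBCHAIN = 5  # residues; shorter subchains cannot be entangled


@dataclass
class FingerprintMatrix:
    """Lower-triangular subchain -> (dominant type, probability) matrix.

    Keys of ``cells`` are residue labels ``(start, end)`` with
    start < end; ``residue_ids[i]`` labels vertex ``i`` of the analyzed
    curve.  The whole-chain cell is the matrix corner.
    """

    cells: dict[tuple[int, int], tuple[object, float]]
    residue_ids: list[int]
    stride: int
    kind: str  # "knot" | "knotoid"
    whole_chain: tuple[int, int]
    sampling: str = ""
    _curve: PolygonalCurve | None = field(default=None, repr=False)
    _cell_n: int = 0
    _seed: int | None = None

    @property
    def whole_chain_type(self):
        return self.cells[self.whole_chain][0]

    def nontrivial_cells(self) -> list[tuple[int, int]]:
        return [
            k
            for k, (t, _) in self.cells.items()
            if not t.is_trivial and t.name != "unknown"
        ]


@dataclass
class CoreAnnotation:
    """Shortest subchain sharing the whole-chain type, plus tail lengths."""

    core_start: int
    core_end: int
    n_tail: int
    c_tail: int
    core_type: object = None


@dataclass
class EntanglementLabels:
    knot_label: str  # "knot" | "slipknot" | "trivial"
    knotoid_label: str | None  # "knotoid" | "slipknotoid" | "trivial" | None


def _subcurve(curve: PolygonalCurve, i: int, j: int) -> PolygonalCurve:
    return PolygonalCurve(curve.vertices[i: j + 1], closed=False)


def _grid(n: int, stride: int) -> list[int]:
    idx = list(range(0, n, stride))
    if idx[-1] != n - 1:
        idx.append(n - 1)
    return idx


def default_stride(n_residues: int) -> int:
    """Bounds the grid to roughly 5000 subchain analyses."""
    return max(1, n_residues // 100)


def _fingerprint(
    curve: PolygonalCurve,
    residue_ids: list[int] | None,
    classify_cell,
    kind: str,
    stride: int | None,
    sampling: str,
    cell_n: int,
    seed: int | None,
) -> FingerprintMatrix:
    if curve.closed:
        raise GeometryError("fingerprints are defined for open chains")
    n = len(curve)
    if residue_ids is None:
        residue_ids = list(range(1, n + 1))
    if len(residue_ids) != n:
        raise ValueError("residue_ids must label every vertex")
    if stride is None:
        stride = default_stride(n)
    if stride < 1:
        raise ValueError("stride must be >= 1")
    grid = _grid(n, stride)
    cells: dict[tuple[int, int], tuple[object, float]] = {}
    for a_pos, i in enumerate(grid):
        for j in grid[a_pos + 1:]:
            if j - i < MIN_SUBCHAIN:
                continue
            full = i == 0 and j == n - 1
            t, p = classify_cell(_subcurve(curve, i, j), full)
            cells[(residue_ids[i], residue_ids[j])] = (t, p)
    whole = (residue_ids[0], residue_ids[-1])
    if whole not in cells:  # tiny chains below the grid
        t, p = classify_cell(curve, True)
        cells[whole] = (t, p)
    return FingerprintMatrix(
        cells=cells,
        residue_ids=list(residue_ids),
        stride=stride,
        kind=kind,
        whole_chain=whole,
        sampling=sampling,
        _curve=curve,
        _cell_n=cell_n,
        _seed=seed,
    )


def knot_fingerprint(
    curve: PolygonalCurve,
    residue_ids: list[int] | None = None,
    n_closures: int = 20,
    stride: int | None = None,
    full_n: int = 100,
    seed: int | None = None,
) -> FingerprintMatrix:
    """Dominant knot type of every stride-grid subchain.

    Subchain cells use ``n_closures`` stochastic closures; the
    whole-chain corner is recomputed at ``full_n``.
    """

    def cell(sub: PolygonalCurve, full: bool):
        sp = knot_spectrum(sub, n=full_n if full else n_closures, seed=seed)
        return dominant_type(sp)

    return _fingerprint(
        curve,
        residue_ids,
        cell,
        "knot",
        stride,
        f"closures={n_closures}/full={full_n}",
        n_closures,
        seed,
    )


def knotoid_fingerprint(
    curve: PolygonalCurve,
    residue_ids: list[int] | None = None,
    n_directions: int = 20,
    stride: int | None = None,
    full_n: int = 100,
    seed: int | None = None,
) -> FingerprintMatrix:
    """Dominant knotoid type of every stride-grid subchain."""

    def cell(sub: PolygonalCurve, full: bool):
        kd = knotoid_distribution(sub, n_directions=full_n if full else n_directions, seed=seed)
        return dominant_type(kd)

    return _fingerprint(
        curve,
        residue_ids,
        cell,
        "knotoid",
        stride,
        f"directions={n_directions}/full={full_n}",
        n_directions,
        seed,
    )


def _cell_type(matrix: FingerprintMatrix, i: int, j: int):
    """Dominant type of the vertex-index subchain (i, j), recomputed.

    Uses the same sampling as the grid cells so that the bisection's
    decisions are consistent with an equally-sampled per-residue scan."""
    n = matrix._cell_n
    sub = _subcurve(matrix._curve, i, j)
    if matrix.kind == "knot":
        sp = knot_spectrum(sub, n=n, seed=matrix._seed)
    else:
        sp = knotoid_distribution(sub, n_directions=n, seed=matrix._seed)
    return dominant_type(sp)[0]


def locate_core(matrix: FingerprintMatrix) -> CoreAnnotation:
    """Shortest subchain whose type equals the whole-chain type.

    Scans the stride grid for the minimal matching cell (ties toward the
    smallest start residue), then bisects each boundary down to
    single-residue precision.
    """
    whole_t = matrix.whole_chain_type
    if whole_t.is_trivial:
        raise TopologyError("no core: the whole chain is trivial")
    rid = matrix.residue_ids
    pos = {r: i for i, r in enumerate(rid)}
    matching = [
        (s, e)
        for (s, e), (t, _) in matrix.cells.items()
        if t.name == whole_t.name
    ]
    s_res, e_res = min(matching, key=lambda se: (pos[se[1]] - pos[se[0]], pos[se[0]]))
    i, j = pos[s_res], pos[e_res]

    if matrix._curve is not None and matrix.stride > 1:
        def holds(ii, jj):
            return _cell_type(matrix, ii, jj).name == whole_t.name

        # bisection within the grid cell, assuming monotone containment
        lo, hi = i, min(i + matrix.stride - 1, len(rid) - 1)
        while lo < hi:  # largest start that still holds
            mid = (lo + hi + 1) // 2
            if mid < j and holds(mid, j):
                lo = mid
            else:
                hi = mid - 1
        i = lo
        lo, hi = max(j - matrix.stride + 1, i + 1), j
        while lo < hi:  # smallest end that still holds
            mid = (lo + hi) // 2
            if holds(i, mid):
                hi = mid
            else:
                lo = mid + 1
        j = lo
        # dominance is not exactly monotone near the 50% boundary, so the
        # bisection can stall in a local minimum; a bounded minimal-length
        # sweep within one stride of the grid cell recovers the shortest
        # window the grid resolution can support
        n = len(rid)
        s_lo = max(0, i - matrix.stride)
        s_hi = min(n - 2, i + matrix.stride)
        e_lo = max(s_lo + MIN_SUBCHAIN, j - matrix.stride)
        e_hi = min(n - 1, j + matrix.stride)
        best_len = j - i
        for length in range(MIN_SUBCHAIN, best_len):
            found = False
            for s in range(s_lo, s_hi + 1):
                e = s + length
                if e < e_lo or e > e_hi:
                    continue
                if holds(s, e):
                    i, j = s, e
                    found = True
                    break
            if found:
                break
    return CoreAnnotation(
        core_start=rid[i],
        core_end=rid[j],
        n_tail=i,
        c_tail=len(rid) - 1 - j,
        core_type=whole_t,
    )


def classify_entanglement(
    knot_matrix: FingerprintMatrix | None,
    knotoid_matrix: FingerprintMatrix | None = None,
) -> EntanglementLabels:
    """Chain-level labels from the fingerprint matrices.

    knot: non-trivial whole chain; slipknot: trivial whole chain with a
    non-trivial subchain cell; analogous labels for knotoids.
    """

    def label(matrix, full_name, slip_name):
        if matrix is None:
            return None
        if not matrix.whole_chain_type.is_trivial and matrix.whole_chain_type.name != "unknown":
            return full_name
        cells = [c for c in matrix.nontrivial_cells() if c != matrix.whole_chain]
        return slip_name if cells else "trivial"

    return EntanglementLabels(
        knot_label=label(knot_matrix, "knot", "slipknot"),
        knotoid_label=label(knotoid_matrix, "knotoid", "slipknotoid"),
    )


def fingerprint_to_tsv(matrix: FingerprintMatrix) -> str:
    """TSV export: start, end, dominant type, probability."""
    lines = ["start\tend\ttype\tprobability"]
    for (s, e), (t, p) in sorted(matrix.cells.items()):
        lines.append(f"{s}\t{e}\t{t.name}\t{p:.4f}")
    return "\n".join(lines) + "\n"
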