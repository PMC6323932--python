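"""Synthetic fixtures: parametric knots, slipknots, bridge and
cystine-knot geometries, and toy PDB writing.

These generators stand in for experimental structures so that every
stage of the pipeline is testable without downloads.  All of them are
deterministic given a seed; coordinates are protein-like in scale (a few
ångströms between consecutive Cα positions).

The torus-knot parametrization with ``(p, q) = (2, 3)`` realizes the
trefoil used throughout: its closed polygon classifies as 3_1, the *open
trefoil* removes one edge and retracts the ends radially to the convex
hull (so stochastic closure is nearly unambiguous), and the *slipknot*
continues the open trefoil with a tail that retraces back out through
the knotted region, cancelling the entanglement of the whole chain while
leaving the knotted subchain intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import PolygonalCurve
from .structure_io import Bridge, ChainModel, Residue, detect_disulfide_bridges

__all__ = [
    "FixtureSpec",
    "make_fixture",
    "torus_knot_curve",
    "open_trefoil_curve",
    "slipknot_curve",
    "straight_curve",
    "chain_from_points",
    "ck_motif_chain",
    "bridged_loop_chain",
    "write_fixture_pdb",
]


@dataclass
class FixtureSpec:
    kind: str  # torus_knot | open_trefoil | slipknot | straight | ck_motif | bridged_loop
    n_vertices: int = 60
    noise: float = 0.0
    seed: int = 0
    params: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# Curve generators
# --------------------------------------------------------------------------


def _noise(pts: np.ndarray, noise: float, seed: int) -> np.ndarray:
    if noise <= 0:
        return pts
    rng = np.random.default_rng(seed)
    return pts + rng.normal(scale=noise, size=pts.shape)


def torus_knot_curve(
    p: int = 2,
    q: int = 3,
    n: int = 60,
    noise: float = 0.0,
    seed: int = 0,
    major: float = 12.0,
    minor: float = 4.8,
) -> PolygonalCurve:
    """Closed (p, q) torus-knot polygon; (2, 3) is the trefoil (3_1)."""
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    x = (major + minor * np.cos(q * t)) * np.cos(p * t)
    y = (major + minor * np.cos(q * t)) * np.sin(p * t)
    z = minor * np.sin(q * t)
    pts = _noise(np.column_stack([x, y, z]), noise, seed)
    return PolygonalCurve(pts, closed=True)


def open_trefoil_curve(
    n: int = 60,
    noise: float = 0.0,
    seed: int = 0,
    retract: float = 12.0,
) -> PolygonalCurve:
    """Open trefoil: the (2,3) torus polygon with one edge removed and the
    two ends retracted radially to the hull (a deeply knotted open chain)."""
    closed = torus_knot_curve(2, 3, n=n, noise=noise, seed=seed)
    pts = closed.vertices[1:].copy()
    centre = pts.mean(axis=0)
    for idx in (0, -1):
        v = pts[idx] - centre
        v[2] = 0.0
        nv = np.linalg.norm(v)
        if nv > 0:
            pts[idx] = pts[idx] + retract * v / nv
    return PolygonalCurve(pts, closed=False)


def slipknot_curve(
    n_knot: int = 50,
    n_tail: int = 25,
    noise: float = 0.0,
    seed: int = 0,
    offset: float = 1.2,
) -> PolygonalCurve:
    """A slipknot: a trefoil-shaped stretch whose tail retraces back out.

    The first part follows the cut trefoil polygon; the tail then shadows
    it in reverse at a small outward offset, pulling the end back through
    the knotted region, and finally exits radially.  The whole chain
    closes to the unknot while the knotted subchain (the first part)
    closes to 3_1.
    """
    closed = torus_knot_curve(2, 3, n=n_knot + 1, noise=0.0, seed=seed)
    knot = closed.vertices[1:].copy()  # open path, ends spatially close
    centre = knot.mean(axis=0)
    tail = []
    n_tail = min(n_tail, len(knot) - 2)
    for k in range(1, n_tail + 1):
        base = knot[len(knot) - 1 - k]
        v = base - centre
        nv = np.linalg.norm(v)
        tail.append(base + offset * v / nv)
    # exit radially outward from the last shadowed position
    last = tail[-1]
    v = last - centre
    v[2] = 0.0
    v /= np.linalg.norm(v)
    exit_pts = [last + v * d for d in (6.0, 12.0, 18.0)]
    pts = np.vstack([knot, tail, exit_pts])
    return PolygonalCurve(_noise(pts, noise, seed), closed=False)


def straight_curve(n: int = 10, noise: float = 0.0, seed: int = 0) -> PolygonalCurve:
    pts = np.column_stack([np.linspace(0, 3.8 * (n - 1), n), np.zeros(n), np.zeros(n)])
    return PolygonalCurve(_noise(pts, noise, seed), closed=False)


# --------------------------------------------------------------------------
# ChainModel assembly
# --------------------------------------------------------------------------


def chain_from_points(
    points: np.ndarray,
    cys_pairs: list[tuple[int, int]] | None = None,
    source_id: str = "FIXTURE_A",
    seq_indices: list[int] | None = None,
) -> ChainModel:
    """Wrap raw Cα positions as a ChainModel.

    ``cys_pairs`` lists 1-based residue-index pairs to connect by
    disulfide bridges: those residues become CYS with SG atoms placed
    2.03 Å apart along the Cα–Cα line, and matching declared (SSBOND)
    records are added; bridges are then detected the normal way.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    seq = seq_indices or list(range(1, n + 1))
    cys_pairs = cys_pairs or []
    cys_res = {r for pair in cys_pairs for r in pair}
    pos = {s: points[i] for i, s in enumerate(seq)}
    residues = [
        Residue(
            chain_id="A",
            seq_index=s,
            name="CYS" if s in cys_res else "ALA",
            ca_xyz=tuple(float(v) for v in pos[s]),
        )
        for s in seq
    ]
    sg: dict[int, tuple[float, float, float]] = {}
    for a, b in cys_pairs:
        ca_a, ca_b = pos[a], pos[b]
        mid = 0.5 * (ca_a + ca_b)
        u = ca_b - ca_a
        nu = np.linalg.norm(u)
        u = u / nu if nu > 0 else np.array([1.0, 0.0, 0.0])
        sg[a] = tuple(float(v) for v in (mid - 1.015 * u))
        sg[b] = tuple(float(v) for v in (mid + 1.015 * u))
    chain = ChainModel(
        residues=residues,
        source_id=source_id,
        sg_atoms=sg,
        declared_ss=[tuple(sorted(p)) for p in cys_pairs],
    )
    chain.bridges = detect_disulfide_bridges(chain)
    return chain


def bridged_loop_chain(
    n_knot: int = 50,
    n_tail: int = 25,
    lead_in: int = 3,
    noise: float = 0.0,
    seed: int = 0,
) -> ChainModel:
    """An unknotted backbone carrying a trefoil covalent loop.

    The backbone is the slipknot (whole-chain closure trivial) preceded
    by a short lead-in, with a disulfide bridging the two ends of the
    knotted stretch: the covalent loop backbone+bridge is a closed
    trefoil even though the backbone itself is not knotted.
    """
    slip = slipknot_curve(n_knot=n_knot, n_tail=n_tail, noise=noise, seed=seed)
    knot_start = slip.vertices[0]
    centre = slip.vertices[:n_knot].mean(axis=0)
    v = knot_start - centre
    v[2] = 0.0
    v /= np.linalg.norm(v)
    lead = [knot_start + v * d for d in np.linspace(10.0, 3.0, lead_in)]
    pts = np.vstack([lead, slip.vertices])
    # bridge joins the first and last residues of the trefoil stretch
    a = lead_in + 1
    b = lead_in + n_knot
    return chain_from_points(pts, cys_pairs=[(a, b)], source_id="BRIDGED_LOOP_A")


# --------------------------------------------------------------------------
# Cystine-knot geometries
# --------------------------------------------------------------------------

# Waypoint layouts: (x, y, z, tag) with tag numbering the six cysteines in
# spatial roles; the ring (two arcs + two bridges) lies in the y=0 plane
# and the piercing bridge runs along the y axis through its centre.


def _ring_arc(theta_deg_from: float, theta_deg_to: float, k: int, radius: float = 5.0):
    th = np.radians(np.linspace(theta_deg_from, theta_deg_to, k))
    return [(radius * np.cos(t), 0.0, radius * np.sin(t)) for t in th]


def _ck_waypoints_growth_factor():
    """Cys ranks: loop bridges (1,4), (2,5); piercer (3,6)."""
    upper = _ring_arc(170, 10, 6)  # cys1 .. cys2 (res 4..9)
    lower = _ring_arc(190, 350, 6)  # cys4 .. cys5 (res 19..24)
    pts: list[tuple] = []
    pts += [(-8, 3, 2), (-7, 2, 1.5), (-6, 1, 1.2)]          # approach
    pts += upper                                              # res 4..9 (cys1, cys2)
    pts += [(8, 0, 1), (8, -3, 1), (4, -4, 0.5), (1.5, -4, 0.2)]
    pts += [(0, -4, 0)]                                       # res 14 (cys3)
    pts += [(-2, -5, 0), (-6, -4, -0.5), (-7, -2, -0.8), (-6.5, -0.8, -0.9)]
    pts += lower                                              # res 19..24 (cys4, cys5)
    pts += [(7, 0.5, -1), (6, 2, -0.5), (4, 4, -0.3), (2, 4.5, 0)]
    pts += [(0, 4, 0)]                                        # res 29 (cys6)
    pts += [(-2, 6, 0.5), (-4, 7, 1), (-6, 8, 1.5)]           # exit
    cys = [4, 9, 14, 19, 24, 29]
    pairs = [(4, 19), (9, 24), (14, 29)]
    return np.array(pts, dtype=float), cys, pairs


def _ck_waypoints_inhibitor():
    """Cys ranks: loop bridges (2,5), (3,6); piercer (1,4)."""
    upper = _ring_arc(170, 10, 6)  # res 9..14 (cys2, cys3)
    lower = _ring_arc(190, 350, 6)  # res 24..29 (cys5, cys6)
    pts: list[tuple] = []
    pts += [(0, -8, 1), (0, -7, 0.6), (0, -5.5, 0.2)]         # approach
    pts += [(0, -4, 0)]                                       # res 4 (cys1)
    pts += [(-2, -5, 0.3), (-6, -4, 0.6), (-7, -2, 0.8), (-6.2, -0.9, 0.85)]
    pts += upper                                              # res 9..14
    pts += [(7, 0.5, 1), (6, 2, 0.8), (4, 4, 0.5), (2, 4.5, 0.2)]
    pts += [(0, 4, 0)]                                        # res 19 (cys4)
    pts += [(-2, 5, -0.2), (-6, 4, -0.5), (-7, 2, -0.7), (-6.2, 0.9, -0.85)]
    pts += lower                                              # res 24..29
    pts += [(7, -1, -1), (8, -3, -1.2), (9, -5, -1.4)]        # exit
    cys = [4, 9, 14, 19, 24, 29]
    pairs = [(9, 24), (14, 29), (4, 19)]
    return np.array(pts, dtype=float), cys, pairs


def _ck_waypoints_cyclic():
    """Growth-factor arrangement with head-to-tail cyclized termini."""
    pts, cys, pairs = _ck_waypoints_growth_factor()
    pts = pts.copy()
    pts[-3] = (-5, 6, 1.8)
    pts[-2] = (-7, 5, 2.0)
    pts[-1] = (-7.9, 3.8, 2.0)  # ends within 5 A of residue 1 at (-8, 3, 2)
    return pts, cys, pairs


def _subdivide(points: np.ndarray, factor: int, keep: list[int]):
    """Insert ``factor - 1`` interpolated residues on each segment, keeping
    track of where the ``keep`` (1-based) indices end up."""
    if factor <= 1:
        return points, {k: k for k in keep}
    out = []
    new_index = {}
    for i, p in enumerate(points):
        out.append(p)
        if (i + 1) in keep:
            new_index[i + 1] = len(out)
        if i + 1 < len(points):
            nxt = points[i + 1]
            for f in range(1, factor):
                out.append(p + (nxt - p) * f / factor)
    return np.asarray(out), new_index


def ck_motif_chain(ck_class: str = "growth_factor", expand: int = 1) -> ChainModel:
    """A synthetic cystine-knot chain of the requested class.

    ``expand`` subdivides every backbone segment, stretching the sequence
    span of the motif without changing its geometry (used to check that
    detection is independent of motif size).
    """
    builders = {
        "growth_factor": _ck_waypoints_growth_factor,
        "inhibitor": _ck_waypoints_inhibitor,
        "cyclic": _ck_waypoints_cyclic,
    }
    if ck_class not in builders:
        raise ValueError(f"unknown cysteine-knot class {ck_class!r}")
    pts, cys, pairs = builders[ck_class]()
    pts, remap = _subdivide(pts, expand, keep=sorted({r for p in pairs for r in p}))
    if expand > 1:
        pairs = [(remap[a], remap[b]) for a, b in pairs]
    return chain_from_points(pts, cys_pairs=pairs, source_id=f"CK_{ck_class.upper()}_A")


# --------------------------------------------------------------------------
# Dispatch + PDB writing
# --------------------------------------------------------------------------


def make_fixture(spec: FixtureSpec) -> ChainModel:
    """Build the ChainModel for a fixture spec (bridges where applicable)."""
    k = spec.kind
    if k == "torus_knot":
        p = spec.params.get("p", 2)
        q = spec.params.get("q", 3)
        curve = torus_knot_curve(p, q, n=spec.n_vertices, noise=spec.noise, seed=spec.seed)
        return chain_from_points(curve.vertices, source_id=f"TORUS_{p}_{q}_A")
    if k == "open_trefoil":
        curve = open_trefoil_curve(n=spec.n_vertices, noise=spec.noise, seed=spec.seed)
        return chain_from_points(curve.vertices, source_id="OPEN_TREFOIL_A")
    if k == "slipknot":
        curve = slipknot_curve(
            n_knot=spec.params.get("n_knot", 50),
            n_tail=spec.params.get("n_tail", 25),
            noise=spec.noise,
            seed=spec.seed,
        )
        return chain_from_points(curve.vertices, source_id="SLIPKNOT_A")
    if k == "straight":
        curve = straight_curve(n=spec.n_vertices, noise=spec.noise, seed=spec.seed)
        return chain_from_points(curve.vertices, source_id="STRAIGHT_A")
    if k == "ck_motif":
        return ck_motif_chain(
            spec.params.get("ck_class", "growth_factor"),
            expand=spec.params.get("expand", 1),
        )
    if k == "bridged_loop":
        return bridged_loop_chain(noise=spec.noise, seed=spec.seed)
    raise ValueError(f"unknown fixture kind {spec.kind!r}")


def write_fixture_pdb(chain: ChainModel, path) -> None:
    """Write a ChainModel as a toy PDB file (CA traces, SG atoms, SSBOND)."""
    import gemmi

    st = gemmi.Structure()
    st.name = chain.source_id or "FIXTURE"
    model = gemmi.Model("1")
    gchain = gemmi.Chain(chain.residues[0].chain_id if chain.residues else "A")
    for r in chain.residues:
        res = gemmi.Residue()
        res.name = r.name
        res.seqid = gemmi.SeqId(r.seq_index, " ")
        at = gemmi.Atom()
        at.name = "CA"
        at.element = gemmi.Element("C")
        at.pos = gemmi.Position(*r.ca_xyz)
        res.add_atom(at)
        if r.seq_index in chain.sg_atoms:
            sg = gemmi.Atom()
            sg.name = "SG"
            sg.element = gemmi.Element("S")
            sg.pos = gemmi.Position(*chain.sg_atoms[r.seq_index])
            res.add_atom(sg)
        gchain.add_residue(res)
    model.add_chain(gchain)
    # ions as single-atom hetero residues in their own chain
    if chain.ions:
        ich = gemmi.Chain("Z")
        for elem, num, pos in chain.ions:
            res = gemmi.Residue()
            res.name = elem
            res.seqid = gemmi.SeqId(num, " ")
            res.het_flag = "H"
            at = gemmi.Atom()
            at.name = elem
            at.element = gemmi.Element(elem.capitalize())
            at.pos = gemmi.Position(*pos)
            res.add_atom(at)
            ich.add_residue(res)
        model.add_chain(ich)
    st.add_model(model)
    cid = chain.residues[0].chain_id if chain.residues else "A"
    for a, b in chain.declared_ss:
        conn = gemmi.Connection()
        conn.type = gemmi.ConnectionType.Disulf
        conn.partner1 = gemmi.AtomAddress(cid, gemmi.SeqId(a, " "), "CYS", "SG")
        conn.partner2 = gemmi.AtomAddress(cid, gemmi.SeqId(b, " "), "CYS", "SG")
        st.connections.append(conn)
    st.setup_entities()
    with open(path, "w") as fh:
        fh.write(st.make_pdb_string())
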