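"""Structure reading: Cα backbones, gaps, disulfide and ion bridges.

Input formats are PDB and mmCIF (via gemmi) plus the plain ASCII xyz
trace dialect ``index x y z`` (one point per line).  Only Cα positions
enter the backbone trace; SG atoms of cysteines, metal ions, and
side-chain O/N/S atoms are retained internally for bridge detection.
Multi-model (NMR) files use the first model; alternate locations resolve
to the highest occupancy, ties broken by altloc letter.  A gap in the
main chain (missing residues) produces no extra vertices — the
connecting segment is implicitly straight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ParseError
from .geometry import PolygonalCurve

try:
    import gemmi
except ImportError as _exc:  # pragma: no cover
    gemmi = None
    _GEMMI_ERR = _exc

__all__ = [
    "Residue",
    "Bridge",
    "ChainModel",
    "parse_structure",
    "extract_backbone",
    "detect_disulfide_bridges",
    "detect_ion_bridges",
    "declare_bridges",
]

DEFAULT_SS_CUTOFF = 2.5  # Å, SG–SG
DEFAULT_ION_CUTOFF = 3.0  # Å, ion to side-chain O/N/S

_BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


@dataclass(frozen=True)
class Residue:
    chain_id: str
    seq_index: int  # author residue number
    name: str  # 3-letter code
    ca_xyz: tuple[float, float, float]
    has_gap_after: bool = False
    icode: str = ""

    @property
    def label(self) -> str:
        """Author index with any insertion code appended verbatim."""
        return f"{self.seq_index}{self.icode}"


@dataclass(frozen=True)
class Bridge:
    """A non-sequential residue–residue connection.

    ``kind`` is one of disulfide / ion / amide / other; ion bridges carry
    the mediating ion identity (element + residue number).  Endpoints are
    stored in canonical order ``res_a.seq_index < res_b.seq_index``.
    """

    kind: str
    res_a: int
    res_b: int
    mediator: str | None = None

    def __post_init__(self):
        if self.res_a == self.res_b:
            raise ValueError("bridge endpoints must differ")
        if self.res_a > self.res_b:
            a, b = self.res_b, self.res_a
            object.__setattr__(self, "res_a", a)
            object.__setattr__(self, "res_b", b)
        if self.kind == "ion" and not self.mediator:
            raise ValueError("ion bridges require a mediator")


@dataclass
class ChainModel:
    """One polypeptide chain: ordered residues, bridges, detection context."""

    residues: list[Residue]
    bridges: list[Bridge] = field(default_factory=list)
    source_id: str = ""
    # internal context for bridge detection
    sg_atoms: dict[int, tuple[float, float, float]] = field(default_factory=dict, repr=False)
    sidechain_donors: list[tuple[int, str, tuple[float, float, float]]] = field(
        default_factory=list, repr=False
    )
    ions: list[tuple[str, int, tuple[float, float, float]]] = field(
        default_factory=list, repr=False
    )
    declared_ss: list[tuple[int, int]] = field(default_factory=list, repr=False)

    def residue(self, seq_index: int) -> Residue:
        for r in self.residues:
            if r.seq_index == seq_index:
                return r
        raise KeyError(f"no residue {seq_index} in chain {self.source_id}")

    @property
    def seq_indices(self) -> list[int]:
        return [r.seq_index for r in self.residues]


# --------------------------------------------------------------------------
# Parsing
# --------------------------------------------------------------------------


def _detect_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".pdb", ".ent"):
        return "pdb"
    if suffix in (".cif", ".mmcif"):
        return "mmcif"
    if suffix in (".xyz", ".txt", ".dat"):
        return "xyz"
    raise ParseError(f"cannot infer format from '{path.name}'; pass format explicitly")


def parse_structure(path, fmt: str | None = None) -> list[ChainModel]:
    """Read a structure file into one :class:`ChainModel` per chain.

    ``fmt`` is one of ``pdb``, ``mmcif``, ``xyz`` (inferred from the
    extension when omitted).  Chains with fewer than two Cα atoms are
    skipped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    fmt = fmt or _detect_format(path)
    if fmt == "xyz":
        return _parse_xyz(path)
    if fmt not in ("pdb", "mmcif"):
        raise ParseError(f"unknown format '{fmt}'")
    if gemmi is None:  # pragma: no cover
        raise ParseError(f"gemmi unavailable: {_GEMMI_ERR}")
    try:
        st = gemmi.read_structure(str(path))
    except Exception as exc:
        raise ParseError(f"failed to parse {path.name}: {exc}") from exc
    return structure_to_chains(st, source=path.stem)


def _best_altloc(atoms) -> "gemmi.Atom | None":
    best = None
    best_key = None
    for at in atoms:
        key = (at.occ, -ord(at.altloc or "A"))
        if best is None or key > best_key:
            best, best_key = at, key
    return best


def structure_to_chains(st, source: str = "") -> list[ChainModel]:
    """Convert a gemmi Structure (first model) to ChainModels."""
    st.setup_entities()
    model = st[0]

    # global context: ions and declared disulfides
    ions: list[tuple[str, int, tuple[float, float, float]]] = []
    for ch in model:
        for res in ch:
            atoms = list(res)
            if len(atoms) == 1 and atoms[0].element.is_metal:
                at = atoms[0]
                ions.append(
                    (at.element.name.upper(), res.seqid.num, (at.pos.x, at.pos.y, at.pos.z))
                )
    declared: dict[str, list[tuple[int, int]]] = {}
    for conn in st.connections:
        if conn.type == gemmi.ConnectionType.Disulf:
            c1, c2 = conn.partner1, conn.partner2
            if c1.chain_name == c2.chain_name:
                a, b = sorted((c1.res_id.seqid.num, c2.res_id.seqid.num))
                declared.setdefault(c1.chain_name, []).append((a, b))

    chains: list[ChainModel] = []
    for ch in model:
        residues: list[Residue] = []
        sg: dict[int, tuple[float, float, float]] = {}
        donors: list[tuple[int, str, tuple[float, float, float]]] = []
        raw: list[tuple] = []
        for res in ch:
            cas = [a for a in res if a.name == "CA" and a.element.name != "Ca"]
            if not cas:
                continue
            ca = _best_altloc(cas)
            raw.append((res, ca))
        if len(raw) < 2:
            if raw:
                warnings.warn(
                    f"chain {ch.name}: fewer than 2 Calpha atoms, skipped"
                )
            continue
        for k, (res, ca) in enumerate(raw):
            gap = False
            if k + 1 < len(raw):
                gap = raw[k + 1][0].seqid.num > res.seqid.num + 1
            residues.append(
                Residue(
                    chain_id=ch.name,
                    seq_index=res.seqid.num,
                    name=res.name,
                    ca_xyz=(ca.pos.x, ca.pos.y, ca.pos.z),
                    has_gap_after=gap,
                    icode=(res.seqid.icode or "").strip(),
                )
            )
            if res.name == "CYS":
                sgs = [a for a in res if a.name == "SG"]
                if sgs:
                    at = _best_altloc(sgs)
                    sg[res.seqid.num] = (at.pos.x, at.pos.y, at.pos.z)
            for at in res:
                if at.name in _BACKBONE_ATOMS:
                    continue
                if at.element.name in ("N", "O", "S"):
                    donors.append(
                        (res.seqid.num, at.element.name, (at.pos.x, at.pos.y, at.pos.z))
                    )
        chains.append(
            ChainModel(
                residues=residues,
                source_id=f"{source}_{ch.name}" if source else ch.name,
                sg_atoms=sg,
                sidechain_donors=donors,
                ions=ions,
                declared_ss=declared.get(ch.name, []),
            )
        )
    return chains


def _parse_xyz(path: Path) -> list[ChainModel]:
    residues: list[Residue] = []
    rows: list[tuple[int, float, float, float]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        parts = s.split()
        if len(parts) != 4:
            raise ParseError(
                f"{path.name}:{lineno}: expected 'index x y z', got {len(parts)} fields"
            )
        try:
            idx = int(parts[0])
            x, y, z = (float(v) for v in parts[1:])
        except ValueError as exc:
            raise ParseError(f"{path.name}:{lineno}: {exc}") from exc
        rows.append((idx, x, y, z))
    if len(rows) < 2:
        raise ParseError(f"{path.name}: xyz trace needs at least 2 points")
    for k, (idx, x, y, z) in enumerate(rows):
        gap = k + 1 < len(rows) and rows[k + 1][0] > idx + 1
        residues.append(
            Residue(chain_id="A", seq_index=idx, name="UNK", ca_xyz=(x, y, z), has_gap_after=gap)
        )
    return [ChainModel(residues=residues, source_id=path.stem)]


# --------------------------------------------------------------------------
# Backbone extraction
# --------------------------------------------------------------------------


def extract_backbone(chain: ChainModel) -> tuple[PolygonalCurve, list[int]]:
    """The Cα trace as an open curve, plus the residue-index map.

    Vertices follow sequence order; gaps contribute no extra vertices
    (their connecting segment is implicitly straight).  Returns
    ``(curve, residue_ids)`` with ``residue_ids[i]`` the author index of
    vertex ``i``.
    """
    if len(chain.residues) < 2:
        raise ParseError(f"chain {chain.source_id}: need >= 2 residues")
    seen: dict[tuple[int, str], int] = {}
    dups = []
    for r in chain.residues:
        key = (r.seq_index, r.icode)
        if key in seen:
            dups.append(r.label)
        seen[key] = r.seq_index
    if dups:
        raise ParseError(
            f"chain {chain.source_id}: duplicate residue indices: {sorted(set(dups))}"
        )
    ordered = sorted(chain.residues, key=lambda r: (r.seq_index, r.icode))
    pts = np.array([r.ca_xyz for r in ordered], dtype=float)
    return PolygonalCurve(pts, closed=False), [r.seq_index for r in ordered]


# --------------------------------------------------------------------------
# Bridge detection
# --------------------------------------------------------------------------


def detect_disulfide_bridges(
    chain: ChainModel, max_ss_dist: float = DEFAULT_SS_CUTOFF
) -> list[Bridge]:
    """Disulfide bridges: declared (SSBOND/struct_conn) plus geometric.

    Geometric pairs require SG–SG distance <= ``max_ss_dist``; each SG
    joins at most one bridge, with closest pairs claimed first.
    """
    chain_set = set(chain.seq_indices)
    bridges: dict[tuple[int, int], Bridge] = {}
    used: set[int] = set()
    for a, b in chain.declared_ss:
        if a in chain_set and b in chain_set and (a, b) not in bridges:
            bridges[(a, b)] = Bridge("disulfide", a, b)
            used.update((a, b))
    pairs = []
    keys = sorted(chain.sg_atoms)
    for i, a in enumerate(keys):
        for b in keys[i + 1:]:
            d = float(
                np.linalg.norm(np.subtract(chain.sg_atoms[a], chain.sg_atoms[b]))
            )
            if d <= max_ss_dist:
                pairs.append((d, a, b))
    for _, a, b in sorted(pairs):
        if a in used or b in used or (a, b) in bridges:
            continue
        bridges[(a, b)] = Bridge("disulfide", a, b)
        used.update((a, b))
    return sorted(bridges.values(), key=lambda br: (br.res_a, br.res_b))


def detect_ion_bridges(
    chain: ChainModel, coordination_dist: float = DEFAULT_ION_CUTOFF
) -> list[Bridge]:
    """Ion-mediated bridges: every pair of residues whose side-chain O/N/S
    atoms coordinate the same metal ion within ``coordination_dist``;
    sequence-adjacent pairs are excluded."""
    out: list[Bridge] = []
    for elem, ion_num, pos in chain.ions:
        coord: set[int] = set()
        p = np.asarray(pos)
        for seq, _el, xyz in chain.sidechain_donors:
            if float(np.linalg.norm(p - np.asarray(xyz))) <= coordination_dist:
                coord.add(seq)
        members = sorted(coord)
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                if b - a <= 1:
                    continue
                out.append(Bridge("ion", a, b, mediator=f"{elem}{ion_num}"))
    return sorted(out, key=lambda br: (br.res_a, br.res_b, br.mediator or ""))


def declare_bridges(
    chain: ChainModel, extra: list[tuple[int, int, str]]
) -> list[Bridge]:
    """User-declared bridges (amide bonds, side-chain concatenations...)."""
    chain_set = set(chain.seq_indices)
    out = []
    for a, b, kind in extra:
        if a not in chain_set or b not in chain_set:
            raise ValueError(f"declared bridge {a}-{b}: residue not in chain")
        out.append(Bridge(kind, a, b))
    return out
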