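import numpy as np
import pytest

from protknot.errors import ParseError
from protknot.fixtures import chain_from_points, straight_curve, write_fixture_pdb
from protknot.structure_io import (
    Bridge,
    ChainModel,
    Residue,
    declare_bridges,
    detect_disulfide_bridges,
    detect_ion_bridges,
    extract_backbone,
    parse_structure,
)


def _toy_pdb(tmp_path, name="toy.pdb", n=5, chains=("A",), cys=()):
    lines = []
    serial = 1
    for ci, cid in enumerate(chains):
        for i in range(1, n + 1):
            resname = "CYS" if (cid, i) in cys else "ALA"
            x, y, z = float(i * 3.8), float(ci * 20), 0.0
            lines.append(
                f"ATOM  {serial:5d}  CA  {resname} {cid}{i:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00 20.00           C"
            )
            serial += 1
    lines.append("END")
    p = tmp_path / name
    p.write_text("\n".join(lines) + "\n")
    return p


class TestParseStructure:
    def test_minimal_five_residue_pdb(self, tmp_path):
        chains = parse_structure(_toy_pdb(tmp_path))
        assert len(chains) == 1
        ch = chains[0]
        assert len(ch.residues) == 5
        assert ch.bridges == []
        assert [r.seq_index for r in ch.residues] == [1, 2, 3, 4, 5]

    def test_two_chains_give_two_models(self, tmp_path):
        chains = parse_structure(_toy_pdb(tmp_path, chains=("A", "B")))
        assert len(chains) == 2
        assert {c.source_id for c in chains} == {"toy_A", "toy_B"}

    def test_xyz_trace(self, tmp_path):
        p = tmp_path / "trace.xyz"
        p.write_text("\n".join(f"{i} {i}.0 0.0 0.0" for i in range(1, 11)) + "\n")
        (chain,) = parse_structure(p)
        assert len(chain.residues) == 10
        assert all(r.name == "UNK" for r in chain.residues)

    def test_xyz_bad_line_reports_position(self, tmp_path):
        p = tmp_path / "bad.xyz"
        p.write_text("1 0 0 0\n2 oops 0\n")
        with pytest.raises(ParseError, match="bad.xyz:2"):
            parse_structure(p)

    def test_missing_file(self, tmp_path):
        with pytest.raises(ParseError):
            parse_structure(tmp_path / "nope.pdb")

    def test_short_chain_skipped_with_warning(self, tmp_path):
        p = _toy_pdb(tmp_path, n=1)
        with pytest.warns(UserWarning):
            chains = parse_structure(p)
        assert chains == []

    def test_gap_flagged_but_no_extra_vertices(self, tmp_path):
        p = tmp_path / "gap.pdb"
        rows = []
        for serial, i in enumerate([8, 9, 10, 15, 16], start=1):
            rows.append(
                f"ATOM  {serial:5d}  CA  ALA A{i:4d}    "
                f"{i * 3.8:8.3f}{0.0:8.3f}{0.0:8.3f}  1.00 20.00           C"
            )
        p.write_text("\n".join(rows) + "\nEND\n")
        (chain,) = parse_structure(p)
        gaps = [r.seq_index for r in chain.residues if r.has_gap_after]
        assert gaps == [10]
        curve, ids = extract_backbone(chain)
        assert len(curve) == len(chain.residues) == 5
        assert ids == [8, 9, 10, 15, 16]


class TestExtractBackbone:
    def test_vertices_follow_sequence_order(self):
        pts = np.column_stack([np.arange(6) * 3.8, np.zeros(6), np.zeros(6)])
        chain = chain_from_points(pts)
        curve, ids = extract_backbone(chain)
        assert np.allclose(curve.vertices, pts)
        assert ids == [1, 2, 3, 4, 5, 6]

    def test_collinear_chain_projects_without_crossings(self):
        from protknot.geometry import project_to_diagram

        chain = chain_from_points(
            np.column_stack([np.arange(5) * 3.8, np.zeros(5), np.zeros(5)])
        )
        curve, _ = extract_backbone(chain)
        d = project_to_diagram(curve, np.array([0.3, 0.5, 0.81]))
        assert d.n_crossings == 0

    def test_duplicate_seq_index_rejected(self):
        residues = [
            Residue("A", 1, "ALA", (0, 0, 0)),
            Residue("A", 2, "ALA", (3.8, 0, 0)),
            Residue("A", 2, "ALA", (7.6, 0, 0)),
        ]
        chain = ChainModel(residues=residues, source_id="DUP_A")
        with pytest.raises(ParseError, match="duplicate"):
            extract_backbone(chain)


class TestDisulfideDetection:
    def test_declared_ssbond_found(self, tmp_path):
        chain = chain_from_points(
            straight_curve(n=25).vertices, cys_pairs=[(4, 21)]
        )
        bridges = detect_disulfide_bridges(chain)
        assert bridges == [Bridge("disulfide", 4, 21)]

    def test_distant_sg_pair_not_bridged(self):
        chain = chain_from_points(straight_curve(n=10).vertices)
        chain.sg_atoms = {2: (0.0, 0.0, 0.0), 8: (5.0, 0.0, 0.0)}
        assert detect_disulfide_bridges(chain) == []

    def test_sg_cluster_resolves_to_closest_pair(self):
        # three SG atoms pairwise within 2.05 A: exactly one bridge, the
        # closest pair (enumerating the three pairings by hand)
        chain = chain_from_points(straight_curve(n=12).vertices)
        chain.sg_atoms = {
            2: (0.0, 0.0, 0.0),
            6: (1.9, 0.0, 0.0),
            10: (0.95, 1.75, 0.0),
        }
        bridges = detect_disulfide_bridges(chain)
        assert bridges == [Bridge("disulfide", 2, 6)]

    def test_geometric_pair_within_cutoff(self):
        chain = chain_from_points(straight_curve(n=10).vertices)
        chain.sg_atoms = {3: (0.0, 0.0, 0.0), 7: (2.0, 0.0, 0.0)}
        assert detect_disulfide_bridges(chain) == [Bridge("disulfide", 3, 7)]


class TestIonDetection:
    def _chain_with_ion(self, coordinating):
        chain = chain_from_points(straight_curve(n=45).vertices)
        chain.ions = [("ZN", 900, (0.0, 50.0, 0.0))]
        chain.sidechain_donors = [
            (seq, "N", (0.0, 50.0 + 0.1 * k, 2.0)) for k, seq in enumerate(coordinating)
        ]
        return chain

    def test_two_coordinating_residues_one_bridge(self):
        bridges = detect_ion_bridges(self._chain_with_ion([10, 40]))
        assert bridges == [Bridge("ion", 10, 40, mediator="ZN900")]

    def test_three_coordinating_residues_three_bridges(self):
        bridges = detect_ion_bridges(self._chain_with_ion([10, 25, 40]))
        assert len(bridges) == 3  # C(3,2) by enumeration
        assert {(b.res_a, b.res_b) for b in bridges} == {(10, 25), (10, 40), (25, 40)}

    def test_far_ion_bridges_nothing(self):
        chain = chain_from_points(straight_curve(n=20).vertices)
        chain.ions = [("ZN", 900, (500.0, 500.0, 500.0))]
        chain.sidechain_donors = [(5, "N", (0.0, 0.0, 2.0))]
        assert detect_ion_bridges(chain) == []

    def test_sequence_adjacent_pairs_excluded(self):
        bridges = detect_ion_bridges(self._chain_with_ion([10, 11, 40]))
        assert {(b.res_a, b.res_b) for b in bridges} == {(10, 40), (11, 40)}


class TestRoundTrip:
    def test_pdb_write_parse_idempotent_on_residues_and_bridges(self, tmp_path):
        chain = chain_from_points(
            straight_curve(n=25).vertices, cys_pairs=[(4, 21), (7, 15)]
        )
        p = tmp_path / "rt.pdb"
        write_fixture_pdb(chain, p)
        (back,) = parse_structure(p)
        assert [r.seq_index for r in back.residues] == [r.seq_index for r in chain.residues]
        assert [r.name for r in back.residues] == [r.name for r in chain.residues]
        curve_a, _ = extract_backbone(chain)
        curve_b, _ = extract_backbone(back)
        assert np.allclose(curve_a.vertices, curve_b.vertices, atol=1e-3)
        assert detect_disulfide_bridges(back) == detect_disulfide_bridges(chain)


class TestBridgeInvariants:
    def test_canonical_order(self):
        b = Bridge("disulfide", 30, 4)
        assert (b.res_a, b.res_b) == (4, 30)

    def test_self_bridge_rejected(self):
        with pytest.raises(ValueError):
            Bridge("disulfide", 5, 5)

    def test_ion_requires_mediator(self):
        with pytest.raises(ValueError):
            Bridge("ion", 3, 9)

    def test_declared_bridges_validated(self):
        chain = chain_from_points(straight_curve(n=10).vertices)
        assert declare_bridges(chain, [(2, 9, "amide")]) == [Bridge("amide", 2, 9)]
        with pytest.raises(ValueError):
            declare_bridges(chain, [(2, 99, "amide")])
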