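import numpy as np
import pytest

from protknot.covalent_loops import (
    CovalentLoop,
    bridged_open_paths,
    build_loop,
    enumerate_covalent_loops,
    format_loop_notation,
    loop_knot_type,
    parse_loop_notation,
    _segment_graph,
)
from protknot.errors import ParseError
from protknot.fixtures import (
    bridged_loop_chain,
    chain_from_points,
    straight_curve,
)
from protknot.geometry import project_to_diagram, sphere_directions
from protknot.knot_invariants import classify_knot
from protknot.structure_io import Bridge

from oracles import brute_cycles


def _chain_with_bridges(n, pairs):
    rng = np.random.default_rng(1)
    pts = straight_curve(n=n).vertices + rng.normal(scale=0.4, size=(n, 3))
    return chain_from_points(pts, cys_pairs=pairs)


class TestEnumeration:
    def test_no_bridges_no_loops(self):
        chain = chain_from_points(straight_curve(n=10).vertices)
        assert enumerate_covalent_loops(chain) == []

    def test_single_bridge_single_loop(self):
        chain = _chain_with_bridges(50, [(10, 40)])
        loops = enumerate_covalent_loops(chain)
        assert len(loops) == 1
        assert loops[0].notation == "10-c-40"
        assert loops[0].n_bridges == 1
        assert loops[0].curve.closed

    def test_two_bridge_loop_notation_matches_reference_string(self):
        chain = _chain_with_bridges(30, [(4, 21), (11, 23)])
        loops = enumerate_covalent_loops(chain, max_bridges=2)
        notations = {lp.notation for lp in loops}
        assert "4-c-11-b-23-c-21" in notations

    @pytest.mark.parametrize(
        "pairs",
        [
            [(5, 20), (10, 30), (25, 40)],  # interleaved
            [(5, 40), (10, 30), (15, 20)],  # nested
            [(5, 15), (20, 30), (35, 45)],  # disjoint
            [(5, 25), (10, 40), (20, 45), (30, 48)],  # four bridges
        ],
    )
    def test_loop_count_matches_exhaustive_cycle_search(self, pairs):
        chain = _chain_with_bridges(50, pairs)
        for max_b in (1, 2, 3, 4):
            loops = enumerate_covalent_loops(chain, max_bridges=max_b)
            nodes, edges = _segment_graph(chain, include_termini=False)
            expected = brute_cycles(nodes, edges, max_b)
            assert len(loops) == len(expected)

    def test_open_ends_never_used_for_closure(self):
        # the two free termini are not connectable: two disjoint bridges
        # yield exactly their two single-bridge loops, nothing closed
        # "around the ends"
        chain = _chain_with_bridges(50, [(5, 15), (30, 45)])
        loops = enumerate_covalent_loops(chain, max_bridges=2)
        assert {lp.notation for lp in loops} == {"5-c-15", "30-c-45"}


class TestLoopKnotType:
    def test_planar_loop_is_unknot(self):
        chain = _chain_with_bridges(30, [(5, 25)])
        (loop,) = enumerate_covalent_loops(chain)
        assert loop_knot_type(loop).knot_type.name == "0_1"

    def test_threaded_loop_is_trefoil_with_unknotted_backbone(self):
        # a backbone that is trivial as an open chain but whose covalent
        # loop closes to a trefoil
        chain = bridged_loop_chain()
        from protknot.probabilistic import dominant_type, knot_spectrum
        from protknot.structure_io import extract_backbone

        curve, _ = extract_backbone(chain)
        t, p = dominant_type(knot_spectrum(curve, n=50))
        assert t.name == "0_1" and p > 0.5
        (loop,) = enumerate_covalent_loops(chain)
        assert loop_knot_type(loop).knot_type.base == "3_1"

    def test_mirrored_loop_has_opposite_chirality(self):
        chain = bridged_loop_chain()
        (loop,) = enumerate_covalent_loops(chain)
        t = loop_knot_type(loop).knot_type
        mirrored = CovalentLoop(
            elements=loop.elements, curve=loop.curve.mirrored(), notation=loop.notation
        )
        tm = loop_knot_type(mirrored).knot_type
        assert {t.name, tm.name} == {"3_1+", "3_1-"}

    def test_knot_type_stable_across_projections(self):
        chain = bridged_loop_chain()
        (loop,) = enumerate_covalent_loops(chain)
        from protknot.geometry import kmt_reduce

        red = kmt_reduce(loop.curve)
        names = set()
        for d in sphere_directions(50, seed=4):
            names.add(classify_knot(project_to_diagram(red, d)).name)
        assert names == {"3_1+"} or names == {"3_1-"}


class TestBridgedOpenPaths:
    def test_no_bridges_gives_backbone_only(self):
        chain = chain_from_points(straight_curve(n=10).vertices)
        paths = bridged_open_paths(chain)
        assert len(paths) == 1
        assert paths[0].notation == "1-c-10"
        assert paths[0].n_bridges == 0

    def test_single_bridge_gives_two_paths(self):
        chain = _chain_with_bridges(50, [(10, 40)])
        paths = bridged_open_paths(chain)
        assert len(paths) == 2
        assert {p.n_bridges for p in paths} == {0, 1}

    @pytest.mark.parametrize(
        "pairs,max_b",
        [([(5, 20), (10, 30), (25, 40)], 2), ([(5, 20), (10, 30), (25, 40)], 3)],
    )
    def test_path_count_matches_exhaustive_search(self, pairs, max_b):
        chain = _chain_with_bridges(50, pairs)
        paths = bridged_open_paths(chain, max_bridges=max_b)

        # brute force: DFS over the same graph, counting N->C walks
        nodes, edges = _segment_graph(chain, include_termini=True)
        adjacency = {n: [] for n in nodes}
        for ei, (kind, a, b) in enumerate(edges):
            adjacency[a].append((ei, kind, b))
            adjacency[b].append((ei, kind, a))
        count = 0

        def walk(node, visited, nb):
            nonlocal count
            if node == 50:
                count += 1
                return
            for ei, kind, nxt in adjacency[node]:
                if nxt in visited:
                    continue
                nb2 = nb + (kind == "bridge")
                if nb2 <= max_b:
                    walk(nxt, visited | {nxt}, nb2)

        walk(1, {1}, 0)
        assert len(paths) == count


class TestNotation:
    def test_reference_loop_string_round_trips(self):
        chain = _chain_with_bridges(30, [(4, 21), (11, 23)])
        loop = parse_loop_notation("4-c-11-b-23-c-21", chain)
        assert isinstance(loop, CovalentLoop)
        assert format_loop_notation(loop) == "4-c-11-b-23-c-21"
        assert loop.n_bridges == 2

    def test_single_bridge_string_is_a_bridge(self):
        assert parse_loop_notation("17-b-29") == Bridge("disulfide", 17, 29)

    def test_round_trip_on_enumerated_loops(self):
        chain = _chain_with_bridges(50, [(5, 25), (10, 40), (20, 45)])
        for loop in enumerate_covalent_loops(chain, max_bridges=3):
            again = parse_loop_notation(loop.notation, chain)
            assert again == loop

    @pytest.mark.parametrize("bad", ["", "4-c", "4-x-9", "4-c-spam", "4--9"])
    def test_malformed_notation_rejected(self, bad):
        with pytest.raises(ParseError):
            parse_loop_notation(bad)
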