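import numpy as np
import pytest

from protknot.cysteine_knots import (
    classify_ck_class,
    detect_cysteine_knots,
    piercing_number,
    verify_ck_loops_unknotted,
)
from protknot.errors import GeometryError
from protknot.fixtures import (
    bridged_loop_chain,
    chain_from_points,
    ck_motif_chain,
    straight_curve,
)
from protknot.geometry import PolygonalCurve

from oracles import brute_piercing


def _circle_loop(r=5.0, n=24):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return PolygonalCurve(
        np.column_stack([r * np.cos(th), np.zeros(n), r * np.sin(th)]), closed=True
    )


class TestPiercingNumber:
    def test_far_segment_misses_planar_loop(self):
        loop = _circle_loop()
        assert piercing_number(loop, (np.array([20.0, -3, 0]), np.array([20.0, 3, 0]))) == 0

    def test_segment_through_centre_pierces_once(self):
        loop = _circle_loop()
        pn = piercing_number(loop, (np.array([0.0, -3, 0]), np.array([0.0, 3, 0])))
        assert abs(pn) == 1

    def test_sign_flips_with_segment_direction(self):
        loop = _circle_loop()
        a, b = np.array([0.0, -3, 0]), np.array([0.0, 3, 0])
        assert piercing_number(loop, (a, b)) == -piercing_number(loop, (b, a))

    def test_double_pass_cancels(self):
        # a segment entering and exiting through the same side of a folded
        # loop: U-shaped path across the disc plane twice -> net 0 is not
        # constructible with one segment, but a segment grazing outside is
        loop = _circle_loop()
        pn = piercing_number(loop, (np.array([6.0, -3, 0]), np.array([6.0, 3, 0])))
        assert pn == 0

    def test_matches_brute_force_on_random_configurations(self):
        rng = np.random.default_rng(17)
        compared = 0
        pierced = 0
        while compared < 200:
            n = int(rng.integers(6, 14))
            th = np.linspace(0, 2 * np.pi, n, endpoint=False)
            ring = np.column_stack(
                [5 * np.cos(th), np.zeros(n), 5 * np.sin(th)]
            ) + rng.normal(scale=0.8, size=(n, 3))
            loop = PolygonalCurve(ring, closed=True)
            p = rng.normal(scale=4.0, size=3)
            q = rng.normal(scale=4.0, size=3)
            oracle = brute_piercing(loop.vertices, loop.vertices.mean(axis=0), p, q)
            if oracle is None:
                continue  # grazing configuration: ambiguous for both
            try:
                pn = piercing_number(loop, (p, q))
            except GeometryError:
                continue
            assert pn == oracle
            compared += 1
            pierced += oracle != 0
        assert pierced > 20  # the sample genuinely exercises piercings

    def test_invariant_under_apex_jitter(self):
        loop = _circle_loop()
        seg = (np.array([0.5, -4, 0.3]), np.array([-0.2, 3.5, -0.1]))
        base = piercing_number(loop, seg)
        # re-run with perturbed copies of the loop: topological, not metric
        rng = np.random.default_rng(3)
        for _ in range(20):
            wobble = PolygonalCurve(
                loop.vertices + rng.normal(scale=0.05, size=loop.vertices.shape),
                closed=True,
            )
            assert piercing_number(wobble, seg) == base

    def test_open_loop_rejected(self):
        with pytest.raises(GeometryError):
            piercing_number(PolygonalCurve(np.random.default_rng(0).normal(size=(5, 3))),
                            (np.zeros(3), np.ones(3)))


class TestDetection:
    def test_growth_factor_fixture_detects_exactly_one_motif(self):
        chain = ck_motif_chain("growth_factor")
        motifs = detect_cysteine_knots(chain)
        assert len(motifs) == 1
        m = motifs[0]
        assert m.loop_notation == "4-c-9-b-24-c-19"
        assert m.piercing_notation == "14-b-29"
        assert m.ck_class == "growth_factor"
        assert not m.multiple_piercing

    def test_coplanar_non_interlocking_bridges_no_motif(self):
        # three disulfides along a straight chain: nothing pierces anything
        chain = chain_from_points(
            straight_curve(n=40).vertices, cys_pairs=[(4, 12), (16, 24), (28, 36)]
        )
        assert detect_cysteine_knots(chain) == []

    def test_detection_agrees_with_piercing_oracle_on_random_triples(self):
        # random 3-bridge chains: a motif is reported iff the brute-force
        # segment-triangle count of some loop/piercer split is odd
        from dataclasses import replace

        from protknot.covalent_loops import enumerate_covalent_loops

        rng = np.random.default_rng(23)
        checked = 0
        with_motif = 0
        while checked < 60:
            pts = rng.normal(size=(30, 3)) * 6.0
            cys = sorted(rng.choice(np.arange(1, 31), size=6, replace=False).tolist())
            order = rng.permutation(6)
            pairs = [
                tuple(sorted((cys[order[0]], cys[order[1]]))),
                tuple(sorted((cys[order[2]], cys[order[3]]))),
                tuple(sorted((cys[order[4]], cys[order[5]]))),
            ]
            chain = chain_from_points(pts, cys_pairs=pairs)
            if len(chain.bridges) != 3:
                continue
            ca = {r.seq_index: np.asarray(r.ca_xyz) for r in chain.residues}
            expected = set()
            ambiguous = False
            for p_idx in range(3):
                piercer = chain.bridges[p_idx]
                loopers = [b for q, b in enumerate(chain.bridges) if q != p_idx]
                tmp = replace(chain, bridges=loopers)
                loops = [
                    lp for lp in enumerate_covalent_loops(tmp, max_bridges=2)
                    if lp.n_bridges == 2
                ]
                if not loops:
                    continue
                apex = loops[0].curve.vertices.mean(axis=0)
                pn = brute_piercing(
                    loops[0].curve.vertices, apex, ca[piercer.res_a], ca[piercer.res_b]
                )
                if pn is None:
                    ambiguous = True
                    break
                if pn % 2 == 1:
                    expected.add((piercer.res_a, piercer.res_b))
            if ambiguous:
                continue
            motifs = detect_cysteine_knots(chain, classify=False)
            got = {(m.piercing_bridge.res_a, m.piercing_bridge.res_b) for m in motifs}
            assert got == expected
            checked += 1
            with_motif += bool(expected)
        assert with_motif >= 5

    def test_symmetric_under_loop_bridge_relabeling(self):
        chain = ck_motif_chain("growth_factor")
        (m,) = detect_cysteine_knots(chain)
        a, b = m.loop_bridges
        assert {(a.res_a, a.res_b), (b.res_a, b.res_b)} == {(4, 19), (9, 24)}

    def test_size_independence_with_wide_span_motif(self):
        chain = ck_motif_chain("growth_factor", expand=17)
        span = max(r.seq_index for r in chain.residues)
        assert span >= 500
        motifs = detect_cysteine_knots(chain)
        assert len(motifs) == 1
        assert motifs[0].ck_class == "growth_factor"


class TestClassification:
    @pytest.mark.parametrize(
        "ck_class", ["growth_factor", "inhibitor", "cyclic"]
    )
    def test_fixture_classes(self, ck_class):
        chain = ck_motif_chain(ck_class)
        (m,) = detect_cysteine_knots(chain)
        assert m.ck_class == ck_class

    def test_cyclized_chain_distance(self):
        chain = ck_motif_chain("cyclic")
        first = np.asarray(chain.residues[0].ca_xyz)
        last = np.asarray(chain.residues[-1].ca_xyz)
        assert np.linalg.norm(first - last) <= 5.0

    def test_unmatched_permutation_is_other(self):
        chain = ck_motif_chain("growth_factor")
        (m,) = detect_cysteine_knots(chain)
        # relabel the motif's bridges into a non-canonical permutation
        from protknot.cysteine_knots import CysteineKnotMotif
        from protknot.structure_io import Bridge

        fake = CysteineKnotMotif(
            loop_bridges=(Bridge("disulfide", 4, 14), Bridge("disulfide", 9, 24)),
            piercing_bridge=Bridge("disulfide", 19, 29),
            loop=m.loop,
            loop_notation=m.loop_notation,
            piercing_notation=m.piercing_notation,
            piercing_sign=1,
        )
        assert classify_ck_class(fake, chain) == "other"


class TestLoopUnknottedness:
    @pytest.mark.parametrize("ck_class", ["growth_factor", "inhibitor", "cyclic"])
    def test_true_motifs_have_only_unknotted_cycles(self, ck_class):
        chain = ck_motif_chain(ck_class)
        (m,) = detect_cysteine_knots(chain)
        assert verify_ck_loops_unknotted(m, chain) == []

    def test_deterministic_trefoil_loop_is_flagged(self):
        # a structure whose covalent loop is a genuine trefoil: the report
        # must flag the knotted cycle
        from protknot.cysteine_knots import CysteineKnotMotif

        chain = bridged_loop_chain()
        (bridge,) = chain.bridges
        motif = CysteineKnotMotif(
            loop_bridges=(bridge, bridge),
            piercing_bridge=bridge,
            loop=None,
            loop_notation="",
            piercing_notation="",
            piercing_sign=1,
        )
        bad = verify_ck_loops_unknotted(motif, chain)
        assert any(t.startswith("3_1") for _, t in bad)
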