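import numpy as np
import pytest

from protknot.errors import GeometryError
from protknot.geometry import (
    PolygonalCurve,
    close_curve,
    closure_sphere,
    kmt_reduce,
    project_to_diagram,
    sphere_directions,
)
from protknot.knot_invariants import alexander_determinant
from protknot.fixtures import torus_knot_curve

from conftest import GENERIC, Z
from oracles import brute_crossing_count


class TestPolygonalCurve:
    def test_closed_curve_drops_duplicated_endpoint(self):
        th = np.linspace(0, 2 * np.pi, 11)
        pts = np.column_stack([np.cos(th), np.sin(th), np.zeros_like(th)])
        c = PolygonalCurve(pts, closed=True)
        assert len(c) == 10

    def test_too_few_vertices_rejected(self):
        with pytest.raises(GeometryError):
            PolygonalCurve(np.zeros((1, 3)))
        with pytest.raises(GeometryError):
            PolygonalCurve(np.random.default_rng(0).normal(size=(2, 3)), closed=True)

    def test_mirror_is_point_reflection(self):
        c = PolygonalCurve(np.arange(12.0).reshape(4, 3))
        assert np.allclose(c.mirrored().vertices, -c.vertices)


class TestKMT:
    def test_planar_convex_closed_polygon_collapses_to_triangle(self):
        th = np.linspace(0, 2 * np.pi, 10, endpoint=False)
        c = PolygonalCurve(np.column_stack([np.cos(th), np.sin(th), np.zeros(10)]), closed=True)
        assert len(kmt_reduce(c)) == 3

    def test_straight_open_chain_collapses_to_segment(self):
        c = PolygonalCurve(
            np.column_stack([np.linspace(0, 49, 50), np.zeros(50), np.zeros(50)])
        )
        assert len(kmt_reduce(c, preserve_endpoints=True)) == 2

    def test_idempotent(self, trefoil_curve):
        once = kmt_reduce(trefoil_curve)
        twice = kmt_reduce(once)
        assert np.array_equal(once.vertices, twice.vertices)

    def test_preserves_determinant_on_noisy_trefoils(self):
        # topology safety: the Alexander determinant of each closed noisy
        # torus-knot polygon is unchanged by the reduction
        rng = np.random.default_rng(42)
        for trial in range(100):
            c = torus_knot_curve(2, 3, n=80, noise=0.5, seed=int(rng.integers(1 << 30)))
            red = kmt_reduce(c)
            assert len(red) <= len(c)
            d0 = alexander_determinant(project_to_diagram(c, GENERIC))
            d1 = alexander_determinant(project_to_diagram(red, GENERIC))
            assert d0 == d1 == 3

    def test_endpoints_kept_for_open_curves(self, open_trefoil):
        red = kmt_reduce(open_trefoil, preserve_endpoints=True)
        assert np.allclose(red.vertices[0], open_trefoil.vertices[0])
        assert np.allclose(red.vertices[-1], open_trefoil.vertices[-1])


class TestSphereDirections:
    def test_single_direction_is_unit(self):
        d = sphere_directions(1)
        assert d.shape == (1, 3)
        assert np.isclose(np.linalg.norm(d[0]), 1.0)

    def test_fibonacci_deterministic_and_distinct(self):
        a = sphere_directions(100)
        b = sphere_directions(100)
        assert np.array_equal(a, b)
        gram = a @ a.T
        np.fill_diagonal(gram, -1)
        assert gram.max() < 1 - 1e-8  # pairwise distinct

    def test_fibonacci_quasi_uniform_nearest_neighbour_spread(self):
        # nearest-neighbour angular gaps should be tight around the mean
        d = sphere_directions(100)
        gram = np.clip(d @ d.T, -1, 1)
        np.fill_diagonal(gram, -1)
        nn = np.arccos(gram.max(axis=1))
        assert nn.max() <= 2.0 * nn.mean()

    def test_random_mode_mean_converges(self):
        d = sphere_directions(1000, seed=7)
        assert np.linalg.norm(d.mean(axis=0)) < 0.1

    def test_invalid_count(self):
        with pytest.raises(GeometryError):
            sphere_directions(0)


class TestProjection:
    def test_planar_circle_has_no_crossings(self):
        th = np.linspace(0, 2 * np.pi, 24, endpoint=False)
        c = PolygonalCurve(np.column_stack([np.cos(th), np.sin(th), np.zeros(24)]), closed=True)
        d = project_to_diagram(c, Z)
        assert d.n_crossings == 0 and d.n_endpoints == 0

    def test_trefoil_three_crossings_same_sign(self):
        c = torus_knot_curve(2, 3, n=90)
        red = c  # project the raw polygon along its symmetry axis
        d = project_to_diagram(red, Z)
        assert d.n_crossings == 3
        signs = {s for _, _, s in d.code}
        assert len(signs) == 1
        assert d.n_crossings == brute_crossing_count(red.vertices, Z, closed=True)

    def test_crossing_count_matches_brute_force_on_random_curves(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            pts = rng.normal(size=(12, 3)) * [3, 3, 1]
            c = PolygonalCurve(pts)
            d = project_to_diagram(c, Z)
            assert d.n_crossings == brute_crossing_count(pts, Z, closed=False)

    def test_open_curve_diagram_has_two_endpoints(self, open_trefoil):
        d = project_to_diagram(open_trefoil, GENERIC)
        assert d.n_endpoints == 2

    def test_every_crossing_visited_exactly_twice(self, trefoil_diagram):
        seen: dict[int, list[bool]] = {}
        for cid, over, _ in trefoil_diagram.code:
            seen.setdefault(cid, []).append(over)
        for overs in seen.values():
            assert sorted(overs) == [False, True]

    def test_mirror_consistency_with_point_reflection(self, trefoil_curve):
        # projecting the point-reflected curve flips every crossing
        d = project_to_diagram(trefoil_curve, GENERIC)
        dm = project_to_diagram(trefoil_curve.mirrored(), GENERIC)
        assert len(d.code) == len(dm.code)
        assert [(c, o, s) for c, o, s in d.code] == [
            (c, not o, -s) for c, o, s in dm.code
        ]
        mm = d.mirror().mirror()
        assert mm.code == d.code

    def test_zero_direction_rejected(self, trefoil_curve):
        with pytest.raises(GeometryError):
            project_to_diagram(trefoil_curve, np.zeros(3))


class TestClosure:
    def test_straight_segment_closes_to_unknot_triangle(self):
        c = PolygonalCurve(np.array([[0.0, 0, 0], [10.0, 0, 0]]))
        centre, radius = closure_sphere(c)
        closed = close_curve(c, centre + radius * np.array([0, 0, 1.0]))
        assert closed.closed and len(closed) == 3
        assert alexander_determinant(project_to_diagram(closed, GENERIC)) == 1

    def test_open_trefoil_closes_to_determinant_three_for_most_points(self, open_trefoil):
        centre, radius = closure_sphere(open_trefoil)
        from protknot.geometry import kmt_reduce, sphere_directions

        hits = 0
        dirs = sphere_directions(100)
        for d in dirs:
            closed = close_curve(open_trefoil, centre + radius * d)
            det = alexander_determinant(project_to_diagram(kmt_reduce(closed), GENERIC))
            hits += det == 3
        assert hits > 50

    def test_antipodal_closure_points_both_valid(self, open_trefoil):
        centre, radius = closure_sphere(open_trefoil)
        for sgn in (1, -1):
            closed = close_curve(open_trefoil, centre + sgn * radius * np.array([0, 0, 1.0]))
            assert closed.closed

    def test_interior_closure_point_rejected(self, open_trefoil):
        with pytest.raises(GeometryError):
            close_curve(open_trefoil, open_trefoil.centroid)

    def test_closing_a_closed_curve_rejected(self, trefoil_curve):
        with pytest.raises(GeometryError):
            close_curve(trefoil_curve, np.array([1e4, 0, 0]))
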