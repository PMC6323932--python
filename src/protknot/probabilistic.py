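"""Probabilistic topology of open chains.

An open backbone has no well-defined knot type: it acquires one only
after its endpoints are connected.  Closure is performed through single
points sampled on a large sphere surrounding the structure (radius 100x
the chain extent), and the *knot spectrum* records the fraction of
closure points producing each knot type.  Knotoids need no closure but
depend on the projection direction instead, so the analogous object is
the distribution of knotoid types over a quasi-uniform set of projection
directions (100 by default).  In both cases the highest-probability type
is the *dominant* type and represents the chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError
from .geometry import (
    PolygonalCurve,
    close_curve,
    closure_sphere,
    kmt_reduce,
    project_to_diagram,
    sphere_directions,
)
from .knot_invariants import UNKNOWN, KnotType, classify_knot
from .knotoid_invariants import UNKNOWN_KNOTOID, KnotoidType, classify_knotoid

__all__ = [
    "KnotSpectrum",
    "KnotoidDistribution",
    "ProjectionGlobe",
    "knot_spectrum",
    "knotoid_distribution",
    "dominant_type",
    "projection_globe",
]


def _normalize_tally(tally: dict) -> dict:
    total = sum(tally.values())
    return {k: v / total for k, v in tally.items()}


@dataclass
class KnotSpectrum:
    """Probability over knot types from stochastic closure."""

    probabilities: dict[KnotType, float]
    n_closures: int
    descriptor: str = "fibonacci"

    def probability(self, ktype: KnotType) -> float:
        return self.probabilities.get(ktype, 0.0)


@dataclass
class KnotoidDistribution:
    """Probability over knotoid types across projection directions."""

    probabilities: dict[KnotoidType, float]
    n_directions: int
    descriptor: str = "fibonacci"

    def probability(self, ktype: KnotoidType) -> float:
        return self.probabilities.get(ktype, 0.0)


@dataclass
class ProjectionGlobe:
    """Per-direction knotoid classification of a full chain."""

    directions: np.ndarray = field(repr=False)
    types: list[KnotoidType] = field(repr=False)

    def distribution(self) -> KnotoidDistribution:
        tally: dict[KnotoidType, int] = {}
        for t in self.types:
            tally[t] = tally.get(t, 0) + 1
        return KnotoidDistribution(_normalize_tally(tally), len(self.types))

    def to_rows(self) -> list[tuple[float, float, str]]:
        """(theta, phi, type-name) rows — theta polar, phi azimuthal, radians."""
        rows = []
        for d, t in zip(self.directions, self.types):
            theta = float(np.arccos(np.clip(d[2], -1.0, 1.0)))
            phi = float(np.arctan2(d[1], d[0]))
            rows.append((theta, phi, t.name))
        return rows


_GENERIC_DIR = np.array([0.173, 0.292, 0.941])  # arbitrary generic projection


def knot_spectrum(
    curve: PolygonalCurve,
    n: int = 100,
    seed: int | None = None,
    closure_factor: float = 100.0,
    homfly_limit: int = 30,
) -> KnotSpectrum:
    """Knot-type probabilities of an open curve over ``n`` stochastic closures.

    Each closure point on the surrounding sphere yields one closed curve,
    which is KMT-reduced, projected along a generic direction, and
    classified; tallies are normalized to probabilities.  Classification
    failures are counted under ``unknown``.
    """
    if curve.closed:
        raise GeometryError("knot_spectrum expects an open curve")
    if n < 1:
        raise GeometryError("need n >= 1 closures")
    centre, radius = closure_sphere(curve, factor=closure_factor)
    dirs = sphere_directions(n, seed)
    tally: dict[KnotType, int] = {}
    for d in dirs:
        try:
            closed = close_curve(curve, centre + radius * d)
            red = kmt_reduce(closed)
            diag = project_to_diagram(red, _GENERIC_DIR)
            ktype = classify_knot(diag, homfly_limit=homfly_limit)
        except Exception:
            ktype = UNKNOWN
        tally[ktype] = tally.get(ktype, 0) + 1
    desc = "fibonacci" if seed is None else f"random(seed={seed})"
    return KnotSpectrum(_normalize_tally(tally), n, desc)


def knotoid_distribution(
    curve: PolygonalCurve,
    n_directions: int = 100,
    seed: int | None = None,
) -> KnotoidDistribution:
    """Knotoid-type probabilities over projection directions.

    Per direction the chain is KMT-reduced with the endpoint pillars for
    that direction kept clear (an endpoint-avoiding reduction), projected,
    and classified via the loop bracket.
    """
    if curve.closed:
        raise GeometryError("knotoid_distribution expects an open curve")
    if n_directions < 1:
        raise GeometryError("need n_directions >= 1")
    globe = projection_globe(curve, resolution=n_directions, seed=seed)
    dist = globe.distribution()
    dist.descriptor = "fibonacci" if seed is None else f"random(seed={seed})"
    return dist


def projection_globe(
    curve: PolygonalCurve,
    resolution: int = 100,
    seed: int | None = None,
) -> ProjectionGlobe:
    """Classify the knotoid type of a chain along every sampled direction."""
    if curve.closed:
        raise GeometryError("projection_globe expects an open curve")
    dirs = sphere_directions(resolution, seed)
    types: list[KnotoidType] = []
    for d in dirs:
        try:
            red = kmt_reduce(curve, preserve_endpoints=True, direction=d)
            diag = project_to_diagram(red, d)
            types.append(classify_knotoid(diag))
        except Exception:
            types.append(UNKNOWN_KNOTOID)
    return ProjectionGlobe(dirs, types)


def dominant_type(spectrum: KnotSpectrum | KnotoidDistribution):
    """Highest-probability type; ties break toward the trivial type, then
    lexicographically.  Returns ``(type, probability)``."""
    probs = spectrum.probabilities
    if not probs:
        raise ValueError("empty spectrum")
    best = max(
        probs.items(),
        key=lambda kv: (kv[1], kv[0].is_trivial, _revlex(kv[0].name)),
    )
    return best[0], best[1]


class _revlex(str):
    """Orders reversed so that max() picks the lexicographically smallest."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)
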