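import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from protknot.fixtures import (
    open_trefoil_curve,
    slipknot_curve,
    straight_curve,
    torus_knot_curve,
)
from protknot.geometry import kmt_reduce, project_to_diagram

Z = np.array([0.0, 0.0, 1.0])
GENERIC = np.array([0.21, 0.13, 0.95])


@pytest.fixture(scope="session")
def trefoil_curve():
    return torus_knot_curve(2, 3, n=120)


@pytest.fixture(scope="session")
def trefoil_diagram(trefoil_curve):
    return project_to_diagram(kmt_reduce(trefoil_curve), GENERIC)


@pytest.fixture(scope="session")
def figure_eight_curve():
    t = np.linspace(0, 2 * np.pi, 200, endpoint=False)
    pts = np.column_stack(
        [
            (8 + 4 * np.cos(2 * t)) * np.cos(3 * t),
            (8 + 4 * np.cos(2 * t)) * np.sin(3 * t),
            4 * np.sin(4 * t),
        ]
    )
    from protknot.geometry import PolygonalCurve

    return PolygonalCurve(pts, closed=True)


@pytest.fixture(scope="session")
def figure_eight_diagram(figure_eight_curve):
    return project_to_diagram(kmt_reduce(figure_eight_curve), GENERIC)


@pytest.fixture(scope="session")
def open_trefoil():
    return open_trefoil_curve(n=60)


@pytest.fixture(scope="session")
def slipknot():
    return slipknot_curve()


@pytest.fixture(scope="session")
def straight():
    return straight_curve(n=10)
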