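import numpy as np
import pytest

from taaspread.geometry import TriSurface, compute_vertex_geometry
from taaspread.synthetic import make_flat_sheet, Scenario


@pytest.fixture(scope="session")
def small_sheet():
    """20x20 mm flat sheet at 1 mm edge target."""
    return make_flat_sheet((20.0, 20.0), 1.0)


@pytest.fixture(scope="session")
def coarse_sheet():
    """60x60 mm flat sheet at 2 mm edge target (fast partition tests)."""
    return make_flat_sheet((60.0, 60.0), 2.0)


@pytest.fixture(scope="session")
def default_scenario():
    return Scenario()


@pytest.fixture
def unit_square():
    """Unit square split into two triangles along the (0,0)-(1,1) diagonal."""
    verts = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0],
                      [1.0, 1.0, 0.0], [0.0, 1.0, 0.0]])
    tris = np.array([[0, 1, 2], [0, 2, 3]])
    return compute_vertex_geometry(TriSurface(verts, tris))
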