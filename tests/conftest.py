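import numpy as np
import pytest
from hypothesis import settings

from morphocell import (CellState, FemSystem, Mesh, RectangleDomain,
                        ShapeTemplate)

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def unit_mesh():
    """Unit square, h = 1/8."""
    return Mesh.rectangle(RectangleDomain(1.0, 1.0), 1.0 / 8.0)


@pytest.fixture(scope="session")
def square_mesh():
    """120×120 μm domain at h = 10 (the chemotaxis domain size)."""
    return Mesh.rectangle(RectangleDomain(120.0, 120.0), 10.0)


@pytest.fixture(scope="session")
def fine_mesh():
    """120×120 μm domain at h = 6 used by the transport/mechanics tests."""
    return Mesh.rectangle(RectangleDomain(120.0, 120.0), 6.0)


@pytest.fixture()
def fem(fine_mesh):
    return FemSystem(fine_mesh, 0.1)


@pytest.fixture()
def circle_cell():
    return CellState.from_template(ShapeTemplate(kind="circle", R=5.0),
                                   centre=(0.0, 0.0), N=40)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
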