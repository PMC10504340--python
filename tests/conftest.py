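import numpy as np
import pytest

from envmorph import RodSpec, gen_rod_contour, mesh_contour


@pytest.fixture(scope="session")
def rod_4x1():
    """Noiseless spherocylinder, length 4 µm, width 1 µm."""
    return gen_rod_contour(RodSpec(length=4, width=1, n_vertices=256))


@pytest.fixture(scope="session")
def mesh_4x1(rod_4x1):
    return mesh_contour(rod_4x1)
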