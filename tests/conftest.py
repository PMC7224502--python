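import sys, pathlib
sys.path.insert(0, str(pathlib.Path(__file__).parent))
import numpy as np
import pytest

from tesfv.conductivity import TissueTable, isotropic_field
from tesfv.phantoms import (
    LayeredSphereModel,
    generate_layered_sphere_mesh,
    ortho_box_mesh,
    slab_mesh,
    three_layer_head_model,
)


@pytest.fixture(scope="session")
def head_model():
    """3-layer spherical head phantom with the 90 mm numerical outer radius."""
    return three_layer_head_model(numerical_outer=True)


@pytest.fixture(scope="session")
def coarse_sphere_mesh(head_model):
    """Small body-fitted sphere mesh shared by read-only tests."""
    return generate_layered_sphere_mesh(head_model, subdivisions=3)


@pytest.fixture(scope="session")
def single_layer_model():
    return LayeredSphereModel(radii=[10.0], conductivities=[1.0])


@pytest.fixture()
def uniform_slab():
    return slab_mesh((3, 3, 8))


@pytest.fixture()
def ortho_slab():
    return ortho_box_mesh((3, 3, 8))


@pytest.fixture()
def unit_tissue():
    return TissueTable({1: 1.0})


def uniform_conductivity(mesh, sigma=1.0):
    labels = np.unique(mesh.cell_labels)
    return isotropic_field(mesh, TissueTable({int(l): sigma for l in labels}))
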