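import numpy as np
import pytest

from ontether.constitutive import load_material_library
from ontether.eyemesh import MeshDensity, generate_mesh
from ontether.geometry import build_geometry


@pytest.fixture(scope="session")
def library():
    return load_material_library()


@pytest.fixture(scope="session")
def geometry():
    return build_geometry()


@pytest.fixture(scope="session")
def coarse_density():
    """Reduced density for fast scenario mechanics tests."""
    return MeshDensity().scaled(1.7)


@pytest.fixture(scope="session")
def eye_mesh_2d(geometry, coarse_density):
    return generate_mesh(geometry, density=coarse_density, mode="2d")


@pytest.fixture(scope="session")
def eye_mesh_2d_default(geometry):
    return generate_mesh(geometry, mode="2d")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)


def all_polynomial_cards(library):
    """Every reduced-polynomial card in the library."""
    cards = []
    for region in library.regions:
        for level in library.levels(region):
            card = library.get(region, level)
            if hasattr(card, "deviatoric_coeffs"):
                cards.append(card)
    return cards
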