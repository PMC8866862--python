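import numpy as np
import pytest

from mandifix import MandibleParams, build_mandible
from mandifix.materials import MaterialCard, load_material_table


@pytest.fixture(scope="session")
def coarse_mandible():
    """Coarse (2 mm) mandible: fast construction checks."""
    return build_mandible(MandibleParams(target_edge_length=2.0))


@pytest.fixture(scope="session")
def mandible():
    """Working-resolution (1 mm) mandible shared across tests."""
    return build_mandible(MandibleParams(target_edge_length=1.0))


@pytest.fixture(scope="session")
def cards():
    return load_material_table()


@pytest.fixture(scope="session")
def iso_card():
    return MaterialCard("iso", 15000.0, 15000.0, 15000.0, 0.3, 0.3, 0.3,
                        isotropic=True)
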