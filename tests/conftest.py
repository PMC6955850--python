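import numpy as np
import pytest

import tavsurrogate as tv
from tavsurrogate.synthetic_fea import SyntheticConfig, build_dataset

#: small mesh size used by fast tests: 119 = 17 x 7 interior grid + 2 commissures
SMALL_NODES = 121


@pytest.fixture(scope="session")
def nominal_design() -> tv.DesignParams:
    return tv.DesignParams(a=5.46, b=3.2, ssl=19.25)


@pytest.fixture(scope="session")
def small_contour(nominal_design):
    return tv.build_contour(nominal_design, n_points=19)


@pytest.fixture(scope="session")
def small_mesh(small_contour):
    return tv.mesh_leaflet(small_contour, target_nodes=SMALL_NODES)


@pytest.fixture(scope="session")
def tiny_dataset():
    """12 designs on the small mesh; enough for split/round-trip mechanics."""
    designs = tv.sample_designs(n=12, seed=42)
    return build_dataset(designs, SyntheticConfig(seed=42), target_nodes=SMALL_NODES)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2026)
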