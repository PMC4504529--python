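"""Shared fixtures: desk-scale phantoms, scans and reconstructions.

Everything is generated programmatically; session scope keeps the expensive
forward projections and reconstructions to one instance per run.
"""

import numpy as np
import pytest

import ldctsim as L

GRID = 256          # phantom raster used throughout the tests
N_VIEWS = 360


@pytest.fixture(scope="session")
def water_map():
    return L.make_water_phantom(grid_size=GRID)


@pytest.fixture(scope="session")
def head_spec():
    return L.PhantomSpec(kind="head")


@pytest.fixture(scope="session")
def head_map(head_spec):
    return L.make_head_phantom(head_spec, grid_size=GRID)


@pytest.fixture(scope="session")
def water_sino(water_map):
    return L.forward_project(water_map, n_views=N_VIEWS)


@pytest.fixture(scope="session")
def head_sino(head_map):
    return L.forward_project(head_map, n_views=N_VIEWS)


@pytest.fixture(scope="session")
def water_recon(water_sino):
    return L.fbp(water_sino)


@pytest.fixture(scope="session")
def head_recon(head_sino):
    return L.fbp(head_sino)


@pytest.fixture(scope="session")
def protocol():
    return L.ScanProtocol(eff_mas=160.0)


@pytest.fixture(scope="session")
def central_roi():
    """The 5-cm calibration ROI at the phantom center."""
    return L.RoiSpec(center=(0.0, 0.0), diameter=50.0, label="central")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
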