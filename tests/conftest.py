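import numpy as np
import pytest

from ctcflow.config import SimulationConfig
from ctcflow.fluid import Grid
from ctcflow.geometry import UM, CellGeometrySpec


@pytest.fixture
def cell_spec():
    """Baseline cell: 10 um disc, 4 um nucleus, 2 um cortex band."""
    return CellGeometrySpec(center=(20 * UM, 18 * UM), point_spacing=0.25 * UM)


@pytest.fixture
def small_grid():
    return Grid(nx=32, ny=32, Lx=32e-4, Ly=32e-4)


@pytest.fixture
def tiny_config():
    """Cheap full-world configuration for smoke-level simulation tests."""
    return SimulationConfig(nx=64, ny=32, n_steps=5, snapshot_every=2)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
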