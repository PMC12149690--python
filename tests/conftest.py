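"""Shared fixtures: phantom layout and small, fast simulation grids.

The small grid (5 slices, 96×96 at 2.2 mm pixels) covers the full 13-vial
footprint and keeps per-test simulation cost at a few milliseconds; the
acceptance tests use the full-resolution default grid instead.
"""

import numpy as np
import pytest

from adcqa import (
    SimulationConfig,
    builtin_layout,
    fit_adc_map,
    simulate_phantom_series,
)

SMALL_MATRIX = (5, 96, 96)
SMALL_VOXEL = (5.0, 2.2, 2.2)


@pytest.fixture(scope="session")
def layout():
    return builtin_layout()


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(matrix=SMALL_MATRIX, voxel_size=SMALL_VOXEL)


@pytest.fixture(scope="session")
def noiseless_series(layout, small_config):
    return simulate_phantom_series(layout, small_config)


@pytest.fixture(scope="session")
def noiseless_map(noiseless_series):
    return fit_adc_map(noiseless_series)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
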