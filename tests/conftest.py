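"""Shared fixtures: small reusable geometry and forward models.

Everything is generated programmatically; heavy objects are
session-scoped so the leadfield is computed once.
"""

from __future__ import annotations

import numpy as np
import pytest

import meghubs as mh


@pytest.fixture(scope="session")
def small_head_sensors():
    """64-channel helmet around a 9 cm head (leadfield unit tests)."""
    return mh.build_head_and_sensors(n_chan=64, head_radius=0.09,
                                     sensor_shell_radius=0.12, seed=0)


@pytest.fixture(scope="session")
def desk_setup():
    """Desk-scale inversion setup: 5 cm head, 120 channels, 12 mm grid.

    ~250 voxels — small enough that a full leadfield + beamformer run
    takes seconds, large enough for localization and parcel tests.
    """
    head, sensors = mh.build_head_and_sensors(
        n_chan=120, head_radius=0.05, sensor_shell_radius=0.08, seed=2
    )
    grid = mh.build_source_grid(head, 0.012)
    leadfield = mh.compute_leadfield(grid, sensors, head)
    return head, sensors, grid, leadfield


@pytest.fixture(scope="session")
def desk_atlas(desk_setup):
    _, _, grid, _ = desk_setup
    return mh.build_synthetic_atlas(grid, n_parcels_per_hemisphere=6, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
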