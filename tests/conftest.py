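"""Shared fixtures: small scan configurations and phantoms.

Everything is generated programmatically; sizes are kept small so the full
suite runs on one CPU in minutes.
"""

from __future__ import annotations

import numpy as np
import pytest

from rsompy.datatypes import PhantomTruth, ScanConfig


@pytest.fixture(scope="session")
def small_config() -> ScanConfig:
    """30x30 scan positions at 20 um pitch, 640 samples at 1 GS/s."""
    return ScanConfig(
        n_fast=30, n_slow=30, step_fast_um=20.0, step_slow_um=20.0,
        n_samples=640, rep_rate_hz=1400.0,
    )


@pytest.fixture(scope="session")
def motion_config() -> ScanConfig:
    """Coarse grid with long A-lines and slow repetition so a full scan
    spans several breathing periods."""
    return ScanConfig(
        n_fast=31, n_slow=31, step_fast_um=20.0, step_slow_um=20.0,
        n_samples=1024, rep_rate_hz=64.0,
    )


def make_point_phantom(
    index: tuple[int, int, int],
    grid_shape=(48, 48, 64),
    voxel_size_um=(12.0, 12.0, 6.0),
) -> PhantomTruth:
    ab = np.zeros(grid_shape, dtype=np.float32)
    ab[index] = 1.0
    return PhantomTruth(
        absorption=ab,
        voxel_size_um=voxel_size_um,
        vessel_mask=ab > 0,
        melanin_mask=np.zeros(grid_shape, dtype=bool),
        vessel_segments=[],
    )


def make_plane_phantom(
    z_index: int = 80,
    grid_shape=(32, 32, 200),
    voxel_size_um=(20.0, 20.0, 5.0),
) -> PhantomTruth:
    """Flat absorbing sheet, a stand-in for the strongly absorbing skin
    surface used by the motion tests."""
    ab = np.zeros(grid_shape, dtype=np.float32)
    ab[:, :, z_index] = 1.0
    return PhantomTruth(
        absorption=ab,
        voxel_size_um=voxel_size_um,
        vessel_mask=ab > 0,
        melanin_mask=np.zeros(grid_shape, dtype=bool),
        vessel_segments=[],
    )
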