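"""Shared fixtures: small, fast scanner/grid configurations.

The "tiny" configuration (short no-raster scan, small grid) keeps
operator-level tests in the millisecond range; the "oracle"
configuration is the 16x16 fixture used for continuum comparisons.
"""

import numpy as np
import pytest

from fflmpi.grids import ImageGrid
from fflmpi.operators import build_projection_model
from fflmpi.scanner import ParticleModel, RasterSpec, ScannerModel


@pytest.fixture(scope="session")
def tiny_scanner():
    # 9 drive periods, no raster: 360 samples at 1.8 MHz
    return ScannerModel(drive_axis="z", raster=None,
                        scan_duration=9 / 45e3, sample_rate=1.8e6,
                        fov=(0.016, 0.016, 0.016))


@pytest.fixture(scope="session")
def tiny_grid():
    return ImageGrid((12, 12), (1e-3, 1e-3))


@pytest.fixture(scope="session")
def particle():
    return ParticleModel()


@pytest.fixture(scope="session")
def tiny_model(tiny_grid, tiny_scanner, particle):
    return build_projection_model(tiny_grid, tiny_scanner, particle,
                                  K=5, bandwidth=30e3)


@pytest.fixture(scope="session")
def raster_scanner():
    # small raster scan staying inside a 16 mm grid
    return ScannerModel(
        drive_axis="z", drive_amplitude=5e-3,
        fov=(0.016, 0.016, 0.016),
        raster=RasterSpec(n_lines=4, line_period=2e-3,
                          x_extent=0.012, z_extent=0.012),
        sample_rate=500e3)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
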