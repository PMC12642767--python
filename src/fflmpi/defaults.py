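"""Default desk-scale study configuration.

The scanner constants mirror a preclinical FFL system: a 5.7 T/m
gradient, 5 mT drive amplitude at 45 kHz, a zig-zag slow raster in the
(x, z) plane, two collinear scans (x- and z-axis drive) per projection
angle, and harmonic compression keeping 0.5 kHz of total bandwidth
around harmonics 2 through 5.  The desk-scale sizes (24^3 voxels,
12 angles, 6 raster lines of 107 ms) keep a full simulate-plus-
reconstruct round in the minutes range on one CPU while preserving the
structure of a full-size acquisition.  The ~0.64 s scan makes the
raster slow enough that the signal envelope's sidebands stay inside the
0.5 kHz harmonic bands (the crossing time of the point spread at the
raster speed must exceed a few milliseconds), mirroring the
seconds-long rasters of the physical scanner; six lines keep the
slow-axis line spacing (5 mm) within reach of the drive excursion and
point spread so the z-axis stays resolved.
"""

from __future__ import annotations

from .grids import ImageGrid
from .operators import ProjectionModel, build_projection_model
from .scanner import ParticleModel, RasterSpec, ScannerModel
from .tomography import AngleSet, ForwardModel3D

__all__ = [
    "DEFAULT_BANDWIDTH",
    "DEFAULT_K",
    "DEFAULT_LAMBDA",
    "default_scanner",
    "default_particle",
    "default_volume_grid",
    "default_angles",
    "default_models",
    "default_forward_model",
]

DEFAULT_K = 5
DEFAULT_BANDWIDTH = 500.0  # Hz, total width per harmonic band

# Default regularization weight, as a dimensionless fraction of
# ||A^H A|| / ||T^T T|| (see ReconConfig.lam_relative): the smoothness
# prior contributes ~1% of the data-term curvature — enough to damp
# noise amplification in weakly sensed directions on smooth objects
# without biasing the fit.  For quantitative point-source analysis at
# the fixed 150-iteration budget, lambda = 0 converges closer to the
# data (see docs/methods.md).
DEFAULT_LAMBDA = 0.01


def oracle_scanner() -> ScannerModel:
    """Scanner for continuum-oracle verification on a 16x16 grid.

    Uses the hardware's higher 15 mT drive option so the FFL drive
    excursion (A/G0 ~ 2.6 mm) spans several 1 mm cells: the bilinear
    trajectory sampling then resolves the harmonic-generating motion and
    the discretization error of the operator pipeline stays below the
    comparison tolerance.  The raster is kept strictly inside the grid
    (the discrete model assigns no signal to trajectory samples outside
    the reconstruction grid, which the continuum does not emulate).
    """
    return ScannerModel(
        gradient=5.7, drive_amplitude=15e-3, drive_frequency=45e3,
        drive_axis="z", fov=(0.016, 0.016, 0.016),
        raster=RasterSpec(n_lines=4, line_period=5e-3,
                          x_extent=0.014, z_extent=0.0084),
        sample_rate=500e3, notch_halfwidth=1e3, max_harmonic=DEFAULT_K)


def oracle_particle() -> ParticleModel:
    # a softer tracer (wider point spread) for the continuum comparison
    return ParticleModel(moment=1e-18, beta=100.0)


def oracle_grid() -> ImageGrid:
    return ImageGrid((16, 16), (1e-3, 1e-3))


def default_scanner(drive_axis: str = "z") -> ScannerModel:
    return ScannerModel(
        gradient=5.7,
        drive_amplitude=5e-3,
        drive_frequency=45e3,
        drive_axis=drive_axis,
        fov=(0.03, 0.03, 0.03),
        raster=RasterSpec(n_lines=6, line_period=107e-3,
                          x_extent=0.03, z_extent=0.03),
        sample_rate=500e3,
        notch_halfwidth=1e3,
        max_harmonic=DEFAULT_K,
    )


def default_particle() -> ParticleModel:
    # ~30 nm equivalent-core multicore tracer; beta = moment / (kB * 300 K)
    return ParticleModel(moment=5.3e-18, beta=1280.0)


def default_volume_grid(n: int = 24) -> ImageGrid:
    return ImageGrid((n, n, n), (1.25e-3,) * 3)


def default_angles(n: int = 12) -> AngleSet:
    return AngleSet.equally_spaced(n)


def default_models(grid: ImageGrid, particle: ParticleModel | None = None,
                   scanners: tuple[ScannerModel, ScannerModel] | None = None,
                   K: int = DEFAULT_K, bandwidth: float = DEFAULT_BANDWIDTH
                   ) -> list[ProjectionModel]:
    """The x-drive and z-drive operator chains on the (x, z) plane grid."""
    particle = particle or default_particle()
    if scanners is None:
        scanners = (default_scanner("x"), default_scanner("z"))
    return [build_projection_model(grid.plane_xz(), sc, particle,
                                   K=K, bandwidth=bandwidth)
            for sc in scanners]


def default_forward_model(volume_grid: ImageGrid | None = None,
                          n_angles: int = 12,
                          particle: ParticleModel | None = None
                          ) -> ForwardModel3D:
    volume_grid = volume_grid or default_volume_grid()
    models = default_models(volume_grid, particle=particle)
    return ForwardModel3D(volume_grid, default_angles(n_angles), models)
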