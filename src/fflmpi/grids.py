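"""Cell-centered image grids.

All grids are symmetric about the scanner isocenter: the coordinate of
voxel index ``i`` along an axis with ``n`` voxels and spacing ``d`` is
``(i - (n - 1) / 2) * d`` metres.  2D grids live in the (x, z) plane of
the scanner (the FFL runs along y); 3D grids are ordered (x, y, z).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ImageGrid"]


@dataclass(frozen=True)
class ImageGrid:
    """A cell-centered rectangular grid with physical spacing in metres."""

    shape: tuple[int, ...]
    spacing: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.shape) not in (2, 3):
            raise ValueError("grid must be 2D (x,z) or 3D (x,y,z)")
        if len(self.spacing) != len(self.shape):
            raise ValueError("spacing and shape dimensionality differ")
        if any(n < 1 for n in self.shape):
            raise ValueError("grid shape entries must be positive")
        if any(d <= 0 for d in self.spacing):
            raise ValueError("grid spacing must be positive")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(d) for d in self.spacing))

    @property
    def ndim(self) -> int:
        return len(self.shape)

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.shape))

    @property
    def extent(self) -> tuple[float, ...]:
        """Physical side length of the grid per axis (metres)."""
        return tuple(n * d for n, d in zip(self.shape, self.spacing))

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def axis_coords(self, axis: int) -> np.ndarray:
        """Coordinates of voxel centers along ``axis`` (metres)."""
        n = self.shape[axis]
        d = self.spacing[axis]
        return (np.arange(n) - (n - 1) / 2.0) * d

    def meshgrid(self) -> tuple[np.ndarray, ...]:
        axes = [self.axis_coords(a) for a in range(self.ndim)]
        return tuple(np.meshgrid(*axes, indexing="ij"))

    def plane_xz(self) -> "ImageGrid":
        """The 2D (x, z) grid obtained by dropping the y axis of a 3D grid."""
        if self.ndim == 2:
            return self
        return ImageGrid((self.shape[0], self.shape[2]), (self.spacing[0], self.spacing[2]))
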