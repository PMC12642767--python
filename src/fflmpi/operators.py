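"""Discrete forward-model operators for 2D FFL projection imaging.

The received MPI signal factors into a chain of efficient linear
operators acting on a voxelized density image rho on the (x, z) grid:

    s = Gamma V E H B rho

* ``B`` weights rho by each receive-coil sensitivity component b_i,
* ``H`` convolves each weighted image with the nine Langevin
  point-spread kernels h_ij,
* ``E`` samples the convolved images along the FFL trajectory
  (bilinear interpolation; "FFP selection"),
* ``V`` multiplies by the trajectory velocity components and sums,
* ``Gamma`` is the receive-chain filter (a notch at the fundamental),
  diagonal in the Fourier domain: ``Gamma = F^-1 D_Gamma F``.

Harmonic compression selects narrow Fourier bands around harmonics
``k = 2..K`` of the drive frequency.  Writing the band selector as ``S``
and the FFT as ``F``, the compressed model is

    A_DC = S D_Gamma F V E H B,

which needs a single FFT per application and is algebraically identical
to ``S F Gamma V E H B``.

All operators are :class:`~fflmpi.linops.LinearMap` instances with exact
adjoints, linear over the complex field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.signal import fftconvolve

from .grids import ImageGrid
from .linops import Compose, DiagonalMap, LinearMap
from .scanner import (
    ParticleModel,
    ScannerModel,
    ffl_position,
    ffl_velocity,
    psf_tensor_grid,
)

__all__ = [
    "TimeSignal",
    "HarmonicBlock",
    "ReceiveWeight",
    "PSFConvolution",
    "TrajectorySampler",
    "VelocityWeight",
    "NotchFilter",
    "FourierMap",
    "HarmonicSelector",
    "gamma_transfer",
    "bilinear_matrix",
    "ProjectionModel",
    "build_projection_model",
    "energy_retention",
]


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------

@dataclass
class TimeSignal:
    """A uniformly sampled receive-coil signal for one scan."""

    samples: np.ndarray
    sample_rate: float
    drive_axis: str | None = None
    angle: float | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("time signal contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate


@dataclass
class HarmonicBlock:
    """Complex Fourier coefficients in bands around harmonics 2..K.

    ``coefficients`` concatenates the per-harmonic bands in ascending
    harmonic then ascending FFT-bin order; ``band_index_map`` maps each
    harmonic k to the FFT bin indices (positive frequencies of the
    length-``n_samples`` DFT) forming its band.
    """

    coefficients: np.ndarray
    band_index_map: dict[int, np.ndarray]
    f0: float
    sample_rate: float
    n_samples: int
    K: int
    bandwidth: float
    drive_axis: str | None = None
    angle: float | None = None

    @property
    def n_coefficients(self) -> int:
        return self.coefficients.size

    def compression_ratio(self) -> float:
        """Compressed bytes / raw bytes: complex128 bands over float64 samples."""
        return (self.n_coefficients * 16) / (self.n_samples * 8)


# ---------------------------------------------------------------------------
# Operators
# ---------------------------------------------------------------------------

class ReceiveWeight(LinearMap):
    """B: pointwise weighting of rho by the receive sensitivity field.

    ``sensitivity`` is either a homogeneous 3-vector or a full (3, nx,
    nz) field.  Maps N -> 3N with output component order (x, y, z).
    """

    def __init__(self, grid: ImageGrid, sensitivity: np.ndarray):
        if grid.ndim != 2:
            raise ValueError("ReceiveWeight acts on 2D (x, z) grids")
        self.grid = grid
        b = np.asarray(sensitivity, dtype=float)
        if b.shape == (3,):
            b = np.broadcast_to(b[:, None, None], (3,) + grid.shape).copy()
        if b.shape != (3,) + grid.shape:
            raise ValueError("sensitivity must be a 3-vector or (3, nx, nz) field")
        self.sensitivity = b
        self.dom_size = grid.n_cells
        self.ran_size = 3 * grid.n_cells

    def forward(self, x):
        img = np.asarray(x).reshape(self.grid.shape)
        return (self.sensitivity * img[None]).reshape(-1)

    def adjoint(self, y):
        imgs = np.asarray(y).reshape((3,) + self.grid.shape)
        return np.sum(self.sensitivity * imgs, axis=0).reshape(-1)


class PSFConvolution(LinearMap):
    """H: convolution of each weighted image with the Langevin PSF kernels.

    Input is the stack (b_i rho), i = x,y,z; output is the stack C_ij =
    (b_i rho) * h_ij for i,j = x,y,z (nine images, row-major ij order).
    Kernels are the point-spread tensor sampled at grid offsets and
    scaled by the voxel area (the Riemann sum of the response integral);
    rows and columns along the FFL axis are identically zero.  FFT-based
    zero-padded linear convolution, cropped back to the grid.
    """

    def __init__(self, grid: ImageGrid, scanner: ScannerModel,
                 particle: ParticleModel, truncation: float = 1e-6):
        if grid.ndim != 2:
            raise ValueError("PSFConvolution acts on 2D (x, z) grids")
        self.grid = grid
        nx, nz = grid.shape
        dx, dz = grid.spacing
        ox = (np.arange(2 * nx - 1) - (nx - 1)) * dx
        oz = (np.arange(2 * nz - 1) - (nz - 1)) * dz
        kernels = psf_tensor_grid(scanner, particle, ox[:, None], oz[None, :])
        kernels = kernels * grid.voxel_volume
        if truncation and truncation > 0:
            kernels = self._truncate(kernels, truncation)
        self.kernels = kernels
        self._norms = np.linalg.norm(kernels.reshape(3, 3, -1), axis=-1)
        self.dom_size = 3 * grid.n_cells
        self.ran_size = 9 * grid.n_cells

    @staticmethod
    def _truncate(kernels: np.ndarray, rel: float) -> np.ndarray:
        mag = np.max(np.abs(kernels), axis=(0, 1))
        thresh = rel * mag.max()
        rows = np.where(np.any(mag > thresh, axis=1))[0]
        cols = np.where(np.any(mag > thresh, axis=0))[0]
        if rows.size == 0:
            return kernels
        cx, cz = (kernels.shape[2] - 1) // 2, (kernels.shape[3] - 1) // 2
        # symmetric odd crop so the kernel center stays at the array center
        rx = max(abs(rows[0] - cx), abs(rows[-1] - cx))
        rz = max(abs(cols[0] - cz), abs(cols[-1] - cz))
        return kernels[:, :, cx - rx:cx + rx + 1, cz - rz:cz + rz + 1]

    def forward(self, x):
        x = np.asarray(x)
        imgs = x.reshape((3,) + self.grid.shape)
        out = np.zeros((3, 3) + self.grid.shape, dtype=np.result_type(x, float))
        for i in range(3):
            if not np.any(imgs[i]):
                continue
            for j in range(3):
                if self._norms[i, j] == 0:
                    continue
                out[i, j] = fftconvolve(imgs[i], self.kernels[i, j], mode="same")
        return out.reshape(-1)

    def adjoint(self, y):
        y = np.asarray(y)
        imgs = y.reshape((3, 3) + self.grid.shape)
        out = np.zeros((3,) + self.grid.shape, dtype=np.result_type(y, float))
        for i in range(3):
            for j in range(3):
                if self._norms[i, j] == 0 or not np.any(imgs[i, j]):
                    continue
                out[i] += fftconvolve(imgs[i, j], self.kernels[i, j][::-1, ::-1],
                                      mode="same")
        return out.reshape(-1)


def _snap(u: np.ndarray, n: int, eps: float = 1e-9) -> np.ndarray:
    """Snap fractional grid indices to the boundary nodes they are within
    ``eps`` of, so rays/points that touch the node lattice exactly (up to
    round-off) are not dropped."""
    u = np.where(np.abs(u) < eps, 0.0, u)
    return np.where(np.abs(u - (n - 1)) < eps, float(n - 1), u)


def bilinear_matrix(grid: ImageGrid, points: np.ndarray) -> sp.csr_matrix:
    """Sparse bilinear interpolation matrix sampling a 2D grid at ``points``.

    ``points`` has shape (2, n) in physical (x, z) coordinates.  Points
    outside the span of voxel centers produce all-zero rows (and hence
    receive a zero splat in the transpose), keeping the adjoint exact.
    """
    if grid.ndim != 2:
        raise ValueError("bilinear_matrix expects a 2D grid")
    nx, nz = grid.shape
    dx, dz = grid.spacing
    x0 = -(nx - 1) / 2.0 * dx
    z0 = -(nz - 1) / 2.0 * dz
    px = _snap((np.asarray(points[0], float) - x0) / dx, nx)
    pz = _snap((np.asarray(points[1], float) - z0) / dz, nz)
    n = px.size

    ix = np.floor(px).astype(np.int64)
    iz = np.floor(pz).astype(np.int64)
    # points on the far boundary node belong to the last cell
    ix[px == nx - 1] -= 1
    iz[pz == nz - 1] -= 1
    fx = px - ix
    fz = pz - iz
    valid = (ix >= 0) & (ix <= nx - 2) & (iz >= 0) & (iz <= nz - 2)

    rows = np.repeat(np.arange(n), 4)
    base = ix * nz + iz
    cols = np.stack([base, base + 1, base + nz, base + nz + 1], axis=1)
    w = np.stack([(1 - fx) * (1 - fz), (1 - fx) * fz,
                  fx * (1 - fz), fx * fz], axis=1)
    w[~valid] = 0.0
    cols[~valid] = 0
    mat = sp.coo_matrix((w.reshape(-1), (rows, cols.reshape(-1))),
                        shape=(n, nx * nz))
    mat.sum_duplicates()
    return mat.tocsr()


class TrajectorySampler(LinearMap):
    """E: sample each convolved image C_ij along the FFL trajectory.

    Maps 9N -> 9T by bilinear interpolation at the FFL (x, z) positions;
    the adjoint splats with the transposed interpolation weights.
    Trajectory samples outside the grid contribute zero.
    """

    def __init__(self, grid: ImageGrid, scanner: ScannerModel):
        self.grid = grid
        t = scanner.time_samples()
        traj = ffl_position(scanner, t)
        self.matrix = bilinear_matrix(grid, traj)
        if self.matrix.nnz == 0 or self.matrix.sum() == 0:
            raise ValueError("FFL trajectory lies entirely outside the grid")
        self._adj = self.matrix.T.tocsr()
        self.n_time = t.size
        self.dom_size = 9 * grid.n_cells
        self.ran_size = 9 * self.n_time

    def forward(self, x):
        x = np.asarray(x)
        imgs = x.reshape(9, self.grid.n_cells)
        out = np.zeros((9, self.n_time), dtype=np.result_type(x, float))
        for c in range(9):  # skip identically-zero channels (y rows/cols)
            if np.any(imgs[c]):
                out[c] = self.matrix @ imgs[c]
        return out.reshape(-1)

    def adjoint(self, y):
        y = np.asarray(y)
        series = y.reshape(9, self.n_time)
        out = np.zeros((9, self.grid.n_cells), dtype=np.result_type(y, float))
        for c in range(9):
            if np.any(series[c]):
                out[c] = self._adj @ series[c]
        return out.reshape(-1)


class VelocityWeight(LinearMap):
    """V: multiply the sampled series by the FFL velocity and sum.

    ``s0(t) = m * sum_ij v_j(t) * series_ij(t)`` with the particle
    moment m; the adjoint broadcasts ``m v_j(t) s(t)`` back to all ij.
    """

    def __init__(self, scanner: ScannerModel, particle: ParticleModel):
        t = scanner.time_samples()
        v2 = ffl_velocity(scanner, t)
        self.velocity = np.zeros((3, t.size))
        self.velocity[0] = v2[0]
        self.velocity[2] = v2[1]
        self.moment = particle.moment
        self.n_time = t.size
        self.dom_size = 9 * self.n_time
        self.ran_size = self.n_time

    def forward(self, x):
        series = np.asarray(x).reshape(3, 3, self.n_time)
        out = np.zeros(self.n_time, dtype=np.result_type(series, float))
        for j in range(3):
            if np.any(self.velocity[j]):
                out += self.velocity[j] * (series[0, j] + series[1, j]
                                           + series[2, j])
        return self.moment * out

    def adjoint(self, y):
        y = np.asarray(y)
        out = np.zeros((3, 3, self.n_time), dtype=np.result_type(y, float))
        for j in range(3):
            if np.any(self.velocity[j]):
                row = self.moment * self.velocity[j] * y
                out[0, j] = row
                out[1, j] = row
                out[2, j] = row
        return out.reshape(-1)


def gamma_transfer(scanner: ScannerModel, n_samples: int) -> np.ndarray:
    """Default receive transfer function over the length-n DFT bins.

    Unit gain and zero phase everywhere except a notch of half-width
    ``scanner.notch_halfwidth`` around +-f0, where the gain is zero.
    """
    freqs = np.fft.fftfreq(n_samples, d=1.0 / scanner.sample_rate)
    transfer = np.ones(n_samples, dtype=complex)
    notch = np.abs(np.abs(freqs) - scanner.drive_frequency) <= scanner.notch_halfwidth
    transfer[notch] = 0.0
    return transfer


class NotchFilter(LinearMap):
    """Gamma: the receive-chain filter as a Fourier-domain diagonal.

    ``Gamma = F^-1 D F`` with ``D`` the (complex) transfer function.
    For real input and a Hermitian-symmetric transfer the output is
    returned real; complex input flows through C-linearly.  The adjoint
    multiplies by the conjugate transfer.
    """

    def __init__(self, transfer: np.ndarray):
        self.transfer = np.asarray(transfer, dtype=complex)
        self.dom_size = self.ran_size = self.transfer.size
        rev = np.roll(self.transfer[::-1], 1)  # D[-k]
        self.hermitian = bool(np.allclose(np.conj(rev), self.transfer))

    def _apply(self, x, transfer):
        x = np.asarray(x)
        out = np.fft.ifft(transfer * np.fft.fft(x))
        if np.isrealobj(x) and self.hermitian:
            return out.real
        return out

    def forward(self, x):
        return self._apply(x, self.transfer)

    def adjoint(self, y):
        return self._apply(y, np.conj(self.transfer))


class FourierMap(LinearMap):
    """F: the unnormalized length-n DFT; adjoint is ``n * ifft``."""

    def __init__(self, n: int):
        self.dom_size = self.ran_size = n

    def forward(self, x):
        return np.fft.fft(np.asarray(x))

    def adjoint(self, y):
        return self.dom_size * np.fft.ifft(np.asarray(y))


class HarmonicSelector(LinearMap):
    """S: selection of Fourier bins in bands around harmonics 2..K.

    A bin at frequency f (positive frequencies only) belongs to harmonic
    k iff ``|f - k f0| <= bandwidth / 2`` (bandwidth is the *total* band
    width).  The adjoint scatters coefficients back into an otherwise
    zero spectrum, so ``S S^H`` is the identity on the compressed space.
    """

    def __init__(self, n_samples: int, sample_rate: float, f0: float,
                 K: int, bandwidth: float):
        if K < 2:
            raise ValueError("need K >= 2 (harmonic bands start at k = 2)")
        if K * f0 + bandwidth / 2 >= sample_rate / 2:
            raise ValueError(
                "highest harmonic band exceeds Nyquist: "
                f"K*f0 + bw/2 = {K * f0 + bandwidth / 2:g} Hz >= "
                f"{sample_rate / 2:g} Hz"
            )
        freqs = np.fft.fftfreq(n_samples, d=1.0 / sample_rate)
        band_map: dict[int, np.ndarray] = {}
        for k in range(2, K + 1):
            sel = (freqs > 0) & (np.abs(freqs - k * f0) <= bandwidth / 2)
            band_map[k] = np.where(sel)[0]
        idx = np.concatenate([band_map[k] for k in range(2, K + 1)])
        if np.unique(idx).size != idx.size:
            raise ValueError("harmonic bands overlap; reduce bandwidth")
        self.band_index_map = band_map
        self.indices = idx
        self.n_samples = n_samples
        self.sample_rate = sample_rate
        self.f0 = f0
        self.K = K
        self.bandwidth = bandwidth
        self.dom_size = n_samples
        self.ran_size = idx.size

    def forward(self, x):
        return np.asarray(x, dtype=complex)[self.indices]

    def adjoint(self, y):
        out = np.zeros(self.n_samples, dtype=complex)
        out[self.indices] = np.asarray(y)
        return out

    def make_block(self, coefficients: np.ndarray, drive_axis=None,
                   angle=None) -> HarmonicBlock:
        return HarmonicBlock(
            coefficients=np.asarray(coefficients, dtype=complex),
            band_index_map={k: v.copy() for k, v in self.band_index_map.items()},
            f0=self.f0, sample_rate=self.sample_rate,
            n_samples=self.n_samples, K=self.K, bandwidth=self.bandwidth,
            drive_axis=drive_axis, angle=angle,
        )


# ---------------------------------------------------------------------------
# Assembled 2D models
# ---------------------------------------------------------------------------

@dataclass
class ProjectionModel:
    """The operator chain for one 2D FFL scan (one drive axis).

    Attributes
    ----------
    signal : LinearMap
        ``V E H B`` — the unfiltered time-domain signal s0.
    time_model : LinearMap
        ``M = Gamma V E H B`` — the filtered time-domain model.
    compressed : LinearMap
        ``A_DC = S D_Gamma F V E H B`` — the harmonic-compressed model
        (single FFT).
    compressed_via_gamma : LinearMap
        ``S F Gamma V E H B`` — the algebraically equivalent three-FFT
        form, kept as a cross-check.
    spectral : LinearMap
        ``S D_Gamma F`` — maps a raw time signal to its compressed
        harmonic coefficients (used to compress measured/noisy data
        identically to the model path).
    """

    grid: ImageGrid
    scanner: ScannerModel
    particle: ParticleModel
    B: ReceiveWeight
    H: PSFConvolution
    E: TrajectorySampler
    V: VelocityWeight
    gamma: NotchFilter
    F: FourierMap
    S: HarmonicSelector
    D_gamma: DiagonalMap
    signal: LinearMap = field(init=False)
    time_model: LinearMap = field(init=False)
    compressed: LinearMap = field(init=False)
    compressed_via_gamma: LinearMap = field(init=False)
    spectral: LinearMap = field(init=False)

    def __post_init__(self) -> None:
        self.signal = Compose([self.V, self.E, self.H, self.B])
        self.time_model = Compose([self.gamma, self.V, self.E, self.H, self.B])
        self.compressed = Compose([self.S, self.D_gamma, self.F,
                                   self.V, self.E, self.H, self.B])
        self.compressed_via_gamma = Compose([self.S, self.F, self.gamma,
                                             self.V, self.E, self.H, self.B])
        self.spectral = Compose([self.S, self.D_gamma, self.F])

    @property
    def n_time(self) -> int:
        return self.V.n_time

    def make_block(self, coefficients, angle=None) -> HarmonicBlock:
        return self.S.make_block(coefficients, drive_axis=self.scanner.drive_axis,
                                 angle=angle)


def build_projection_model(grid: ImageGrid, scanner: ScannerModel,
                           particle: ParticleModel, K: int | None = None,
                           bandwidth: float = 500.0,
                           transfer: np.ndarray | None = None,
                           sensitivity: np.ndarray | None = None,
                           kernel_truncation: float = 1e-6) -> ProjectionModel:
    """Assemble the full operator chain for one scanner configuration."""
    grid = grid.plane_xz()
    if K is None:
        K = scanner.max_harmonic
    n = scanner.n_samples
    if transfer is None:
        transfer = gamma_transfer(scanner, n)
    transfer = np.asarray(transfer, dtype=complex)
    if transfer.size != n:
        raise ValueError("transfer function length must match the scan samples")
    b = sensitivity if sensitivity is not None else scanner.sensitivity_vector
    return ProjectionModel(
        grid=grid, scanner=scanner, particle=particle,
        B=ReceiveWeight(grid, b),
        H=PSFConvolution(grid, scanner, particle, truncation=kernel_truncation),
        E=TrajectorySampler(grid, scanner),
        V=VelocityWeight(scanner, particle),
        gamma=NotchFilter(transfer),
        F=FourierMap(n),
        S=HarmonicSelector(n, scanner.sample_rate, scanner.drive_frequency,
                           K, bandwidth),
        D_gamma=DiagonalMap(transfer),
    )


def energy_retention(signal: np.ndarray, scanner: ScannerModel,
                     K: int | None = None, bandwidth: float = 500.0) -> float:
    """Fraction of notch-filtered signal energy inside harmonic bands 2..K.

    Energies are computed via Parseval on the full DFT; the selected
    positive-frequency bins are counted twice to account for their
    conjugate mirrors in the real signal's spectrum.
    """
    signal = np.asarray(signal, dtype=float)
    n = signal.size
    if K is None:
        K = scanner.max_harmonic
    transfer = gamma_transfer(scanner, n)
    spec = transfer * np.fft.fft(signal)
    total = float(np.sum(np.abs(spec) ** 2))
    if total == 0:
        return 1.0
    sel = HarmonicSelector(n, scanner.sample_rate, scanner.drive_frequency,
                           K, bandwidth)
    retained = 2.0 * float(np.sum(np.abs(spec[sel.indices]) ** 2))
    return retained / total
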