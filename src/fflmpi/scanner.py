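"""Continuous physics of a field-free-line (FFL) MPI scanner.

The scanner applies a static gradient field ``-G x`` with gradient matrix
``G = diag(-G0, 0, G0)``, which nulls the field along a line parallel to
the y-axis (the FFL), plus a sinusoidal drive field and a slow zig-zag
raster shift that together sweep the FFL through the (x, z) plane.  The
nanoparticle ensemble responds with the equilibrium Langevin
magnetization, and the receive coil detects the time derivative of the
net moment projected onto its sensitivity profile.

Units: all magnetic fields are stored as ``mu0 * H`` in tesla, so the
Langevin saturation constant ``beta`` has units 1/T and the argument of
the Langevin function is ``beta * ||field||``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RasterSpec",
    "ScannerModel",
    "ParticleModel",
    "langevin",
    "langevin_derivative",
    "langevin_over_argument",
    "ffl_position",
    "ffl_velocity",
    "magnetic_field",
    "drive_field",
    "psf_tensor",
    "psf_tensor_grid",
]

_AXIS_INDEX = {"x": 0, "z": 2}


@dataclass(frozen=True)
class RasterSpec:
    """Slow zig-zag raster of the FFL: fast triangular sweep along x, slow
    linear ramp along z.

    ``n_lines`` fast lines of duration ``line_period`` each traverse the
    full ``x_extent`` (peak-to-peak, metres) while z ramps linearly over
    ``z_extent``.  Velocity at the triangle vertices is taken as the
    right-hand derivative.
    """

    n_lines: int = 6
    line_period: float = 107e-3
    x_extent: float = 0.03
    z_extent: float = 0.03

    def __post_init__(self) -> None:
        if self.n_lines < 1 or self.line_period <= 0:
            raise ValueError("raster needs n_lines >= 1 and line_period > 0")
        if self.x_extent < 0 or self.z_extent < 0:
            raise ValueError("raster extents must be nonnegative")

    @property
    def duration(self) -> float:
        return self.n_lines * self.line_period

    @property
    def line_spacing(self) -> float:
        """Slow-axis shift per fast line (metres)."""
        return self.z_extent / self.n_lines

    def position(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Raster displacement (x, z) of the FFL at time ``t`` (metres)."""
        t = np.asarray(t, dtype=float)
        phase = t / self.line_period
        line = np.floor(phase)
        frac = phase - line
        forward = np.mod(line, 2) == 0
        x = np.where(forward, frac, 1.0 - frac) * self.x_extent - self.x_extent / 2.0
        z = (t / self.duration) * self.z_extent - self.z_extent / 2.0
        return x, z

    def velocity(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        t = np.asarray(t, dtype=float)
        line = np.floor(t / self.line_period)
        sign = np.where(np.mod(line, 2) == 0, 1.0, -1.0)
        vx = sign * self.x_extent / self.line_period
        vz = np.full_like(t, self.z_extent / self.duration)
        return vx, vz


@dataclass(frozen=True)
class ScannerModel:
    """Geometry and waveforms of one FFL scan.

    Parameters
    ----------
    gradient : float
        Gradient strength G0 (T/m); the gradient matrix is
        ``diag(-G0, 0, G0)``.
    drive_amplitude : float
        Drive field amplitude A (tesla, as mu0*H).
    drive_frequency : float
        Fundamental drive frequency f0 (Hz).
    drive_axis : str
        ``"x"`` or ``"z"``; the FFL itself is fixed along y.
    fov : tuple
        Field-of-view extents per axis (x, y, z), metres.
    raster : RasterSpec or None
        Slow-shift waveform; ``None`` for a pure drive scan, in which
        case ``scan_duration`` must be given.
    sample_rate : float
        Receive sampling rate (Hz).
    notch_halfwidth : float
        Half-width (Hz) of the fundamental notch of the receive chain.
    receive_sensitivity : tuple or None
        Homogeneous coil sensitivity vector b; ``None`` selects the unit
        vector along the drive axis.
    max_harmonic : int
        Highest harmonic intended to be retained; used for the Nyquist
        validity check ``sample_rate > 2 * max_harmonic * drive_frequency``.
    """

    gradient: float = 5.7
    drive_amplitude: float = 5e-3
    drive_frequency: float = 45e3
    drive_axis: str = "z"
    fov: tuple[float, float, float] = (0.03, 0.03, 0.03)
    raster: RasterSpec | None = field(default_factory=RasterSpec)
    sample_rate: float = 500e3
    notch_halfwidth: float = 1e3
    receive_sensitivity: tuple[float, float, float] | None = None
    max_harmonic: int = 5
    scan_duration: float | None = None

    def __post_init__(self) -> None:
        if self.gradient <= 0:
            raise ValueError("gradient strength must be positive")
        if self.drive_frequency <= 0:
            raise ValueError("drive frequency must be positive")
        if self.drive_amplitude < 0:
            raise ValueError("drive amplitude must be nonnegative")
        if self.drive_axis not in _AXIS_INDEX:
            raise ValueError("drive_axis must be 'x' or 'z'")
        if any(e <= 0 for e in self.fov):
            raise ValueError("fov extents must be positive")
        if self.sample_rate <= 2 * self.max_harmonic * self.drive_frequency:
            raise ValueError(
                "sample_rate must exceed 2 * max_harmonic * drive_frequency "
                "(Nyquist for the retained harmonics)"
            )
        if self.raster is None and self.scan_duration is None:
            raise ValueError("scan_duration required when there is no raster")

    @property
    def gradient_matrix(self) -> np.ndarray:
        g = self.gradient
        return np.diag([-g, 0.0, g])

    @property
    def duration(self) -> float:
        if self.scan_duration is not None:
            return self.scan_duration
        return self.raster.duration

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sample_rate))

    def time_samples(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    @property
    def drive_excursion(self) -> float:
        """Peak FFL displacement due to the drive field, A/G0 (metres)."""
        return self.drive_amplitude / self.gradient

    @property
    def sensitivity_vector(self) -> np.ndarray:
        if self.receive_sensitivity is not None:
            return np.asarray(self.receive_sensitivity, dtype=float)
        b = np.zeros(3)
        b[_AXIS_INDEX[self.drive_axis]] = 1.0
        return b

    def to_dict(self) -> dict:
        d = {
            "gradient_T_per_m": self.gradient,
            "drive_amplitude_T": self.drive_amplitude,
            "drive_frequency_Hz": self.drive_frequency,
            "drive_axis": self.drive_axis,
            "fov_m": list(self.fov),
            "sample_rate_Hz": self.sample_rate,
            "notch_halfwidth_Hz": self.notch_halfwidth,
            "max_harmonic": self.max_harmonic,
        }
        if self.raster is not None:
            d["raster"] = {
                "n_lines": self.raster.n_lines,
                "line_period_s": self.raster.line_period,
                "x_extent_m": self.raster.x_extent,
                "z_extent_m": self.raster.z_extent,
            }
        if self.scan_duration is not None:
            d["scan_duration_s"] = self.scan_duration
        if self.receive_sensitivity is not None:
            d["receive_sensitivity"] = list(self.receive_sensitivity)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScannerModel":
        raster = None
        if "raster" in d:
            r = d["raster"]
            raster = RasterSpec(
                n_lines=int(r["n_lines"]),
                line_period=float(r["line_period_s"]),
                x_extent=float(r["x_extent_m"]),
                z_extent=float(r["z_extent_m"]),
            )
        return cls(
            gradient=float(d["gradient_T_per_m"]),
            drive_amplitude=float(d["drive_amplitude_T"]),
            drive_frequency=float(d["drive_frequency_Hz"]),
            drive_axis=str(d["drive_axis"]),
            fov=tuple(float(v) for v in d["fov_m"]),
            raster=raster,
            sample_rate=float(d["sample_rate_Hz"]),
            notch_halfwidth=float(d.get("notch_halfwidth_Hz", 1e3)),
            receive_sensitivity=(
                tuple(float(v) for v in d["receive_sensitivity"])
                if "receive_sensitivity" in d
                else None
            ),
            max_harmonic=int(d.get("max_harmonic", 5)),
            scan_duration=(
                float(d["scan_duration_s"]) if "scan_duration_s" in d else None
            ),
        )


@dataclass(frozen=True)
class ParticleModel:
    """Langevin nanoparticle ensemble: a single magnetic moment per
    particle and the saturation constant of its equilibrium response.

    ``moment`` is the magnetic moment of one particle (A m^2); ``beta``
    (1/T) multiplies the field magnitude (as mu0*H) inside the Langevin
    function.  For a thermal ensemble ``beta = moment / (kB * T)``.
    The defaults describe a multicore tracer with a ~30 nm equivalent
    magnetite core (m = Ms * pi/6 * d^3 ~ 5.3e-18 A m^2 at
    Ms = 350 kA/m), giving beta = m / (kB * 300 K) ~ 1280 /T and a
    sub-millimetre point spread at a 5.7 T/m gradient.
    """

    moment: float = 5.3e-18
    beta: float = 1280.0

    def __post_init__(self) -> None:
        if self.moment <= 0 or self.beta <= 0:
            raise ValueError("particle moment and beta must be positive")

    def to_dict(self) -> dict:
        return {"magnetic_moment_Am2": self.moment, "beta_per_T": self.beta}

    @classmethod
    def from_dict(cls, d: dict) -> "ParticleModel":
        return cls(moment=float(d["magnetic_moment_Am2"]), beta=float(d["beta_per_T"]))


# ---------------------------------------------------------------------------
# Langevin function and derivatives
# ---------------------------------------------------------------------------

_SERIES_CUT = 1e-3
_DERIV_SERIES_CUT = 1e-2


def langevin(a):
    """Langevin function L(a) = coth(a) - 1/a, odd, saturating at 1.

    A Taylor series ``a/3 - a^3/45`` is used for |a| < 1e-3 where the
    closed form loses precision to cancellation (series truncation error
    there is ~6e-15 relative, below the cancellation error).
    """
    a = np.asarray(a, dtype=float)
    small = np.abs(a) < _SERIES_CUT
    safe = np.where(small, 1.0, a)
    closed = 1.0 / np.tanh(safe) - 1.0 / safe
    series = a / 3.0 - a**3 / 45.0
    out = np.where(small, series, closed)
    return out if out.ndim else float(out)


def langevin_derivative(a):
    """L'(a) = 1/a^2 - 1/sinh(a)^2; L'(0) = 1/3; positive and decreasing."""
    a = np.asarray(a, dtype=float)
    small = np.abs(a) < _DERIV_SERIES_CUT
    safe = np.where(small, 1.0, a)
    with np.errstate(over="ignore"):  # sinh overflow -> 1/inf^2 = 0, exact
        closed = 1.0 / safe**2 - 1.0 / np.sinh(safe) ** 2
    series = 1.0 / 3.0 - a**2 / 15.0 + 2.0 * a**4 / 189.0
    out = np.where(small, series, closed)
    return out if out.ndim else float(out)


def langevin_over_argument(a):
    """L(a)/a, the isotropic susceptibility factor; equals 1/3 at a = 0."""
    a = np.asarray(a, dtype=float)
    small = np.abs(a) < _SERIES_CUT
    safe = np.where(small, 1.0, a)
    closed = (1.0 / np.tanh(safe) - 1.0 / safe) / safe
    series = 1.0 / 3.0 - a**2 / 45.0
    out = np.where(small, series, closed)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Trajectory and fields
# ---------------------------------------------------------------------------

def ffl_position(model: ScannerModel, t) -> np.ndarray:
    """FFL intersection with the (x, z) plane at time ``t``.

    Returns an array of shape (2,) for scalar ``t`` or (2, n) for a time
    vector, ordered (x, z).  The drive displaces the FFL along the drive
    axis by ``(A/G0) sin(2 pi f0 t)``; the raster adds the slow shift.
    """
    t = np.asarray(t, dtype=float)
    d = model.drive_excursion * np.sin(2 * np.pi * model.drive_frequency * t)
    x = np.zeros_like(t)
    z = np.zeros_like(t)
    if model.drive_axis == "x":
        x = x + d
    else:
        z = z + d
    if model.raster is not None:
        rx, rz = model.raster.position(t)
        x = x + rx
        z = z + rz
    return np.stack([x, z])


def ffl_velocity(model: ScannerModel, t) -> np.ndarray:
    """Analytic time derivative of :func:`ffl_position`, shape (2,) or (2, n)."""
    t = np.asarray(t, dtype=float)
    omega = 2 * np.pi * model.drive_frequency
    d = model.drive_excursion * omega * np.cos(omega * t)
    vx = np.zeros_like(t)
    vz = np.zeros_like(t)
    if model.drive_axis == "x":
        vx = vx + d
    else:
        vz = vz + d
    if model.raster is not None:
        rvx, rvz = model.raster.velocity(t)
        vx = vx + rvx
        vz = vz + rvz
    return np.stack([vx, vz])


def _check_time(model: ScannerModel, t) -> None:
    t = np.asarray(t, dtype=float)
    eps = 1e-12
    if np.any(t < -eps) or np.any(t > model.duration + eps):
        raise ValueError(
            f"time outside scan duration [0, {model.duration:g}] s"
        )


def drive_field(model: ScannerModel, t) -> np.ndarray:
    """Total applied homogeneous field H_D(t) = G xi(t) (tesla, as mu0*H).

    Includes both the sinusoidal drive and the slow raster shift field;
    it has no y component, so the FFL sweeps within (x, z) planes.
    """
    xi = ffl_position(model, t)
    g = model.gradient
    return np.stack([-g * xi[0], np.zeros_like(xi[0]), g * xi[1]])


def magnetic_field(model: ScannerModel, x, t) -> np.ndarray:
    """Total field ``H(x, t) = G (xi(t) - x)`` at position ``x`` (tesla).

    ``x`` is a 3-vector (metres).  The y component is always zero since
    the gradient matrix has a null middle row.  Raises for ``t`` outside
    the scan duration.
    """
    _check_time(model, t)
    x = np.asarray(x, dtype=float)
    xi = ffl_position(model, t)
    g = model.gradient
    hx = -g * (xi[0] - x[0])
    hz = g * (xi[1] - x[2])
    return np.stack([hx, np.zeros_like(hx), hz])


# ---------------------------------------------------------------------------
# Point-spread tensor
# ---------------------------------------------------------------------------

def _jacobian_terms(w_norm: np.ndarray, beta: float):
    """Isotropic and radial coefficients of the Langevin Jacobian.

    For w = field vector, the Jacobian of ``L(beta |w|) w/|w|`` w.r.t. w
    is ``iso * (I - ww^T/|w|^2) + rad * ww^T/|w|^2`` with
    ``iso = L(a)/|w| = beta * L(a)/a`` and ``rad = beta * L'(a)``,
    ``a = beta |w|``.  Both tend to ``beta/3`` as w -> 0.
    """
    a = beta * w_norm
    iso = beta * langevin_over_argument(a)
    rad = beta * langevin_derivative(a)
    return np.asarray(iso), np.asarray(rad)


def psf_tensor(model: ScannerModel, particle: ParticleModel, u) -> np.ndarray:
    """Point-spread tensor h(u) of the Langevin response, shape (3, 3).

    ``u`` is the offset (metres) from the FFL to the source point.  With
    ``w = G u`` the tensor is ``h(u) = J(w) G`` where ``J`` is the
    Jacobian of the Langevin magnetization direction-magnitude product
    with respect to the field.  Rows and columns along the FFL axis (y)
    vanish because G has a zero middle row/column; at u = 0 the
    isotropic limit gives ``h = (beta/3) G``.
    """
    u = np.asarray(u, dtype=float)
    G = model.gradient_matrix
    w = G @ u
    wn = np.linalg.norm(w)
    iso, rad = _jacobian_terms(np.asarray(wn), particle.beta)
    if wn == 0:
        J = float(iso) * np.eye(3)
    else:
        what = w / wn
        P = np.outer(what, what)
        J = float(iso) * (np.eye(3) - P) + float(rad) * P
    return J @ G


def psf_tensor_grid(model: ScannerModel, particle: ParticleModel,
                    ux: np.ndarray, uz: np.ndarray) -> np.ndarray:
    """Vectorized :func:`psf_tensor` over offsets ``(ux, 0, uz)``.

    ``ux`` and ``uz`` are broadcastable offset arrays (metres); returns
    an array of shape (3, 3) + broadcast shape.  Only the four (x, z)
    components are nonzero for the FFL gradient.
    """
    ux, uz = np.broadcast_arrays(np.asarray(ux, float), np.asarray(uz, float))
    g = model.gradient
    wx = -g * ux
    wz = g * uz
    wn = np.hypot(wx, wz)
    iso, rad = _jacobian_terms(wn, particle.beta)
    with np.errstate(invalid="ignore", divide="ignore"):
        nx = np.where(wn > 0, wx / np.where(wn > 0, wn, 1.0), 0.0)
        nz = np.where(wn > 0, wz / np.where(wn > 0, wn, 1.0), 0.0)
    diff = rad - iso
    J_xx = iso + diff * nx * nx
    J_zz = iso + diff * nz * nz
    J_xz = diff * nx * nz
    h = np.zeros((3, 3) + wn.shape)
    h[0, 0] = -g * J_xx   # J_xx * G_xx
    h[0, 2] = g * J_xz    # J_xz * G_zz
    h[2, 0] = -g * J_xz   # J_zx * G_xx
    h[2, 2] = g * J_zz    # J_zz * G_zz
    return h
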