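"""Persistence: HDF5 signal/harmonic containers, NIfTI volumes, YAML configs.

The HDF5 container stores one group per scan ("scan_000", ...) with the
raw time-domain samples and/or the compressed harmonic coefficients,
tagged with the projection angle and drive axis.  The compression
layout (K, bandwidth, band bin indices) is stored inside the container
so a reconstruction can never silently mismatch the band layout of the
data.  Round-trips are bit-exact.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import yaml

from .grids import ImageGrid
from .operators import HarmonicBlock, TimeSignal
from .scanner import ParticleModel, ScannerModel

__all__ = [
    "SCHEMA_VERSION",
    "write_container",
    "read_container",
    "write_volume",
    "read_volume",
    "write_projection_stack",
    "read_projection_stack",
    "save_scanner_config",
    "load_scanner_config",
    "save_particle_config",
    "load_particle_config",
]

SCHEMA_VERSION = 1


class ContainerError(RuntimeError):
    pass


def write_container(path, signals: list[TimeSignal] | None = None,
                    blocks: list[HarmonicBlock] | None = None) -> None:
    """Write scans to an HDF5 container.

    ``signals`` and ``blocks`` are parallel lists (either may be None);
    when both are given they must describe the same scans in the same
    order.
    """
    signals = signals or []
    blocks = blocks or []
    n = max(len(signals), len(blocks))
    if signals and blocks and len(signals) != len(blocks):
        raise ValueError("signals and blocks must describe the same scans")
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["n_scans"] = n
        for i in range(n):
            g = f.create_group(f"scan_{i:03d}")
            sig = signals[i] if signals else None
            blk = blocks[i] if blocks else None
            ref = sig or blk
            if ref.angle is not None:
                g.attrs["angle_deg"] = float(ref.angle)
            if ref.drive_axis is not None:
                g.attrs["drive_axis"] = str(ref.drive_axis)
            if sig is not None:
                d = g.create_dataset("raw", data=np.asarray(sig.samples))
                d.attrs["sample_rate_Hz"] = sig.sample_rate
            if blk is not None:
                d = g.create_dataset("coeffs",
                                     data=np.asarray(blk.coefficients, complex))
                d.attrs["f0_Hz"] = blk.f0
                d.attrs["sample_rate_Hz"] = blk.sample_rate
                d.attrs["n_samples"] = blk.n_samples
                d.attrs["K"] = blk.K
                d.attrs["bandwidth_Hz"] = blk.bandwidth
                idx = np.concatenate([blk.band_index_map[k]
                                      for k in sorted(blk.band_index_map)])
                ks = np.concatenate([np.full(blk.band_index_map[k].size, k)
                                     for k in sorted(blk.band_index_map)])
                g.create_dataset("band_indices", data=idx.astype(np.int64))
                g.create_dataset("band_harmonics", data=ks.astype(np.int64))


def read_container(path) -> tuple[list[TimeSignal], list[HarmonicBlock]]:
    """Read a container; returns (signals, blocks), each possibly empty."""
    signals: list[TimeSignal] = []
    blocks: list[HarmonicBlock] = []
    with h5py.File(path, "r") as f:
        version = f.attrs.get("schema_version")
        if version is None:
            raise ContainerError("not an fflmpi container: missing schema_version")
        if int(version) != SCHEMA_VERSION:
            raise ContainerError(
                f"unsupported container schema version {version} "
                f"(supported: {SCHEMA_VERSION})"
            )
        names = sorted(k for k in f.keys() if k.startswith("scan_"))
        for name in names:
            g = f[name]
            angle = float(g.attrs["angle_deg"]) if "angle_deg" in g.attrs else None
            axis = str(g.attrs["drive_axis"]) if "drive_axis" in g.attrs else None
            if "raw" in g:
                d = g["raw"]
                signals.append(TimeSignal(d[()], float(d.attrs["sample_rate_Hz"]),
                                          drive_axis=axis, angle=angle))
            if "coeffs" in g:
                if "band_indices" not in g or "band_harmonics" not in g:
                    missing = ("band_indices" if "band_indices" not in g
                               else "band_harmonics")
                    raise ContainerError(
                        f"{name}: compressed data without its band layout "
                        f"(missing dataset '{missing}')"
                    )
                d = g["coeffs"]
                idx = g["band_indices"][()]
                ks = g["band_harmonics"][()]
                band_map = {int(k): idx[ks == k] for k in np.unique(ks)}
                blocks.append(HarmonicBlock(
                    coefficients=d[()],
                    band_index_map=band_map,
                    f0=float(d.attrs["f0_Hz"]),
                    sample_rate=float(d.attrs["sample_rate_Hz"]),
                    n_samples=int(d.attrs["n_samples"]),
                    K=int(d.attrs["K"]),
                    bandwidth=float(d.attrs["bandwidth_Hz"]),
                    drive_axis=axis, angle=angle,
                ))
    return signals, blocks


# ---------------------------------------------------------------------------
# NIfTI volumes
# ---------------------------------------------------------------------------

def write_volume(path, volume: np.ndarray, grid: ImageGrid) -> None:
    """Write a volume as NIfTI with spacing in mm and the grid centered
    on the origin (cell-centered, RAS-like axis order x, y, z)."""
    volume = np.asarray(volume)
    if volume.shape != grid.shape:
        raise ValueError("volume shape does not match grid")
    spacing_mm = np.asarray(grid.spacing) * 1e3
    affine = np.eye(4)
    for i, (n, d) in enumerate(zip(grid.shape, spacing_mm)):
        affine[i, i] = d
        affine[i, 3] = -(n - 1) / 2.0 * d
    img = nib.Nifti1Image(volume, affine)
    img.header.set_zooms(tuple(spacing_mm))
    nib.save(img, str(path))


def read_volume(path) -> tuple[np.ndarray, ImageGrid]:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"volume file not found: {p}")
    img = nib.load(str(p))
    data = np.asarray(img.dataobj)
    zooms = img.header.get_zooms()[:data.ndim]
    grid = ImageGrid(tuple(data.shape), tuple(float(z) * 1e-3 for z in zooms))
    return data, grid


def write_projection_stack(path, stack: np.ndarray, grid2d: ImageGrid,
                           angles) -> None:
    """Write per-angle 2D projections as a NIfTI (x', z, angle) with the
    projection angles in a JSON sidecar next to the image file."""
    import json
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] != len(tuple(angles)):
        raise ValueError("stack must be (n_angles, nx, nz)")
    vol = np.moveaxis(stack, 0, -1)  # (nx, nz, angle)
    grid3 = ImageGrid(vol.shape, grid2d.spacing + (1e-3,))
    write_volume(path, vol, grid3)
    sidecar = Path(str(path)).with_suffix("").with_suffix("")  # strip .nii.gz
    Path(str(sidecar) + ".json").write_text(
        json.dumps({"angles_deg": [float(a) for a in angles]}))


def read_projection_stack(path) -> tuple[np.ndarray, ImageGrid, list[float]]:
    import json
    vol, grid3 = read_volume(path)
    sidecar = Path(str(path)).with_suffix("").with_suffix("")
    meta = json.loads(Path(str(sidecar) + ".json").read_text())
    stack = np.moveaxis(vol, -1, 0)
    grid2d = ImageGrid(vol.shape[:2], grid3.spacing[:2])
    return stack, grid2d, [float(a) for a in meta["angles_deg"]]


# ---------------------------------------------------------------------------
# YAML configs
# ---------------------------------------------------------------------------

def save_scanner_config(path, scanner: ScannerModel) -> None:
    Path(path).write_text(yaml.safe_dump(scanner.to_dict(), sort_keys=False))


def load_scanner_config(path) -> ScannerModel:
    return ScannerModel.from_dict(yaml.safe_load(Path(path).read_text()))


def save_particle_config(path, particle: ParticleModel) -> None:
    Path(path).write_text(yaml.safe_dump(particle.to_dict(), sort_keys=False))


def load_particle_config(path) -> ParticleModel:
    return ParticleModel.from_dict(yaml.safe_load(Path(path).read_text()))
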