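"""Image-stack I/O and two-point hydroxyapatite-phantom calibration.

MicroCT scanners report X-ray attenuation on an arbitrary grayscale.  Scanning
two cylinders of known calcium-hydroxyapatite (CaHA) density alongside the
specimen pins that scale down: the unique affine map sending the two phantom
mean intensities to the two known densities converts every voxel to
hydroxyapatite-equivalent mineral density (g/cm^3 CaHA).

Volumes are indexed ``(slice, row, col)``; slice index 0 is the proximal end
of the digit and the last slice is distal.  Physical coordinates are voxel
centres times the isotropic voxel size in micrometres.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
import imageio.v3 as iio

__all__ = [
    "ImageVolume",
    "CalibrationModel",
    "read_stack",
    "write_stack",
    "fit_calibration",
    "apply_calibration",
]

#: default phantom densities, g/cm^3 CaHA
DEFAULT_PHANTOM_DENSITIES = (0.25, 0.75)

_SLICE_EXTENSIONS = (".tif", ".tiff", ".png")
_SIDECAR_NAME = "voxel_size.json"


@dataclass
class ImageVolume:
    """A 3D grayscale microCT volume with isotropic voxel size.

    Parameters
    ----------
    data
        3D array ``(slice, row, col)`` of nonnegative intensities (or, after
        calibration, densities in g/cm^3).
    voxel_size_um
        Isotropic voxel edge length in micrometres.
    """

    data: np.ndarray
    voxel_size_um: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        if min(self.data.shape) < 1:
            raise ValueError(f"all dimensions must be >= 1, got {self.data.shape}")
        if not self.voxel_size_um > 0:
            raise ValueError(f"voxel_size_um must be positive, got {self.voxel_size_um}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]


@dataclass
class CalibrationModel:
    """Affine intensity -> density map fixed by two phantom scans.

    ``density = slope * intensity + intercept``.  By construction the model
    reproduces the two source densities exactly at the two source means.
    """

    slope: float
    intercept: float
    source_means: tuple[float, float] = field(default=(np.nan, np.nan))
    source_densities: tuple[float, float] = field(default=(np.nan, np.nan))

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("calibration slope must be nonzero")

    def __call__(self, intensity: np.ndarray | float) -> np.ndarray | float:
        return self.slope * np.asarray(intensity, dtype=float) + self.intercept


def _natural_key(name: str) -> list:
    return [int(tok) if tok.isdigit() else tok for tok in re.split(r"(\d+)", name)]


def read_stack(path: str | Path, voxel_size_um: float | None = None) -> ImageVolume:
    """Assemble an :class:`ImageVolume` from a slice directory or stack file.

    ``path`` may be a directory of TIFF/PNG slices (lexicographic order
    defines the proximal->distal axis) or a multi-page TIFF.  The voxel size
    is taken from ``voxel_size_um`` if given, otherwise from a
    ``voxel_size.json`` sidecar next to the slices.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            (p for p in path.iterdir() if p.suffix.lower() in _SLICE_EXTENSIONS),
            key=lambda p: _natural_key(p.name),
        )
        if not files:
            raise ValueError(f"no image slices found in {path}")
        slices = []
        for f in files:
            img = tifffile.imread(f) if f.suffix.lower() in (".tif", ".tiff") else iio.imread(f)
            img = np.asarray(img)
            if img.ndim != 2:
                raise ValueError(f"slice {f.name} is not 2D (shape {img.shape})")
            slices.append(img)
        shapes = {s.shape for s in slices}
        if len(shapes) != 1:
            raise ValueError(f"mixed slice dimensions in {path}: {sorted(shapes)}")
        data = np.stack(slices, axis=0)
        sidecar = path / _SIDECAR_NAME
    elif path.is_file():
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        sidecar = path.with_suffix(".json")
    else:
        raise FileNotFoundError(path)

    if voxel_size_um is None:
        if sidecar.exists():
            voxel_size_um = float(json.loads(sidecar.read_text())["voxel_size_um"])
        else:
            raise ValueError(
                f"voxel size unknown for {path}: pass voxel_size_um or provide a "
                f"{_SIDECAR_NAME} sidecar"
            )
    return ImageVolume(data=data, voxel_size_um=voxel_size_um)


def write_stack(volume: ImageVolume, path: str | Path) -> list[Path]:
    """Write a volume as a zero-padded TIFF slice sequence plus sidecar.

    Integer volumes are written with their own dtype; floating-point volumes
    are written as float32 TIFF.  Both round-trip losslessly through
    :func:`read_stack` (float data must be float32-representable).
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    data = volume.data
    if np.issubdtype(data.dtype, np.floating):
        data = data.astype(np.float32)
    width = max(4, len(str(volume.n_slices - 1)))
    written = []
    for i in range(volume.n_slices):
        f = path / f"slice_{i:0{width}d}.tif"
        tifffile.imwrite(f, data[i])
        written.append(f)
    (path / _SIDECAR_NAME).write_text(
        json.dumps({"voxel_size_um": volume.voxel_size_um}, sort_keys=True)
    )
    return written


def _central_roi_mask(shape: tuple[int, int, int], roi_fraction: float) -> np.ndarray:
    """Central cylindrical ROI: ``roi_fraction`` of the half-width in radius,
    central 80% of slices axially."""
    nz, ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    radius = roi_fraction * (min(ny, nx) / 2.0)
    disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    mask = np.zeros(shape, dtype=bool)
    z0, z1 = int(round(0.1 * nz)), max(int(round(0.9 * nz)), 1)
    mask[z0:z1] = disc
    return mask


def fit_calibration(
    phantom_low: ImageVolume,
    phantom_high: ImageVolume,
    densities: Sequence[float] = DEFAULT_PHANTOM_DENSITIES,
    roi_fraction: float = 0.8,
) -> CalibrationModel:
    """Fit the two-point affine intensity -> density calibration.

    The mean intensity within a central cylindrical ROI of each homogeneous
    phantom scan is mapped onto the corresponding known CaHA density.  With
    exactly two phantoms the affine interpolant is unique; no regression is
    involved.
    """
    d_low, d_high = float(densities[0]), float(densities[1])
    if d_low == d_high:
        raise ValueError("phantom densities must be distinct")
    if d_low < 0 or d_high < 0:
        raise ValueError("phantom densities must be nonnegative")
    means = []
    for vol in (phantom_low, phantom_high):
        roi = _central_roi_mask(vol.shape, roi_fraction)
        means.append(float(vol.data[roi].mean()))
    m_low, m_high = means
    if m_low == m_high:
        raise ValueError(
            "phantom mean intensities are equal; two-point calibration is degenerate"
        )
    slope = (d_high - d_low) / (m_high - m_low)
    intercept = d_low - slope * m_low
    return CalibrationModel(
        slope=slope,
        intercept=intercept,
        source_means=(m_low, m_high),
        source_densities=(d_low, d_high),
    )


def apply_calibration(
    volume: ImageVolume, model: CalibrationModel, clamp_negative: bool = True
) -> ImageVolume:
    """Convert a grayscale volume to per-voxel density (g/cm^3 CaHA).

    Air and soft tissue can calibrate to slightly negative densities; these
    are physically meaningless and clamped to zero by default.
    """
    density = model(volume.data.astype(float))
    if clamp_negative:
        density = np.maximum(density, 0.0)
    return ImageVolume(data=density, voxel_size_um=volume.voxel_size_um)
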