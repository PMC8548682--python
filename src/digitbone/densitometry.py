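"""Block-averaged bone mineral density: coarse-graining, masking, sampling,
kernel density summaries, and heatmap export.

The calibrated per-voxel density volume is coarse-grained into L^3 blocks
(L = 3 by default), each carrying the mean density of its member voxels —
the representative data points used for all downstream density and modulus
statistics.  A bone mask restricts analysis to mineralised blocks, and
per-digit random subsamples (2,000 values by default) feed the cohort-level
distribution comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import gaussian_kde
from skimage.measure import block_reduce

from digitbone.microct_io import ImageVolume

__all__ = [
    "DensityVolume",
    "DensitySample",
    "block_average",
    "compute_bone_mask",
    "sample_density",
    "density_kde",
    "export_density_heatmap",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class DensityVolume:
    """Per-block hydroxyapatite-equivalent density with an optional bone mask."""

    block_density: np.ndarray
    L: int
    voxel_size_um: float
    bone_mask: np.ndarray | None = None
    threshold: float | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bone_mask is not None and self.bone_mask.shape != self.block_density.shape:
            raise ValueError("bone_mask shape must match block_density shape")

    @property
    def masked_values(self) -> np.ndarray:
        if self.bone_mask is None:
            raise ValueError("no bone mask set; run compute_bone_mask first")
        return self.block_density[self.bone_mask]


@dataclass
class DensitySample:
    """Random subsample of masked block densities for one digit."""

    values: np.ndarray
    digit: str = ""
    mouse: str = ""
    status: str = ""
    age_group: str = ""
    seed: int | None = None


def block_average(
    volume: ImageVolume | np.ndarray,
    L: int = 3,
    voxel_size_um: float | None = None,
    provenance: dict | None = None,
) -> DensityVolume:
    """Coarse-grain a per-voxel density volume into L x L x L block means.

    Blocks are non-overlapping; edge blocks smaller than L are averaged over
    the voxels they actually contain (discarding them would bias the distal
    tip, the region of interest).  ``L = 1`` returns the input unchanged.
    """
    if isinstance(volume, ImageVolume):
        data = volume.data.astype(float)
        voxel_size_um = volume.voxel_size_um
    else:
        data = np.asarray(volume, dtype=float)
        if voxel_size_um is None:
            voxel_size_um = 1.0
    if L < 1:
        raise ValueError("block edge L must be >= 1")
    if L > max(data.shape):
        raise ValueError(f"L={L} exceeds every volume dimension {data.shape}")
    if L == 1:
        blocks = data.copy()
    else:
        sums = block_reduce(data, (L, L, L), np.sum, cval=0.0)
        counts = block_reduce(np.ones_like(data), (L, L, L), np.sum, cval=0.0)
        blocks = sums / counts
    return DensityVolume(
        block_density=blocks,
        L=L,
        voxel_size_um=float(voxel_size_um),
        provenance=dict(provenance or {}),
    )


def compute_bone_mask(
    blocks: DensityVolume,
    threshold_g_cm3: float = 0.15,
    keep_largest_component: bool = True,
) -> DensityVolume:
    """Mask blocks at or above the density threshold as bone.

    Optionally retains only the largest 26-connected component, dropping
    disconnected noise blocks.  An empty mask warns rather than errors so a
    cohort run can report the digit as failed downstream.
    """
    if threshold_g_cm3 < 0:
        raise ValueError("bone threshold must be nonnegative")
    mask = blocks.block_density >= threshold_g_cm3
    if keep_largest_component and mask.any():
        labels, n = ndimage.label(mask, structure=_CONN26)
        if n > 1:
            sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
            mask = labels == (int(np.argmax(sizes)) + 1)
    if not mask.any():
        warnings.warn(
            f"bone mask is empty at threshold {threshold_g_cm3} g/cm^3", stacklevel=2
        )
    return DensityVolume(
        block_density=blocks.block_density,
        L=blocks.L,
        voxel_size_um=blocks.voxel_size_um,
        bone_mask=mask,
        threshold=threshold_g_cm3,
        provenance=dict(blocks.provenance),
    )


def sample_density(
    blocks: DensityVolume, n: int = 2000, seed: int = 0, **labels: str
) -> DensitySample:
    """Uniform random sample of n masked block densities (one digit).

    Sampling is without replacement; if the mask holds fewer than n blocks
    the full set is resampled with replacement, with a warning.
    """
    if n < 1:
        raise ValueError("sample size must be >= 1")
    values = blocks.masked_values
    if values.size == 0:
        raise ValueError("cannot sample from an empty bone mask")
    rng = np.random.default_rng(seed)
    replace = n > values.size
    if replace:
        warnings.warn(
            f"requested {n} values but mask holds {values.size}; "
            "sampling with replacement",
            stacklevel=2,
        )
    picked = rng.choice(values, size=n, replace=replace)
    return DensitySample(values=picked, seed=seed, **labels)


def density_kde(
    samples: list[DensitySample],
    bandwidth_rule: str | float = "silverman",
    grid_points: int = 512,
    grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Pooled Gaussian kernel density estimate of one group of digits.

    Values from all samples are pooled; the KDE is tabulated on a shared grid
    (padded past the data range so the curve integrates to ~1).  Pass an
    explicit ``grid`` to compare several groups on identical support.
    """
    if not samples:
        raise ValueError("need at least one density sample")
    pooled = np.concatenate([np.asarray(s.values, dtype=float) for s in samples])
    spread = pooled.std()
    if spread == 0:
        warnings.warn(
            "all pooled values identical; falling back to minimum bandwidth",
            stacklevel=2,
        )
        center = pooled[0]
        bw = max(1e-3, 1e-3 * max(abs(center), 1.0))
        if grid is None:
            grid = np.linspace(center - 6 * bw, center + 6 * bw, grid_points)
        dens = np.exp(-0.5 * ((grid - center) / bw) ** 2) / (bw * np.sqrt(2 * np.pi))
        return pd.DataFrame({"density_value": grid, "kde": dens})
    kde = gaussian_kde(pooled, bw_method=bandwidth_rule)
    if grid is None:
        bw = kde.factor * spread
        lo, hi = pooled.min() - 5 * bw, pooled.max() + 5 * bw
        grid = np.linspace(lo, hi, grid_points)
    return pd.DataFrame({"density_value": grid, "kde": kde(grid)})


def export_density_heatmap(
    blocks: DensityVolume,
    path,
    plane: int | None = None,
    axis: int = 1,
    colormap_range: tuple[float, float] | None = None,
    cmap: str = "inferno",
) -> None:
    """Write a colorized cross-sectional density slice with a colour bar.

    ``colormap_range`` fixes the density -> colour scale; share one range
    across digits so identical densities render identically.  ``axis=1``
    gives the sagittal-style longitudinal section; ``axis=0`` a transverse
    slice.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    data = blocks.block_density
    if plane is None:
        plane = data.shape[axis] // 2
    if not (0 <= plane < data.shape[axis]):
        raise ValueError(f"plane {plane} out of range for axis {axis} (size {data.shape[axis]})")
    sl = np.take(data, plane, axis=axis)
    vmin, vmax = colormap_range if colormap_range else (0.0, float(data.max()))
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(sl.T if axis != 0 else sl, cmap=cmap, vmin=vmin, vmax=vmax,
                   origin="lower", interpolation="nearest")
    fig.colorbar(im, ax=ax, label="mineral density (g/cm$^3$ CaHA)")
    ax.set_title(blocks.provenance.get("digit", "density map"))
    ax.set_xlabel("proximal → distal" if axis != 0 else "x")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
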