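"""Elasticity computations: Oliver-Pharr conversion, the density-modulus
power law, and proximal-distal modulus profiling.

Two independent routes to elasticity are implemented:

* measurement side — nanoindentation reports a *reduced* modulus ``E_r``
  combining sample and indenter compliance; Young's modulus of the bone is
  recovered from the Oliver-Pharr relation

      1/E_r = (1 - nu^2)/E + (1 - nu_i^2)/E_i

  with nu = 0.3 for bone and a diamond Berkovich indenter
  (E_i = 1141 GPa, nu_i = 0.07);

* prediction side — microCT-calibrated hydroxyapatite-equivalent density is
  mapped to elastic modulus through the quantitative-CT power law

      rho_ash = 0.8772 * rho_HA + 0.0789
      E       = 10200 * rho_ash ** 2.01

  evaluated per coarse-grained block, giving a full-volume modulus map that
  physical indentation of a tiny, irregular bone cannot provide.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from digitbone.densitometry import DensityVolume

__all__ = [
    "IndenterParams",
    "MaterialParams",
    "DensityModulusParams",
    "ModulusVolume",
    "AxialProfile",
    "reduced_to_youngs",
    "youngs_to_reduced",
    "ash_density",
    "density_to_modulus",
    "modulus_volume",
    "axial_profile",
    "split_regions",
]


@dataclass
class IndenterParams:
    """Elastic constants of the indenter tip (diamond Berkovich defaults)."""

    E_i: float = 1141.0  # GPa
    nu_i: float = 0.07

    def __post_init__(self) -> None:
        if self.E_i <= 0:
            raise ValueError("indenter modulus must be positive")
        if not (0 <= self.nu_i < 0.5):
            raise ValueError("indenter Poisson ratio must lie in [0, 0.5)")


@dataclass
class MaterialParams:
    """Elastic constants of the indented material (bone default nu = 0.3)."""

    nu: float = 0.3

    def __post_init__(self) -> None:
        if not (0 <= self.nu < 0.5):
            raise ValueError("Poisson ratio must lie in [0, 0.5)")


@dataclass
class DensityModulusParams:
    """Coefficients of the density -> elasticity power law.

    The power law is evaluated in the coefficient's native units (read as
    MPa) and divided by ``output_divisor`` for reporting; the default 1000
    reports GPa.  ``ash_slope``/``ash_intercept`` convert
    hydroxyapatite-equivalent density to ash density (both g/cm^3).
    """

    coeff: float = 10200.0
    exponent: float = 2.01
    ash_slope: float = 0.8772
    ash_intercept: float = 0.0789
    output_divisor: float = 1000.0
    output_unit: str = "GPa"

    def __post_init__(self) -> None:
        if self.coeff <= 0 or self.exponent <= 0 or self.ash_slope <= 0:
            raise ValueError("coeff, exponent, and ash_slope must be positive")
        if self.output_divisor <= 0:
            raise ValueError("output_divisor must be positive")


@dataclass
class ModulusVolume:
    """Per-block predicted elastic modulus; NaN marks non-bone blocks."""

    block_modulus: np.ndarray
    bone_mask: np.ndarray
    L: int
    voxel_size_um: float
    unit: str = "GPa"
    provenance: dict = field(default_factory=dict)


@dataclass
class AxialProfile:
    """Modulus against normalized proximal->distal position, with a local
    polynomial regression smooth."""

    positions: np.ndarray  # in [0, 1], one per masked block
    values: np.ndarray
    grid: np.ndarray  # uniform evaluation grid in [0, 1]
    fitted: np.ndarray  # smooth evaluated on grid
    span: float
    degree: int


def reduced_to_youngs(
    E_r: np.ndarray | float,
    mat: MaterialParams | None = None,
    ind: IndenterParams | None = None,
) -> np.ndarray | float:
    """Young's modulus of the sample from nanoindentation reduced modulus.

    Inverts the Oliver-Pharr compliance sum.  The sample term
    ``1/E_r - (1 - nu_i^2)/E_i`` must stay positive: a reduced modulus at or
    beyond the indenter-corrected limit has no physical solution.
    """
    mat = mat or MaterialParams()
    ind = ind or IndenterParams()
    E_r = np.asarray(E_r, dtype=float)
    if np.any(E_r <= 0):
        raise ValueError("reduced modulus must be positive")
    indenter_term = (1.0 - ind.nu_i**2) / ind.E_i
    sample_term = 1.0 / E_r - indenter_term
    if np.any(sample_term <= 0):
        bad = float(np.max(E_r))
        raise ValueError(
            f"reduced modulus {bad:g} GPa is at or beyond the indenter-corrected "
            f"limit {1.0 / indenter_term:g} GPa; the Oliver-Pharr relation has no "
            "positive solution"
        )
    E = (1.0 - mat.nu**2) / sample_term
    return float(E) if E.ndim == 0 else E


def youngs_to_reduced(
    E: np.ndarray | float,
    mat: MaterialParams | None = None,
    ind: IndenterParams | None = None,
) -> np.ndarray | float:
    """Forward Oliver-Pharr map: sample Young's modulus -> reduced modulus."""
    mat = mat or MaterialParams()
    ind = ind or IndenterParams()
    E = np.asarray(E, dtype=float)
    if np.any(E <= 0):
        raise ValueError("Young's modulus must be positive")
    inv = (1.0 - mat.nu**2) / E + (1.0 - ind.nu_i**2) / ind.E_i
    E_r = 1.0 / inv
    return float(E_r) if E_r.ndim == 0 else E_r


def ash_density(
    rho_HA: np.ndarray | float, params: DensityModulusParams | None = None
) -> np.ndarray | float:
    """Ash density (g/cm^3) from hydroxyapatite-equivalent density."""
    params = params or DensityModulusParams()
    rho_HA = np.asarray(rho_HA, dtype=float)
    if np.any(rho_HA < 0):
        raise ValueError("hydroxyapatite-equivalent density must be nonnegative")
    rho_ash = params.ash_slope * rho_HA + params.ash_intercept
    return float(rho_ash) if rho_ash.ndim == 0 else rho_ash


def density_to_modulus(
    rho_HA: np.ndarray | float,
    params: DensityModulusParams | None = None,
    native_units: bool = False,
) -> np.ndarray | float:
    """Predicted elastic modulus from hydroxyapatite-equivalent density.

    With ``native_units=True`` the power law is returned in the coefficient's
    own units (MPa for the default coefficients); otherwise it is divided by
    ``params.output_divisor`` (default: report GPa).  Strictly increasing in
    ``rho_HA``.
    """
    params = params or DensityModulusParams()
    rho_ash = np.asarray(ash_density(rho_HA, params), dtype=float)
    E = params.coeff * rho_ash**params.exponent
    if not native_units:
        E = E / params.output_divisor
    return float(E) if E.ndim == 0 else E


def modulus_volume(
    blocks: "DensityVolume", params: DensityModulusParams | None = None
) -> ModulusVolume:
    """Apply the power law over the masked blocks of a density volume."""
    params = params or DensityModulusParams()
    if blocks.bone_mask is None:
        raise ValueError("density volume has no bone mask; run compute_bone_mask first")
    out = np.full(blocks.block_density.shape, np.nan)
    m = blocks.bone_mask
    out[m] = density_to_modulus(blocks.block_density[m], params)
    return ModulusVolume(
        block_modulus=out,
        bone_mask=m.copy(),
        L=blocks.L,
        voxel_size_um=blocks.voxel_size_um,
        unit=params.output_unit,
        provenance=dict(blocks.provenance),
    )


def _normalized_axial_positions(mask: np.ndarray) -> np.ndarray:
    """Per-masked-block position along axis 0, scaled so the most proximal
    masked slice is 0 and the most distal is 1."""
    zs = np.nonzero(mask)[0].astype(float)
    z_min, z_max = zs.min(), zs.max()
    if z_max == z_min:
        return np.zeros_like(zs)
    return (zs - z_min) / (z_max - z_min)


def local_polynomial_smooth(
    x: np.ndarray,
    y: np.ndarray,
    grid: np.ndarray,
    span: float = 0.33,
    degree: int = 2,
) -> np.ndarray:
    """LOESS-style local polynomial regression with tricube weights.

    For each grid point the ``ceil(span * n)`` nearest observations (by
    distance in x) receive tricube weights scaled by the window radius, and a
    weighted polynomial of the given degree is fitted and evaluated there.
    Windows shrink at the boundaries simply because the nearest-neighbour set
    is one-sided.  Degenerate windows (fewer distinct x than degree + 1)
    fall back to a lower degree.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if not (0 < span <= 1):
        raise ValueError("span must lie in (0, 1]")
    k = max(degree + 1, int(np.ceil(span * n)))
    k = min(k, n)
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    fitted = np.empty(grid.size)
    for j, x0 in enumerate(grid):
        # contiguous window of the k nearest x values around x0
        pos = np.searchsorted(xs, x0)
        lo = min(max(pos - k // 2, 0), n - k)
        hi = lo + k
        while lo > 0 and (x0 - xs[lo - 1]) < (xs[hi - 1] - x0):
            lo -= 1
            hi -= 1
        while hi < n and (xs[hi] - x0) < (x0 - xs[lo]):
            lo += 1
            hi += 1
        xw, yw = xs[lo:hi], ys[lo:hi]
        h = max(np.max(np.abs(xw - x0)), 1e-12)
        w = (1 - np.minimum(np.abs(xw - x0) / h, 1.0) ** 3) ** 3
        w = np.maximum(w, 1e-9)  # keep the boundary point from vanishing
        deg = min(degree, len(np.unique(xw)) - 1)
        V = np.vander(xw - x0, deg + 1, increasing=True)
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(V * sw[:, None], yw * sw, rcond=None)
        fitted[j] = beta[0]
    return fitted


def axial_profile(
    mod: ModulusVolume,
    span: float = 0.33,
    degree: int = 2,
    grid_points: int = 100,
) -> AxialProfile:
    """Proximal->distal modulus profile with a LOESS smooth (span 0.33).

    Every masked block contributes its modulus at its normalized slice
    coordinate; the local polynomial regression curve summarises the spatial
    trend the way the per-digit profile figures do.
    """
    mask = mod.bone_mask & np.isfinite(mod.block_modulus)
    n = int(mask.sum())
    if n < 10:
        raise ValueError(f"need at least 10 masked blocks for a profile, have {n}")
    positions = _normalized_axial_positions(mask)
    values = mod.block_modulus[mask]
    grid = np.linspace(0.0, 1.0, grid_points)
    fitted = local_polynomial_smooth(positions, values, grid, span=span, degree=degree)
    return AxialProfile(
        positions=positions, values=values, grid=grid, fitted=fitted,
        span=span, degree=degree,
    )


def split_regions(
    positions: np.ndarray, boundary_fraction: float = 0.5
) -> np.ndarray:
    """Label normalized positions as ``proximal`` (< boundary) or ``distal``.

    The anatomical amputation plane is unavailable for synthetic digits, so
    the boundary defaults to half the masked axial extent.
    """
    if not (0 < boundary_fraction < 1):
        raise ValueError("boundary_fraction must lie in (0, 1)")
    positions = np.asarray(positions, dtype=float)
    return np.where(positions < boundary_fraction, "proximal", "distal")
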