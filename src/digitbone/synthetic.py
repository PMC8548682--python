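"""Synthetic digit phantoms, calibration scans, and nanoindentation cohorts.

Every downstream stage of the pipeline is exercised against objects generated
here, with exact ground truth carried alongside:

* :func:`generate_digit_phantom` renders a conical P3-like bone — a tapering
  cortical shell, optionally a trabecular interior (regenerated, "D42"
  phantoms) or a solid cortical interior (unamputated, "UA" phantoms) — with
  tortuous internal channels emulating the vascular-like void spaces of
  regenerated bone.  The exact analytic centerline length of every channel is
  returned, so skeleton-length recovery can be scored against truth.
* :func:`generate_calibration_phantoms` renders the two homogeneous CaHA
  cylinders used for two-point density calibration.
* :func:`simulate_indentation_study` draws a hierarchical nanoindentation
  dataset (mouse / site-within-mouse / indent) with known fixed effects, so
  the mixed-model machinery can be validated by parameter recovery.

Rendering model: compartment density (g/cm^3 CaHA) -> affine grayscale
intensity -> Gaussian blur (partial-volume surrogate) -> additive Gaussian
noise.  With zero blur and zero noise the rendered intensity at each voxel is
exactly the affine model applied to the compartment density.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.ndimage import gaussian_filter

from digitbone.biomechanics import IndenterParams, MaterialParams, youngs_to_reduced
from digitbone.microct_io import ImageVolume, write_stack

__all__ = [
    "PhantomSpec",
    "PhantomGroundTruth",
    "IndentationEffects",
    "polyline_length",
    "generate_digit_phantom",
    "generate_straight_tube_phantom",
    "generate_calibration_phantoms",
    "simulate_indentation_study",
    "render_cohort",
]

# compartment labels in the ground-truth label volume
LABEL_BACKGROUND = 0
LABEL_CORTICAL = 1
LABEL_TRABECULAR = 2
LABEL_CHANNEL = 3


@dataclass
class PhantomSpec:
    """Geometry, density, and imaging parameters of a synthetic digit.

    Defaults emulate a distal mouse P3 scanned at 3.9 um isotropic voxels:
    a cone tapering from ``outer_radius_proximal`` to ``outer_radius_distal``
    over ``bone_length_voxels`` slices, a cortical shell of
    ``cortical_thickness_voxels``, and ``n_channels`` tortuous internal
    channels of radius ``channel_radius_voxels``.  Densities are
    hydroxyapatite-equivalent (g/cm^3 CaHA); mouse cortical tissue mineral
    density is ~1.0 and woven trabecular regenerate distinctly lower.
    ``age_density_shift`` is added to both bone compartments to emulate the
    aged-bone mineral-density increase.
    """

    bone_length_voxels: int = 100
    outer_radius_proximal: float = 24.0
    outer_radius_distal: float = 7.0
    cortical_thickness_voxels: int = 5
    n_channels: int = 3
    channel_radius_voxels: int = 2
    channel_tortuosity: float = 0.3
    density_cortical: float = 1.0
    density_trabecular: float = 0.6
    density_background: float = 0.0
    age_density_shift: float = 0.0
    blur_sigma_voxels: float = 0.0
    noise_sd: float = 0.0
    voxel_size_um: float = 3.9
    intensity_slope: float = 200.0  # intensity units per (g/cm^3)
    intensity_intercept: float = 10.0
    status: str = "D42"  # "UA": solid cortical interior; "D42": trabecular
    age_group: str = "18mo"
    seed: int = 0

    def validate(self) -> None:
        if self.bone_length_voxels < 8:
            raise ValueError("degenerate geometry: bone_length_voxels must be >= 8")
        if not (self.outer_radius_proximal >= self.outer_radius_distal > 0):
            raise ValueError("outer radius profile must taper proximal -> distal, both > 0")
        if not (self.outer_radius_distal > self.cortical_thickness_voxels > 0):
            raise ValueError("outer radius must exceed cortical thickness, which must be > 0")
        if self.n_channels > 0 and self.channel_radius_voxels >= self.cortical_thickness_voxels:
            raise ValueError(
                "channel radius must be smaller than the cortical thickness "
                "(a wider channel would breach the cortex)"
            )
        if min(self.density_cortical, self.density_trabecular, self.density_background) < 0:
            raise ValueError("densities must be nonnegative")
        if not (
            self.density_background < self.density_trabecular < self.density_cortical
        ):
            raise ValueError("require background < trabecular < cortical density")
        if self.channel_tortuosity < 0 or self.noise_sd < 0 or self.blur_sigma_voxels < 0:
            raise ValueError("tortuosity, noise_sd, blur_sigma must be nonnegative")
        if self.status not in ("UA", "D42"):
            raise ValueError(f"status must be 'UA' or 'D42', got {self.status!r}")


@dataclass
class PhantomGroundTruth:
    """Exact ground truth accompanying a rendered phantom."""

    channel_centerline_length_um: float
    channel_polylines: list[np.ndarray]  # each (n, 3) in voxel coordinates
    compartment_density: dict[int, float]  # label -> g/cm^3 CaHA
    label_volume: np.ndarray  # same shape as the rendered image
    intensity_slope: float
    intensity_intercept: float


@dataclass
class IndentationEffects:
    """Fixed effects and variance components of the indentation simulator.

    Units are GPa throughout.  ``region_effect`` is distal minus proximal,
    ``status_effect`` is D42 minus UA, ``age_effect`` is aged minus young
    (applied only when both age groups are generated).  Defaults mirror the
    measured cohort: Young's modulus drops by ~1.96 GPa and hardness by
    ~0.101 GPa in regenerated distal bone, while direct indentation shows no
    age effect.  Each digit carries 8 sites (5 distal, 3 proximal) with a
    2x2 indent array per site.
    """

    grand_mean_E: float = 18.0
    grand_mean_H: float = 0.8
    region_effect: float = 0.0
    status_effect: float = -1.96
    age_effect: float = 0.0
    region_effect_H: float = 0.0
    status_effect_H: float = -0.101
    sd_mouse: float = 0.5
    sd_site: float = 0.8
    sd_indent: float = 1.0
    sd_mouse_H: float = 0.03
    sd_site_H: float = 0.05
    sd_indent_H: float = 0.08
    n_mice: int = 3
    n_sites_distal: int = 5
    n_sites_proximal: int = 3
    n_indents_per_site: int = 4

    def validate(self) -> None:
        sds = (
            self.sd_mouse, self.sd_site, self.sd_indent,
            self.sd_mouse_H, self.sd_site_H, self.sd_indent_H,
        )
        if any(s < 0 for s in sds):
            raise ValueError("random-effect standard deviations must be >= 0")
        counts = (
            self.n_mice, self.n_sites_distal, self.n_sites_proximal,
            self.n_indents_per_site,
        )
        if any(c <= 0 for c in counts):
            raise ValueError("design counts must be positive")
        if self.grand_mean_E <= 0 or self.grand_mean_H <= 0:
            raise ValueError("grand means must be positive")


def polyline_length(points: np.ndarray, voxel_size_um: float = 1.0) -> float:
    """Euclidean length of a polyline given as an ``(n, 3)`` vertex array."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum() * voxel_size_um)


def _outer_radius(spec: PhantomSpec, z_rel: np.ndarray) -> np.ndarray:
    """Linear taper from proximal to distal radius; z_rel in [0, 1]."""
    return spec.outer_radius_proximal + z_rel * (
        spec.outer_radius_distal - spec.outer_radius_proximal
    )


def _generate_channel_centerlines(
    spec: PhantomSpec, z0: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Smooth perturbed polylines from the proximal base toward the tip.

    Control points every ~12 slices are drawn as a random walk in the
    cross-sectional plane, cubic-spline smoothed, and radially clamped so the
    tube (plus a one-voxel margin) stays inside the inner lumen.  Channels
    start in distinct angular sectors and are kept pairwise separated by at
    least one voxel of bone (truncating at the first violation, retrying a
    few perturbations), so the rendered tubes are disjoint and the summed
    per-channel polyline length is geometrically meaningful ground truth.
    """
    margin = spec.channel_radius_voxels + 1.0
    # two radii plus a >1-voxel bone wall that survives center rounding
    separation = 2.0 * spec.channel_radius_voxels + 2.5
    zs = np.arange(spec.bone_length_voxels, dtype=float)
    lumen = _outer_radius(spec, zs / (spec.bone_length_voxels - 1)) - spec.cortical_thickness_voxels
    usable = lumen - margin  # max centerline offset from axis at each slice
    z_start = int(np.ceil(margin)) + 1
    # stop before the tip: the shrinking lumen cannot hold separated channels
    room = max(0.7 * separation, 1.0) if spec.n_channels > 1 else 0.5
    valid = np.nonzero(usable > room)[0]
    valid = valid[valid >= z_start]
    if valid.size < 8:
        return []
    z_end = int(valid[-1])
    z_line = np.arange(z_start, z_end + 1, dtype=float)
    n = z_line.size
    limit = np.interp(z_line, zs, usable)

    def _candidate(sector: float) -> np.ndarray:
        theta = sector + rng.uniform(-0.3, 0.3) * 2 * np.pi / max(spec.n_channels, 1)
        base_r = rng.uniform(0.4, 0.75) * max(usable[z_start], 0.0)
        base = np.array([base_r * np.cos(theta), base_r * np.sin(theta)])
        n_ctrl = max(4, n // 12)
        zc = np.linspace(z_line[0], z_line[-1], n_ctrl)
        amp = spec.channel_tortuosity * np.interp(zc, zs, np.maximum(usable, 0.0))
        ctrl = rng.standard_normal((n_ctrl, 2)) * amp[:, None]
        offs = base + CubicSpline(zc, ctrl, axis=0)(z_line)
        r = np.linalg.norm(offs, axis=1)
        over = r > limit
        scale = np.ones(n)
        scale[over] = limit[over] / r[over]
        return offs * scale[:, None]

    def _ok_length(offs: np.ndarray, accepted: list[np.ndarray]) -> int:
        """Number of leading samples keeping >= separation from others."""
        good = np.ones(n, dtype=bool)
        for other in accepted:
            k = min(n, other.shape[0])
            d = np.linalg.norm(offs[:k] - other[:k], axis=1)
            good[:k] &= d >= separation
        bad = np.nonzero(~good)[0]
        return int(bad[0]) if bad.size else n

    accepted: list[np.ndarray] = []
    min_len = min(15, max(n // 3, 2))
    for c in range(spec.n_channels):
        sector = 2 * np.pi * c / max(spec.n_channels, 1)
        best, best_len = None, 0
        for _ in range(40):
            offs = _candidate(sector)
            ok = _ok_length(offs, accepted)
            if ok > best_len:
                best, best_len = offs[:ok], ok
            if ok == n:
                break
        if best is not None and best_len >= min_len:
            accepted.append(best)

    centerlines = []
    for offs in accepted:
        k = offs.shape[0]
        pts = np.column_stack([z0 + z_line[:k], offs])  # (z, dy, dx)
        centerlines.append(pts)
    return centerlines


def _stamp_tube(
    carve: np.ndarray, centerline: np.ndarray, radius: float, center_yx: tuple[float, float]
) -> None:
    """Mark all voxels within ``radius`` of the (subdivided) centerline."""
    # subdivide segments to <= 0.5 voxel steps so the tube has no gaps
    pts = []
    for a, b in zip(centerline[:-1], centerline[1:]):
        seg = np.linalg.norm(b - a)
        k = max(2, int(np.ceil(seg / 0.5)) + 1)
        pts.append(np.linspace(a, b, k)[:-1])
    pts.append(centerline[-1:])
    pts = np.concatenate(pts, axis=0)

    r_int = int(np.ceil(radius))
    dz, dy, dx = np.mgrid[-r_int : r_int + 1, -r_int : r_int + 1, -r_int : r_int + 1]
    ball = np.column_stack(
        [d[dz**2 + dy**2 + dx**2 <= radius**2] for d in (dz, dy, dx)]
    )
    cy, cx = center_yx
    centers = np.round(pts + np.array([0.0, cy, cx])).astype(int)
    centers = np.unique(centers, axis=0)
    vox = (centers[:, None, :] + ball[None, :, :]).reshape(-1, 3)
    vox = np.unique(vox, axis=0)
    shape = carve.shape
    ok = np.all((vox >= 0) & (vox < np.array(shape)), axis=1)
    vox = vox[ok]
    carve[vox[:, 0], vox[:, 1], vox[:, 2]] = True


def _render(
    labels: np.ndarray, density_of: dict[int, float], spec_like, rng: np.random.Generator
) -> np.ndarray:
    """Density labels -> affine intensity -> blur -> additive noise."""
    density = np.zeros(labels.shape, dtype=float)
    for lab, dens in density_of.items():
        density[labels == lab] = dens
    img = spec_like.intensity_slope * density + spec_like.intensity_intercept
    if spec_like.blur_sigma_voxels > 0:
        img = gaussian_filter(img, spec_like.blur_sigma_voxels)
    if spec_like.noise_sd > 0:
        img = img + rng.normal(0.0, spec_like.noise_sd, size=img.shape)
    return np.maximum(img, 0.0).astype(np.float32)


def generate_digit_phantom(spec: PhantomSpec) -> tuple[ImageVolume, PhantomGroundTruth]:
    """Render a synthetic digit and return it with exact ground truth.

    The bone occupies slices ``[4, 4 + bone_length)`` of a volume padded by
    four background slices/voxels on every side.  ``status == "UA"`` renders
    a solid cortical interior; ``status == "D42"`` renders a trabecular
    interior and carves ``n_channels`` tortuous channels.  Channels are
    rendered at background density and labelled separately in the ground
    truth.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    pad = 4
    nz = spec.bone_length_voxels + 2 * pad
    half = int(np.ceil(spec.outer_radius_proximal)) + pad
    ny = nx = 2 * half + 1
    cy = cx = float(half)

    labels = np.full((nz, ny, nx), LABEL_BACKGROUND, dtype=np.uint8)
    yy, xx = np.mgrid[0:ny, 0:nx]
    rr = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    for z in range(spec.bone_length_voxels):
        r_out = _outer_radius(spec, z / (spec.bone_length_voxels - 1))
        r_in = r_out - spec.cortical_thickness_voxels
        sl = labels[pad + z]
        sl[rr <= r_out] = LABEL_CORTICAL
        if r_in > 0 and spec.status == "D42":
            sl[rr <= r_in] = LABEL_TRABECULAR

    centerlines: list[np.ndarray] = []
    if spec.n_channels > 0:
        centerlines = _generate_channel_centerlines(spec, pad, rng)
        carve = np.zeros_like(labels, dtype=bool)
        for line in centerlines:
            _stamp_tube(carve, line, spec.channel_radius_voxels, (cy, cx))
        # channels live strictly inside the bone interior
        interior = labels == (LABEL_TRABECULAR if spec.status == "D42" else LABEL_CORTICAL)
        labels[carve & interior] = LABEL_CHANNEL

    shift = spec.age_density_shift
    density_of = {
        LABEL_BACKGROUND: spec.density_background,
        LABEL_CORTICAL: spec.density_cortical + shift,
        LABEL_TRABECULAR: spec.density_trabecular + shift,
        LABEL_CHANNEL: spec.density_background,
    }
    img = _render(labels, density_of, spec, rng)

    total_len = sum(polyline_length(line, spec.voxel_size_um) for line in centerlines)
    truth = PhantomGroundTruth(
        channel_centerline_length_um=total_len,
        channel_polylines=centerlines,
        compartment_density=density_of,
        label_volume=labels,
        intensity_slope=spec.intensity_slope,
        intensity_intercept=spec.intensity_intercept,
    )
    return ImageVolume(data=img, voxel_size_um=spec.voxel_size_um), truth


def generate_straight_tube_phantom(
    tube_length_voxels: int = 400,
    tube_radius_voxels: int = 2,
    bone_radius_voxels: int = 10,
    cap_voxels: int = 6,
    density_bone: float = 1.0,
    voxel_size_um: float = 3.9,
    intensity_slope: float = 200.0,
    intensity_intercept: float = 10.0,
) -> tuple[ImageVolume, PhantomGroundTruth]:
    """Solid cylinder of bone with one straight, fully internal axial tube.

    The tube centerline spans ``tube_length_voxels`` voxel centres, so its
    analytic length is ``(tube_length_voxels - 1) * voxel_size_um``.  This is
    the cleanest possible geometry for validating skeleton-length recovery.
    """
    if tube_length_voxels < 2:
        raise ValueError("tube must span at least two voxel centres")
    if tube_radius_voxels >= bone_radius_voxels:
        raise ValueError("tube radius must be smaller than the bone radius")
    nz = tube_length_voxels + 2 * cap_voxels
    half = bone_radius_voxels + 3
    ny = nx = 2 * half + 1
    cy = cx = float(half)
    labels = np.full((nz, ny, nx), LABEL_BACKGROUND, dtype=np.uint8)
    yy, xx = np.mgrid[0:ny, 0:nx]
    disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= bone_radius_voxels**2
    labels[:, disc] = LABEL_CORTICAL
    tube = (yy - cy) ** 2 + (xx - cx) ** 2 <= tube_radius_voxels**2
    labels[cap_voxels : cap_voxels + tube_length_voxels, tube] = LABEL_CHANNEL

    density_of = {
        LABEL_BACKGROUND: 0.0,
        LABEL_CORTICAL: density_bone,
        LABEL_TRABECULAR: density_bone,
        LABEL_CHANNEL: 0.0,
    }
    spec_like = PhantomSpec(
        intensity_slope=intensity_slope, intensity_intercept=intensity_intercept
    )
    img = _render(labels, density_of, spec_like, np.random.default_rng(0))
    line = np.column_stack(
        [
            np.arange(cap_voxels, cap_voxels + tube_length_voxels, dtype=float),
            np.full(tube_length_voxels, cy),
            np.full(tube_length_voxels, cx),
        ]
    )
    # store offsets about the axis consistently with generate_digit_phantom
    line_rel = line.copy()
    line_rel[:, 1] -= cy
    line_rel[:, 2] -= cx
    truth = PhantomGroundTruth(
        channel_centerline_length_um=polyline_length(line, voxel_size_um),
        channel_polylines=[line_rel],
        compartment_density=density_of,
        label_volume=labels,
        intensity_slope=intensity_slope,
        intensity_intercept=intensity_intercept,
    )
    return ImageVolume(data=img, voxel_size_um=voxel_size_um), truth


def generate_calibration_phantoms(
    densities: tuple[float, float] = (0.25, 0.75),
    intensity_model: tuple[float, float] = (200.0, 10.0),
    noise_sd: float = 0.0,
    seed: int = 0,
    shape: tuple[int, int, int] = (40, 64, 64),
    cylinder_fraction: float = 0.48,
    voxel_size_um: float = 3.9,
) -> tuple[ImageVolume, ImageVolume]:
    """Render the two homogeneous CaHA calibration cylinders.

    Each scan is a cylinder of the given density (filling
    ``cylinder_fraction`` of the frame width in radius) against zero-density
    background, rendered through the affine ``intensity_model = (slope,
    intercept)`` with optional additive Gaussian noise.
    """
    d_low, d_high = float(densities[0]), float(densities[1])
    if d_low == d_high:
        raise ValueError("calibration phantom densities must be distinct")
    if d_low < 0 or d_high < 0:
        raise ValueError("densities must be nonnegative")
    slope, intercept = intensity_model
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    radius = cylinder_fraction * min(ny, nx)
    disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2

    vols = []
    for d in (d_low, d_high):
        density = np.where(disc, d, 0.0)[None].repeat(nz, axis=0)
        img = slope * density + intercept
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, size=img.shape)
        vols.append(ImageVolume(data=img.astype(np.float64), voxel_size_um=voxel_size_um))
    return vols[0], vols[1]


def simulate_indentation_study(
    effects: IndentationEffects,
    seed: int = 0,
    age_groups: tuple[str, ...] = ("18mo",),
) -> pd.DataFrame:
    """Draw a nanoindentation cohort with known fixed and random effects.

    Each mouse contributes one UA and one D42 digit (the amputation design
    uses contralateral digits of the same animal), each digit 8 sites (5
    distal, 3 proximal), each site a 2x2 indent array.  Per-record response:

    ``E = grand_mean + fixed effects + b_mouse + b_site + e_indent``

    with independent Gaussian random effects.  Hardness is drawn analogously
    with its own effect sizes and variance components.  Reduced modulus
    ``E_r`` is back-computed from ``E`` through the Oliver-Pharr relation so
    the dataset is consumable by the measurement-side converter.
    """
    effects.validate()
    rng = np.random.default_rng(seed)
    rows = []
    sites_region = ["distal"] * effects.n_sites_distal + ["proximal"] * effects.n_sites_proximal
    for age in age_groups:
        for m in range(1, effects.n_mice + 1):
            mouse = f"{age}_m{m}"
            b_mouse = rng.normal(0.0, effects.sd_mouse)
            b_mouse_H = rng.normal(0.0, effects.sd_mouse_H)
            for status in ("UA", "D42"):
                for s, region in enumerate(sites_region, start=1):
                    b_site = rng.normal(0.0, effects.sd_site)
                    b_site_H = rng.normal(0.0, effects.sd_site_H)
                    mu = (
                        effects.grand_mean_E
                        + (effects.region_effect if region == "distal" else 0.0)
                        + (effects.status_effect if status == "D42" else 0.0)
                        + (effects.age_effect if age != age_groups[0] else 0.0)
                    )
                    mu_H = (
                        effects.grand_mean_H
                        + (effects.region_effect_H if region == "distal" else 0.0)
                        + (effects.status_effect_H if status == "D42" else 0.0)
                    )
                    e = mu + b_mouse + b_site + rng.normal(
                        0.0, effects.sd_indent, size=effects.n_indents_per_site
                    )
                    h = mu_H + b_mouse_H + b_site_H + rng.normal(
                        0.0, effects.sd_indent_H, size=effects.n_indents_per_site
                    )
                    for k in range(effects.n_indents_per_site):
                        rows.append(
                            (mouse, f"{mouse}-{status}", status, age, region, s, k + 1,
                             e[k], h[k])
                        )
    df = pd.DataFrame(
        rows,
        columns=["mouse", "digit", "status", "age_group", "region", "site", "indent",
                 "E", "H"],
    )
    # E can stray nonpositive only under absurd variance settings; guard anyway
    df["E"] = df["E"].clip(lower=1e-6)
    df["H"] = df["H"].clip(lower=1e-6)
    df["E_r"] = youngs_to_reduced(
        df["E"].to_numpy(), MaterialParams(), IndenterParams()
    )
    return df


def render_cohort(
    groups: dict[str, tuple[PhantomSpec, int]],
    out_dir: str | Path,
    seed: int = 0,
    digits_per_mouse: int = 2,
) -> Path:
    """Write slice stacks plus a ground-truth manifest for a synthetic cohort.

    ``groups`` maps a group label to ``(template_spec, n_digits)``; each digit
    gets a deterministic per-digit seed derived from ``seed``.  Digits are
    assigned to mice round-robin (``digits_per_mouse`` per mouse) within each
    age group, so the same mouse label is shared between the UA and D42
    groups of one age — mirroring the contralateral-digit design.  Returns
    the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    manifest: dict = {"seed": int(seed), "digits": []}
    for group in sorted(groups):
        template, n_digits = groups[group]
        for i in range(n_digits):
            digit_seed = int(rng.integers(0, 2**31 - 1))
            spec = dataclasses.replace(template, seed=digit_seed)
            vol, truth = generate_digit_phantom(spec)
            digit_id = f"{group}_d{i + 1}"
            stack_dir = out_dir / digit_id
            write_stack(vol, stack_dir)
            mouse = f"{spec.age_group}_m{i // digits_per_mouse + 1}"
            manifest["digits"].append(
                {
                    "digit_id": digit_id,
                    "group": group,
                    "status": spec.status,
                    "age_group": spec.age_group,
                    "mouse": mouse,
                    "path": digit_id,
                    "voxel_size_um": spec.voxel_size_um,
                    "seed": digit_seed,
                    "channel_length_um": truth.channel_centerline_length_um,
                    "density_cortical": spec.density_cortical + spec.age_density_shift,
                    "density_trabecular": spec.density_trabecular + spec.age_density_shift,
                }
            )
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest_path
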