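"""End-to-end cohort pipeline: stacks -> calibration -> densitometry ->
modulus maps -> profiles -> skeleton metrics -> cohort statistics.

A single YAML config drives the run.  Calibration failure is fatal (every
downstream number depends on it); any other per-digit failure is isolated,
logged, and reported without aborting the cohort.  All randomness derives
from the config seed, and every tabular output carries the config hash in a
header comment, so identical config + seed reproduces byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from digitbone import __version__
from digitbone.biomechanics import (
    DensityModulusParams,
    axial_profile,
    modulus_volume,
    split_regions,
)
from digitbone.cohort_stats import (
    DEFAULT_CONTRASTS,
    compare_quantiles,
    fit_mixed_anova,
    subsample_for_modulus,
    test_contrasts,
)
from digitbone.densitometry import (
    DensitySample,
    block_average,
    compute_bone_mask,
    density_kde,
    sample_density,
)
from digitbone.microct_io import apply_calibration, fit_calibration, read_stack
from digitbone.voids import (
    internal_void_mask,
    normalize_skeleton,
    segment_bone,
    skeleton_total_length,
    skeletonize_voids,
)

__all__ = ["RunConfig", "RunReport", "validate_config", "run_pipeline"]

logger = logging.getLogger("digitbone.pipeline")


@dataclass
class RunConfig:
    """Validated pipeline configuration (see ``validate_config``)."""

    manifest: Path
    phantom_low: Path
    phantom_high: Path
    phantom_densities: tuple[float, float] = (0.25, 0.75)
    roi_fraction: float = 0.8
    voxel_size_um: float | None = None
    block_L: int = 3
    bone_threshold: float = 0.15
    closing_radius: int = 5
    boundary_tolerance: int = 1
    density_modulus: DensityModulusParams = field(default_factory=DensityModulusParams)
    region_boundary: float = 0.5
    loess_span: float = 0.33
    loess_degree: int = 2
    percentiles: tuple[float, ...] = (10, 25, 50, 75, 90, 95)
    n_density_sample: int = 2000
    n_modulus_sample: int = 1000
    n_boot: int = 500
    seed: int = 0
    reference_group: str | None = None
    compare_groups: tuple[tuple[str, str], ...] = ()

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d["density_modulus"] = dataclasses.asdict(self.density_modulus)
        canon = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Tables, per-digit failures, and provenance of one cohort run."""

    tables: dict[str, pd.DataFrame]
    failures: list[dict]
    provenance: dict
    out_dir: Path


_KNOWN_KEYS = {
    "manifest", "phantom_low", "phantom_high", "phantom_densities",
    "roi_fraction", "voxel_size_um", "block_L", "bone_threshold",
    "closing_radius", "boundary_tolerance", "density_modulus",
    "region_boundary", "loess_span", "loess_degree", "percentiles",
    "n_density_sample", "n_modulus_sample", "n_boot", "seed",
    "reference_group", "compare_groups",
}
_DM_KEYS = {"coeff", "exponent", "ash_slope", "ash_intercept",
            "output_divisor", "output_unit"}


def validate_config(path: str | Path) -> RunConfig:
    """Parse, default, and range-check a YAML pipeline config.

    Paths are resolved relative to the config file.  Unknown keys are
    rejected by name so typos fail loudly rather than silently falling back
    to defaults.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown config key(s): {sorted(unknown)}")
    for key in ("manifest", "phantom_low", "phantom_high"):
        if key not in raw:
            raise ValueError(f"{path}: missing required key {key!r}")

    base = path.parent

    def _path(key: str) -> Path:
        p = Path(raw[key])
        p = p if p.is_absolute() else base / p
        if not p.exists():
            raise ValueError(f"{path}: key {key!r} points to nonexistent path {p}")
        return p

    dm_raw = raw.get("density_modulus", {}) or {}
    unknown_dm = set(dm_raw) - _DM_KEYS
    if unknown_dm:
        raise ValueError(f"{path}: unknown density_modulus key(s): {sorted(unknown_dm)}")
    cfg = RunConfig(
        manifest=_path("manifest"),
        phantom_low=_path("phantom_low"),
        phantom_high=_path("phantom_high"),
        phantom_densities=tuple(raw.get("phantom_densities", (0.25, 0.75))),
        roi_fraction=float(raw.get("roi_fraction", 0.8)),
        voxel_size_um=raw.get("voxel_size_um"),
        block_L=int(raw.get("block_L", 3)),
        bone_threshold=float(raw.get("bone_threshold", 0.15)),
        closing_radius=int(raw.get("closing_radius", 5)),
        boundary_tolerance=int(raw.get("boundary_tolerance", 1)),
        density_modulus=DensityModulusParams(**dm_raw),
        region_boundary=float(raw.get("region_boundary", 0.5)),
        loess_span=float(raw.get("loess_span", 0.33)),
        loess_degree=int(raw.get("loess_degree", 2)),
        percentiles=tuple(raw.get("percentiles", (10, 25, 50, 75, 90, 95))),
        n_density_sample=int(raw.get("n_density_sample", 2000)),
        n_modulus_sample=int(raw.get("n_modulus_sample", 1000)),
        n_boot=int(raw.get("n_boot", 500)),
        seed=int(raw.get("seed", 0)),
        reference_group=raw.get("reference_group"),
        compare_groups=tuple(tuple(p) for p in raw.get("compare_groups", ())),
    )
    if len(cfg.phantom_densities) != 2 or cfg.phantom_densities[0] == cfg.phantom_densities[1]:
        raise ValueError(f"{path}: phantom_densities must be two distinct values")
    if cfg.bone_threshold < 0:
        raise ValueError(f"{path}: bone_threshold must be nonnegative")
    if cfg.block_L < 1:
        raise ValueError(f"{path}: block_L must be >= 1")
    if not (0 < cfg.region_boundary < 1):
        raise ValueError(f"{path}: region_boundary must lie in (0, 1)")
    if not (0 < cfg.loess_span <= 1):
        raise ValueError(f"{path}: loess_span must lie in (0, 1]")
    for p in cfg.percentiles:
        if not (0 < p < 100):
            raise ValueError(f"{path}: percentile {p} outside (0, 100)")
    for n in (cfg.n_density_sample, cfg.n_modulus_sample, cfg.n_boot):
        if n < 1:
            raise ValueError(f"{path}: sampling sizes must be positive")
    return cfg


def _write_tsv(df: pd.DataFrame, path: Path, header: dict) -> None:
    """Write a TSV atomically, with a provenance comment header."""
    tmp = path.with_suffix(path.suffix + ".tmp")
    lines = "".join(f"# {k}={v}\n" for k, v in sorted(header.items()))
    body = df.to_csv(sep="\t", index=False, float_format="%.10g")
    tmp.write_text(lines + body)
    tmp.replace(path)


def _analyze_digit(entry: dict, model, cfg: RunConfig, seed: int):
    """Full per-digit analysis; returns the per-digit result bundle."""
    stack_path = entry["_stack_path"]
    vol = read_stack(stack_path, voxel_size_um=cfg.voxel_size_um or entry.get("voxel_size_um"))
    dens = apply_calibration(vol, model)
    blocks = block_average(dens, L=cfg.block_L,
                           provenance={"digit": entry["digit_id"]})
    blocks = compute_bone_mask(blocks, threshold_g_cm3=cfg.bone_threshold)
    if blocks.bone_mask.sum() == 0:
        raise ValueError("empty bone mask")
    sample = sample_density(
        blocks, n=cfg.n_density_sample, seed=seed,
        digit=entry["digit_id"], mouse=entry["mouse"],
        status=entry["status"], age_group=entry["age_group"],
    )
    mod = modulus_volume(blocks, cfg.density_modulus)
    profile = axial_profile(mod, span=cfg.loess_span, degree=cfg.loess_degree)
    regions = split_regions(profile.positions, cfg.region_boundary)
    mod_table = pd.DataFrame(
        {
            "mouse": entry["mouse"],
            "digit": entry["digit_id"],
            "group": entry["group"],
            "status": entry["status"],
            "age_group": entry["age_group"],
            "region": regions,
            "position": profile.positions,
            "modulus": profile.values,
        }
    )
    # void architecture on the calibrated per-voxel density volume
    bone = segment_bone(dens, threshold=cfg.bone_threshold)
    voids = internal_void_mask(bone, cfg.closing_radius, cfg.boundary_tolerance)
    skel = skeletonize_voids(voids)
    summary = skeleton_total_length(
        skel, dens.voxel_size_um, digit=entry["digit_id"], group=entry["group"]
    )
    return sample, profile, mod_table, summary


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> RunReport:
    """Execute the cohort pipeline and write the report tables.

    Stage order: calibration (fatal on failure) -> per-digit densitometry,
    modulus mapping, profiling, and void skeletonization (failures isolated
    per digit) -> cohort tables (skeleton normalisation, pooled KDEs, mixed
    ANOVA contrasts on subsampled modulus, cluster-bootstrap quantile
    comparisons).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    header = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "software": f"digitbone {__version__}",
        "modulus_unit": cfg.density_modulus.output_unit,
    }

    # --- calibration (fatal) ---
    t0 = time.perf_counter()
    low = read_stack(cfg.phantom_low, voxel_size_um=cfg.voxel_size_um)
    high = read_stack(cfg.phantom_high, voxel_size_um=cfg.voxel_size_um)
    model = fit_calibration(low, high, cfg.phantom_densities, cfg.roi_fraction)
    logger.info("calibration: slope=%.6g intercept=%.6g (%.2fs)",
                model.slope, model.intercept, time.perf_counter() - t0)

    manifest = json.loads(Path(cfg.manifest).read_text())
    digits = sorted(manifest["digits"], key=lambda d: d["digit_id"])
    for d in digits:
        d["_stack_path"] = Path(cfg.manifest).parent / d["path"]

    rng = np.random.default_rng(cfg.seed)
    digit_seeds = {d["digit_id"]: int(rng.integers(0, 2**31 - 1)) for d in digits}
    stats_seed = int(rng.integers(0, 2**31 - 1))

    samples: list[DensitySample] = []
    profiles: dict[str, object] = {}
    mod_tables: list[pd.DataFrame] = []
    skeletons = []
    failures: list[dict] = []
    for entry in digits:
        t0 = time.perf_counter()
        try:
            sample, profile, mod_table, summary = _analyze_digit(
                entry, model, cfg, digit_seeds[entry["digit_id"]]
            )
        except Exception as exc:  # noqa: BLE001 - digit isolation contract
            logger.warning("digit %s failed: %s", entry["digit_id"], exc)
            failures.append({"digit_id": entry["digit_id"], "reason": str(exc)})
            continue
        samples.append(sample)
        profiles[entry["digit_id"]] = profile
        mod_tables.append(mod_table)
        skeletons.append(summary)
        logger.info("digit %s done (%.2fs)", entry["digit_id"],
                    time.perf_counter() - t0)

    tables: dict[str, pd.DataFrame] = {}

    # density samples
    if samples:
        tables["density_samples"] = pd.DataFrame(
            {
                "mouse": np.repeat([s.mouse for s in samples],
                                   [len(s.values) for s in samples]),
                "digit": np.repeat([s.digit for s in samples],
                                   [len(s.values) for s in samples]),
                "age_group": np.repeat([s.age_group for s in samples],
                                       [len(s.values) for s in samples]),
                "status": np.repeat([s.status for s in samples],
                                    [len(s.values) for s in samples]),
                "value": np.concatenate([s.values for s in samples]),
            }
        )

    # pooled KDE per group on a shared grid
    group_of = {d["digit_id"]: d["group"] for d in digits}
    by_group: dict[str, list[DensitySample]] = {}
    for s in samples:
        by_group.setdefault(group_of[s.digit], []).append(s)
    if by_group:
        all_vals = np.concatenate([s.values for s in samples])
        pad = 0.1 * (all_vals.max() - all_vals.min() + 1e-9)
        grid = np.linspace(all_vals.min() - pad, all_vals.max() + pad, 512)
        kde_parts = []
        for g in sorted(by_group):
            k = density_kde(by_group[g], grid=grid)
            k.insert(0, "group", g)
            kde_parts.append(k)
        tables["density_kde"] = pd.concat(kde_parts, ignore_index=True)

    # profiles
    if profiles:
        prof_parts = []
        for digit_id in sorted(profiles):
            p = profiles[digit_id]
            prof_parts.append(pd.DataFrame(
                {"digit": digit_id, "position": p.grid, "fitted_modulus": p.fitted}
            ))
        tables["modulus_profiles"] = pd.concat(prof_parts, ignore_index=True)

    # skeleton summaries (normalised to the reference group when possible)
    if skeletons:
        ref = cfg.reference_group
        if ref is None:
            ua_groups = sorted({s.group for s in skeletons if "UA" in s.group})
            ref = ua_groups[0] if ua_groups else None
        if ref is not None and any(
            s.group == ref and s.total_length_um > 0 for s in skeletons
        ):
            normalize_skeleton(skeletons, ref)
        tables["skeleton_summary"] = pd.DataFrame(
            {
                "digit": [s.digit for s in skeletons],
                "group": [s.group for s in skeletons],
                "total_length_um": [s.total_length_um for s in skeletons],
                "n_components": [s.n_components for s in skeletons],
                "normalized_length": [
                    np.nan if s.normalized_length is None else s.normalized_length
                    for s in skeletons
                ],
            }
        )

    # modulus mixed ANOVA per age group (mouse random intercept, no sites)
    contrast_rows = []
    if mod_tables:
        mod_all = pd.concat(mod_tables, ignore_index=True)
        sub = subsample_for_modulus(
            mod_all, n=cfg.n_modulus_sample, strata=("digit", "region"),
            value_col="modulus", seed=stats_seed,
        )
        tables["modulus_samples"] = sub[
            ["mouse", "digit", "group", "status", "age_group", "region", "modulus"]
        ]
        for age, age_sub in sub.groupby("age_group", sort=True):
            if set(age_sub["status"]) != {"UA", "D42"} or age_sub["mouse"].nunique() < 2:
                logger.info("skipping modulus ANOVA for age %s (incomplete design)", age)
                continue
            fit = fit_mixed_anova(age_sub, response="modulus", include_site=False)
            for c in test_contrasts(fit, DEFAULT_CONTRASTS):
                contrast_rows.append(
                    {"age_group": age, "contrast": c.name, "estimate": c.estimate,
                     "se": c.se, "ci_low": c.ci_low, "ci_high": c.ci_high,
                     "p_adjusted": c.p_adjusted}
                )
    if contrast_rows:
        tables["modulus_contrasts"] = pd.DataFrame(contrast_rows)

    # quantile comparisons
    q_rows = []
    for ga, gb in cfg.compare_groups:
        sa, sb = by_group.get(ga, []), by_group.get(gb, [])
        if len(sa) < 2 or len(sb) < 2:
            logger.info("skipping quantile comparison %s vs %s (too few digits)", ga, gb)
            continue
        res = compare_quantiles(sa, sb, percentiles=cfg.percentiles,
                                n_boot=cfg.n_boot, seed=stats_seed)
        res.insert(0, "comparison", f"{gb} - {ga}")
        q_rows.append(res)
    if q_rows:
        tables["quantile_comparisons"] = pd.concat(q_rows, ignore_index=True)

    for name, df in tables.items():
        _write_tsv(df, out_dir / f"{name}.tsv", header)
    provenance = {
        **header,
        "calibration_slope": model.slope,
        "calibration_intercept": model.intercept,
        "digit_seeds": digit_seeds,
        "stats_seed": stats_seed,
        "df_method": "containment",
        "n_digits": len(digits),
        "failures": failures,
    }
    (out_dir / "run_metadata.json").write_text(
        json.dumps(provenance, indent=1, sort_keys=True)
    )
    return RunReport(tables=tables, failures=failures, provenance=provenance,
                     out_dir=out_dir)
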