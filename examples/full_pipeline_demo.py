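"""End-to-end cohort run on a small synthetic cohort.

Generates unamputated (UA) and day-42 regenerated (D42) digit phantoms plus
calibration cylinders, then runs the full pipeline: calibration, block
densitometry, modulus mapping and profiling, void skeletonization, and the
cohort statistics.  Equivalent to::

    digitbone generate --out demo --seed 5 --digits-per-group 2
    digitbone run --config demo/config.yaml --out demo/results
"""

import dataclasses
import tempfile
from pathlib import Path

import yaml

from digitbone import PhantomSpec, generate_calibration_phantoms, render_cohort
from digitbone.microct_io import write_stack
from digitbone.pipeline import run_pipeline, validate_config

root = Path(tempfile.mkdtemp(prefix="digitbone_demo_"))
spec = PhantomSpec(
    bone_length_voxels=60, outer_radius_proximal=16.0, outer_radius_distal=7.0,
    cortical_thickness_voxels=4, n_channels=3, channel_radius_voxels=2,
    blur_sigma_voxels=0.8, noise_sd=2.0,
)
groups = {
    "UA_18mo": (dataclasses.replace(spec, status="UA", n_channels=2), 2),
    "D42_18mo": (spec, 2),
}
render_cohort(groups, root / "stacks", seed=5)
low, high = generate_calibration_phantoms(
    intensity_model=(spec.intensity_slope, spec.intensity_intercept),
    noise_sd=2.0, seed=6,
)
write_stack(low, root / "phantom_low")
write_stack(high, root / "phantom_high")
(root / "config.yaml").write_text(yaml.safe_dump({
    "manifest": "stacks/manifest.json",
    "phantom_low": "phantom_low",
    "phantom_high": "phantom_high",
    "seed": 5,
    "n_boot": 300,
    "reference_group": "UA_18mo",
    "compare_groups": [["UA_18mo", "D42_18mo"]],
}))

report = run_pipeline(validate_config(root / "config.yaml"), root / "results")
print(f"run directory: {report.out_dir}")
print(f"tables written: {sorted(report.tables)}  failures: {report.failures}")

skel = report.tables["skeleton_summary"]
print("\nskeleton summary (normalised to the UA group mean):")
print(skel.to_string(index=False))

if "quantile_comparisons" in report.tables:
    print("\ndensity quantile comparisons (D42 - UA):")
    print(report.tables["quantile_comparisons"].to_string(index=False))

print()
print("Regenerated digits carry more internal vascular-like void length than")
print("unamputated ones (normalised length > 1), and their density quantiles")
print("sit below the UA group because woven regenerate is less mineralised.")
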