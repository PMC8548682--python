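"""Two-point hydroxyapatite-phantom calibration on synthetic scans.

Generates the 0.25 and 0.75 g/cm^3 CaHA calibration cylinders with a known
affine intensity model plus noise, fits the two-point calibration, and
applies it to a noisy synthetic digit, recovering the compartment densities.
"""

import numpy as np

from digitbone import (
    PhantomSpec,
    apply_calibration,
    fit_calibration,
    generate_calibration_phantoms,
    generate_digit_phantom,
)

spec = PhantomSpec(noise_sd=2.0, blur_sigma_voxels=0.8, seed=1)
low, high = generate_calibration_phantoms(
    intensity_model=(spec.intensity_slope, spec.intensity_intercept),
    noise_sd=2.0, seed=2,
)
model = fit_calibration(low, high, densities=(0.25, 0.75))
print(f"calibration: density = {model.slope:.6f} * intensity + {model.intercept:+.6f}")
print(f"phantom means {model.source_means[0]:.2f} / {model.source_means[1]:.2f} "
      f"map to {model(model.source_means[0]):.4f} / "
      f"{model(model.source_means[1]):.4f} g/cm^3")

vol, truth = generate_digit_phantom(spec)
dens = apply_calibration(vol, model)
for lab, name in [(1, "cortical"), (2, "trabecular")]:
    region = truth.label_volume == lab
    if region.any():
        est = np.median(dens.data[region])
        print(f"{name:10s}: true {truth.compartment_density[lab]:.3f}, "
              f"median calibrated {est:.3f} g/cm^3")

print()
print("The affine model pins the scanner's arbitrary grayscale to physical")
print("mineral density; compartment medians recover the ground truth to")
print("within the blur/noise the generator injected.")
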