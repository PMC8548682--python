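# Methods

This note documents the models implemented in `digitbone`, the parameter
choices that matter, what the synthetic-data generator does and does not
emulate, and the numerical conventions.

## Coordinate and unit conventions

Volumes are indexed `(slice, row, col)`; slice 0 is proximal, the last slice
distal. Voxels are isotropic; the default size is 3.9 µm, typical of
high-resolution ex vivo digit scans. Physical coordinates are voxel centres
times the voxel size. Mineral density is hydroxyapatite-equivalent
(g/cm³ CaHA) throughout; the calibration phantoms are labelled 0.25 and
0.75 in these units.

## Density calibration

Two homogeneous CaHA cylinders are scanned alongside the specimen. The mean
intensity inside a central cylindrical ROI of each phantom (radius = 0.8 of
the half-width, central 80% of slices; the fraction is configurable) is
mapped onto the known density. With exactly two phantoms the affine
interpolant is unique, so a two-point solve — not a regression — is the only
defensible estimator; the model reproduces the two source densities to
machine precision by construction. The ROI fraction is a package choice:
its purpose is to exclude edge/partial-volume voxels, and any interior
fraction gives identical results on homogeneous phantoms. Calibrated
negative densities (air, soft tissue) are clamped to zero by default.

## Block densitometry

The calibrated per-voxel volume is partitioned into non-overlapping
L × L × L blocks (L = 3 default) carrying the mean of their member voxels.
Edge blocks smaller than L are averaged over the voxels they actually
contain; discarding them would bias the distal tip, which is the region of
interest in regeneration. Blocks at or above a density threshold
(0.15 g/cm³ CaHA default, configurable — roughly half the density of woven
regenerate, well above soft-tissue residuals) form the bone mask, optionally
restricted to the largest 26-connected component to drop speckle.
Per-digit density distributions are summarised by a seeded random subsample
of 2,000 masked block values and pooled Gaussian KDEs (Silverman bandwidth).

## Elasticity

*Measurement side.* Nanoindentation reports reduced modulus E_r; Young's
modulus follows from the Oliver–Pharr compliance sum
1/E_r = (1 − ν²)/E + (1 − ν_i²)/E_i with ν = 0.3 (bone) and a diamond
Berkovich tip (E_i = 1141 GPa, ν_i = 0.07). The map is strictly increasing
and exactly invertible; inputs at or beyond the indenter-corrected limit
(≈1146.6 GPa for the defaults) are rejected with a diagnostic.

*Prediction side.* Block density is converted to ash density
(ρ_ash = 0.8772 ρ_HA + 0.0789) and then to modulus E = 10200 ρ_ash^2.01.
The coefficient is read as MPa and divided by 1000 for reporting in GPa;
this unit choice is isolated in a single configurable divisor
(`DensityModulusParams.output_divisor`) and surfaced in all table headers,
since the power-law source leaves the output unit implicit. With it, a
fully mineralised cortical block (~1 g/cm³ CaHA) predicts ~9 GPa —
consistent in magnitude with the indentation-derived moduli.

*Axial profiles.* Each masked block contributes its modulus at a normalized
proximal→distal coordinate (0 = most proximal masked slice, 1 = most
distal). A locally weighted polynomial regression (tricube weights, degree
2, span 0.33 — the fraction of points per local fit) is evaluated on a
100-point grid. LOESS is implemented in-package because the available
library smoother is restricted to degree 1; windows are nearest-neighbour
sets, so they shrink one-sidedly at the boundaries. The proximal/distal
region split defaults to half the masked axial extent: the anatomical
amputation plane is not available for synthetic digits, and the boundary is
configurable for real data. Region statistics pool blocks within each
region rather than aggregating per slice first.

## Internal void architecture

The single most consequential interpretation in the package: "internal void
space" is operationalised as *envelope minus bone*. Bone is segmented by
global threshold (largest 26-connected component retained); the envelope is
the morphological closing of the bone mask with a ball (radius 5 voxels
default — comfortably above the expected channel radius, and monotone:
larger radii never shrink the void space); voids are envelope AND NOT bone,
with components reaching within one voxel of the envelope surface discarded
as exterior concavities.

Voids are thinned to a one-voxel medial skeleton by 3D parallel thinning
(Lee et al. 1994, via scikit-image), which preserves 26-connectivity
topology; the component count is checked against the void mask per run.
Total centerline length is the weight of a minimum spanning forest over the
26-neighbour skeleton graph with edge lengths voxel × {1, √2, √3}; the
spanning forest counts each 2×2 junction cluster once where a naive edge
sum would overcount. Per-digit totals are normalised to the mean total
length of a reference group (unamputated digits by convention; the selector
is configurable because the source convention — one reference animal versus
the group mean — is ambiguous).

Known biases, both visible in the validation suite: digitised oblique paths
measured with {1, √2, √3} weights overestimate smooth-curve length by up to
~8%, while thinning erodes roughly one tube radius from each channel end.
Net recovery error on tortuous-channel phantoms is typically +4…+10%, and a
long straight tube recovers its analytic length almost exactly.

## Cohort statistics

*Mixed ANOVA.* Indentation responses are modelled with fixed effects
region × status (2×2 with interaction, treatment coding) and random
intercepts for mouse and for indentation site nested in mouse (fitted by
REML via statsmodels MixedLM; the site term enters as a per-mouse variance
component). Calculated-modulus tables omit the site level. Contrast
inference uses containment-style denominator degrees of freedom — the
number of experimental units at the finest level where the fixed effects
vary (sites for indentation; observations net of fixed-effect rank and
mouse levels otherwise). Satterthwaite approximation was considered but
requires the variance-parameter covariance, which the fitting backend does
not expose; the containment choice is recorded in every result's metadata
and validated by simulation in the test suite (status-effect bias below 10%
of the effect, 95% CI coverage within 0.93–0.97, and familywise error at
most 0.06 at the default design).

*Simultaneous contrasts.* The default family — UA proximal vs distal, D42
proximal vs distal, UA distal vs D42 distal, each "A vs B" reported as
A − B — is tested single-step max-t: the joint distribution of the contrast
t-statistics is multivariate t with correlation from the fixed-effect
covariance, sampled with a fixed internal seed (10⁵ draws) to obtain
adjusted p-values and simultaneous 95% CIs. A family of one reduces to the
exact t test; Bonferroni is available as a deterministic fallback.

*Quantile comparisons.* Group differences of pooled density/modulus
quantiles (default percentile set {10, 25, 50, 75, 90, 95}, covering every
percentile the source analyses mention) are estimated per percentile, with
uncertainty from a two-stage cluster bootstrap: resample mice, then digits
within each resampled mouse, recomputing pooled quantiles each draw. Both
stages use the m−1 convention (draw k−1 of k clusters with replacement,
Rao–Wu rescaling in its simplest form): naive k-of-k resampling shrinks the
implied variance by (k−1)/k, which at the 3–6 mice typical of these cohorts
visibly inflates the nominal-5% type-I rate in null simulations, whereas
the m−1 scheme keeps it inside the 2–8% band verified per percentile by the
test suite. The
percentile-bootstrap 95% CI and a CI-inversion two-sided p (add-one
corrected) are reported. This bootstrap deliberately replaces linear
quantile mixed models: it targets the same estimand — percentile-level
group differences with mouse-level dependence — while being fully
specifiable and seedable.

## Synthetic-data generator

The generator renders what the pipeline needs to be tested against truth,
not a physically faithful CT simulation.

*Digit phantoms.* A cone tapering linearly from a proximal to a distal
outer radius (defaults 24 → 7 voxels over 100 slices) with a cortical shell
(5 voxels). "UA" phantoms render a solid cortical interior (no trabecular
compartment); "D42" phantoms render a trabecular interior. Internal
channels emulate the vascular-like void spaces: smooth perturbed polylines
(cubic-spline-smoothed random control points, perpendicular amplitude
scaled by the tortuosity parameter and the local lumen radius), radially
clamped inside the lumen, rasterised as tubes of fixed radius. Channels
start in distinct angular sectors and are kept pairwise separated by more
than a voxel of bone — truncating at the first violation and retrying the
perturbation — so the rendered tubes are disjoint and the summed per-channel
polyline length is exact, geometrically meaningful ground truth. Unamputated
presets carry fewer channels (cortical vascular canals) so the reference
group has nonzero void length to normalise against. Compartment densities
default to 1.0 (cortical), 0.6 (trabecular), 0 (background) g/cm³ CaHA,
with an additive shift (0.1 in aged presets) emulating the aged-bone
density increase. Rendering is density → affine intensity → Gaussian blur
(partial-volume surrogate) → additive Gaussian noise → clamp at zero; with
zero blur and noise the intensity is exactly affine in compartment density.

Not emulated: X-ray projection physics, beam hardening, reconstruction
artefacts, realistic trabecular micro-architecture, or anatomically curved
digits. Passing tests therefore demonstrate correctness of the measurement
chain under controlled geometry and noise, not robustness to every
scanner artefact.

*Indentation cohorts.* Each mouse contributes one UA and one D42 digit
(contralateral-digit design), each digit 5 distal + 3 proximal sites, each
site a 2×2 indent array. Responses are grand mean + fixed effects
(status effect −1.96 GPa on E and −0.101 GPa on hardness by default,
mirroring the measured distal regeneration contrasts; no age effect on
direct indentation, matching the measured null) + Gaussian mouse, site, and
indent deviations (0.5/0.8/1.0 GPa defaults — scatter typical of bone
nanoindentation). Reduced modulus is back-computed through the
Oliver–Pharr relation so simulated data flow through the same conversion as
measured data.

## Determinism and problem sizes

Every stochastic operation takes a seed; pipeline runs derive per-digit and
statistics seeds deterministically from the config seed, and tables are
written with fixed float formatting, so identical config + seed yields
byte-identical outputs. The validation suite sizes its simulations to keep
the whole run at desk scale (500-replicate parameter-recovery and
bootstrap-calibration studies, a 1,000-replicate familywise-error study,
20-phantom length-recovery sweeps, and cohorts of 2–6 small digits for
end-to-end runs); all sizes are ordinary function arguments, so larger
studies only cost time.

## Known limitations

* The density–modulus power law was developed for quantitative CT of bone
  at larger scales; applying it per 3-voxel block extrapolates it to
  microstructure, which is exactly the modelling step the prediction-side
  analysis rests on.
* The containment df rule is conservative-leaning for balanced designs but
  approximate; for very unbalanced designs a Kenward–Roger/Satterthwaite
  implementation would be preferable.
* Skeleton length carries the lattice and end-erosion biases quantified
  above; comparisons between groups processed identically are unaffected to
  first order, absolute lengths carry the few-percent bias.
* The proximal/distal split on synthetic digits is geometric (fraction of
  the masked axial extent), not anatomical.
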