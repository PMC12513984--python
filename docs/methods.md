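# Methods

This note documents the models, parameter choices and numerical decisions
behind `ccfd`, and what the synthetic validation does and does not show
about real data.

## Synthetic choriocapillaris scenes

**Mesh model.** The capillary mesh is synthesized by thresholding
band-pass filtered Gaussian noise. The pass band is a Gaussian annulus in
radial spatial frequency centred on the mid-range intercapillary distance
(ICD): with capillary diameters of 16–20 µm and edge-to-edge gaps of
5–20 µm the ICD (one vessel plus one physiologic void) spans 21–40 µm, and
the filter is centred at 1/30.5 µm⁻¹ with a relative bandwidth of 1/3.
Only two properties of the mesh are contractual, and both are tested: the
radially averaged power spectrum peaks at a period inside 21–40 µm, and
the vessel/gap duty cycle matches the requested fill. The synthesis route
itself (band-pass noise rather than explicit vessel tracing) is an
implementation choice.

**Duty cycle and the deficit floor.** The intrinsic vessel fill is fixed
at `d_mid / (d_mid + gap_min) = 18/23 ≈ 0.78`, i.e. an intrinsic void
fraction of ≈ 0.22. The narrow end of the physiologic gap range is used
deliberately: the generator's job is to study *pathological* deficit
fractions of 0.30–0.60 on top of the physiologic voids, and a larger
intrinsic floor would make those targets unreachable. Pathological
deficits are carved as disc-shaped voids (default radius 75 µm, ±20%
jitter) until the true deficit fraction — exactly the zero set of the
flow field — is within ±0.01 of the target. Targets below the floor raise
an error that reports the achievable floor; a target of 1.0 short-circuits
to the all-void field.

**Vessel texture.** Vessel interiors carry a smooth intensity in
[0.55, 1] derived from the same band-pass field, so images are continuous
rather than binary while the deficit mask stays exact.

**Reference grid.** 1024 px over 3 mm (≈ 2.93 µm/px), chosen so the
swept-source rendering is resample-free and the minimum vessel diameter
spans > 5 px. Device renderings never upsample.

**Devices.** Three profiles: `SS` (3 mm, 1024 px), `SD_V1` and `SD_V4`
(3 mm, 400 px). Four-volume averaging is modelled purely as averaging
four independent noise draws (noise SD halves); no inter-volume motion is
simulated. The noise scales (0.03 for SS, 0.06 for SD, normalized
intensity) are generator defaults, not calibrated claims about either
instrument: the intensity distribution of real CC slabs is not
characterized here, and the noise model is a stand-in. Structural
baseline reflectance is a fixed constant 0.8 before attenuation.

**Shadows.** Drusen are cosine-tapered discs (default: 8 drusen, 100 µm
radius ± 30%, floor attenuation 0.4 — diameters of large-drusen scale).
Attenuation multiplies the structural and flow channels by the *same*
factor, which is the premise that makes inverted-structural compensation
meaningful; overlapping drusen combine by taking the elementwise minimum
so the factor stays in (0, 1] and equals 1 outside footprints.

**Volumes.** For slab-extraction testing, a voxel at depth *d* below the
local BM carries the truth field weighted by an axial profile; the cohort
pipeline uses a Gaussian CC band centred 16 µm below BM (SD 9 µm) plus an
independent, coarser "inner choroid" mesh centred at 42 µm, so different
slabs genuinely see different vasculature.

## Slab extraction

Projection is the mean of samples at `bm + z_inner, …, bm + z_outer`
(inclusive bounds, the outer bound always included), with linear
interpolation at fractional depths; maximum projection is available by
flag. Which statistic the commercial devices use for their automatic
slabs is not public; mean was chosen for linearity and noise behaviour,
and the choice is configurable rather than resolved. "Below BM" is
measured along the axial axis, positive downward. The axial step must be
≤ 2 µm so that 10-µm slabs contain at least five samples.

## Compensation

`F' = F · G_σ(1 − S)` with reflect padding. The smoothing scale is not
standardized anywhere; the default σ = 15 µm (≈ 2 px on the SD grid,
≈ 5 px on the SS grid) is wider than one capillary and narrower than a
druse, so the attenuation estimate tracks shadows without erasing
vascular texture. Output rescaling (affine map of the result onto [0, 1],
on by default) mirrors the display-range behaviour of the interactive
recipe; a constant result maps to zero. Images are normalized at load
time by the dtype maximum, never by per-image min/max, because per-image
stretching silently changes Phansalkar behaviour. Note the recipe is a
heuristic: with a structural baseline of 0.8 it over-boosts mildly
shadowed regions in intensity terms, but the threshold-based FD metrics
are far less sensitive to over-brightening than to darkening, which is
why compensation still strictly reduces FD% error on shadowed scenes.

## Binarization

Circular window (Euclidean, the Fiji convention), reflect padding, local
mean and population SD computed by convolution; threshold
`t = µ(1 + p·e^(−qµ) + k(σ/r − 1))` with (k, r, p, q) = (0.25, 0.5, 2, 10)
— the constants of the original method as shipped in the Fiji Auto Local
Threshold plugin. Tie rule: a pixel equal to its threshold is a deficit,
so the all-zero image is 100% deficit (fixed, documented, and exercised by
tests). Whether the "white objects" convention was applied to flow or
deficit in common practice is ambiguous; this package fixes deficit =
at-or-below threshold. The default radius of 4 px is used on both grids
even though it spans different physical widths (30 µm at 7.5 µm/px,
≈ 11.7 µm at 2.93 µm/px) — preserved as-is because that is how the method
is applied in practice; `radius_um_to_px` converts a physical radius by
rounding for users who prefer matched physical windows. The windowed
implementation is verified bit-identical to a per-pixel brute-force
oracle on random images at radii 1–8.

## Particle metrics

8-connectivity by default ("contiguous" is conventionally the
Analyze-Particles 8-neighbour rule); 4 by flag. No minimum particle size
is applied by default. The FD% denominator is all image pixels — no
exclusion ROI is defined. An optional post-filter removes components with
equivalent diameter `2√(area/π)` < 27 µm (deficits within the normal ICD);
it is off by default because in practice that exclusion is an implicit
property of the window radius, not an explicit filter. Metrics are stored
at full precision; the table layer rounds to 2 decimals.

## Statistics

- **Wilcoxon signed-rank**: zero differences dropped; for n ≤ 15 the
  two-sided p is exact by convolution over all 2ⁿ sign assignments on
  doubled midranks (valid under ties, conditional on the observed
  ranks); beyond that, normal approximation with tie correction. The
  exact path matches an independent full-enumeration oracle, and the
  approximate path's empirical type-I error at n = 23 is ≈ 0.05.
- **ICC(2,1)**: Shrout–Fleiss two-way random effects, single measure,
  absolute agreement, from the two-way mean squares; 95% CI by the
  F-based interval with Satterthwaite degrees of freedom (McGraw–Wong).
  Cross-checked against `pingouin.intraclass_corr`. Zero total variance
  is refused (ICC undefined). The published per-device slab-agreement
  ICCs are read as "ICC across the five slab columns per device", and
  that is what the table layer computes.
- **Repeated-measures ANOVA**: one-factor within-subject decomposition
  from explicit sums of squares (equivalent to the mixed model with a
  random subject intercept under the complete balanced design);
  cross-checked against `statsmodels` AnovaRM. A two-factor
  (device × slab) wrapper over AnovaRM is provided for the run report.
- **Tukey HSD**: studentized-range tail on the RM error term,
  `q = |mᵢ − mⱼ| / √(MSE/n)` with (n−1)(k−1) error df; the scipy tail is
  verified against a direct numerical-integration oracle to 1e−4.
- Two-sided tests throughout, α = 0.05, no correction beyond Tukey.
  Because the source of each published pairwise p-value is ambiguous
  (both a mixed model and Wilcoxon tests are named), the device-pair
  column of the Table-1 analogue reports the Wilcoxon p-values and the
  slab-pair matrix of the Table-2 analogue reports Tukey p-values; both
  machineries are exposed so users can report either side by side.

## Problem sizes and determinism

Validation experiments use 20 seeded scenes per condition with targets
spread over 0.30–0.60, rendered on the swept-source grid for recovery
(resample-free geometry) and on the noisy spectral-domain grid for the
radius-dependence experiment; the default cohort run is 5 eyes × 3
devices × 5 slabs. All randomness flows through explicit integer seeds;
reruns are byte-identical, and every output row carries a parameter hash.

## What the synthetic validation does not show

Passing tests demonstrate internal correctness (definitions, oracles,
invariances, calibration) and qualitative reproduction of planted
effects. They do not certify agreement with any real instrument: speckle,
motion artifacts, projection-artifact residue, RPE elevation geometry,
segmentation error and true CC intensity statistics are all outside the
generator. Published cohort means/SDs, slab-pair p-value matrices and the
printed ICCs depend on a 23-eye patient image set that is not publicly
deposited and are therefore checked only at the level of arithmetic
consistency (FD% ↔ total area) and planted-effect significance patterns.
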