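# Methods

## Scope

`adcqa` implements the offline analysis half of a multi-scanner ADC
quality-assurance program: ADC map fitting from b-value images, vial/organ
ROI statistics, the QIBA Diffusion Profile conformance battery, and
multi-scanner aggregation — plus a synthetic data generator that stands in
for scanner exports. Scanner hardware, pulse-sequence physics, image
registration and human contouring are out of scope; organ masks are consumed
already aligned to the ADC grid.

## Signal model and ADC fit

Every voxel is assumed to decay mono-exponentially, S(b) = S0·exp(−b·ADC).
The fitter decodes stored values to physical signal (stored×slope +
intercept, applied exactly once), then fits ln S against b per voxel by
ordinary least squares with uniform weights. For exactly two b-values this
is identically the closed form ln(S1/S2)/(b2−b1). A signal²-weighted
variant (approximate maximum likelihood for additive noise on S) is
available behind `weighting="signal2"` but is not the default, because the
reference analysis software's weighting is not public; the weighting in
force is recorded in every report header.

Conventions and edge cases:

- Units: public ADC values are µm²/ms (= 10⁻³ mm²/s); the fit runs in mm²/s
  and the 10³ factor is applied once at the type boundary.
- Validity floor: voxels with any fitted signal ≤ max(10⁻⁶ × series max, 0)
  are masked invalid rather than fitted; the floor is configurable and
  recorded on the map.
- Negative fitted ADCs are retained and flagged (clamping is a report-time
  option) so noise statistics stay unbiased.
- b-value subsets are a property of the sequence profile, not hard-coded:
  the standardized phantom sequence fits all of b = 0/500/900/2000 s/mm²,
  the anatomy-specific sequences fit b = 150/500 only (b = 0 is excluded to
  dodge perfusion-driven pseudo-diffusion).

## ROI conventions

- Circular vial ROIs use the pixel-center-inside-circle test in the
  centered physical frame; a sub-pixel circle still claims the nearest
  pixel. Statistics pool valid voxels across the ROI slices (the pooled
  mean equals the count-weighted mean of the per-slice means, which are
  also reported).
- "Central three slices" means the lower-median slice and its two
  neighbors: slices (n−1)//2 − 1 … (n−1)//2 + 1.
- Two ROI diameters are used deliberately: 10 mm for the manual
  map-comparison convention (inline vs. offline maps), and 20 mm (≈2/3 of
  the 30 mm vial diameter) for the automated conformance battery, which
  emulates vendor software's automated whole-vial ROIs. The choice matters:
  the repeatability metrics scale as (within-ROI CV)/√N, so a 10 mm ROI at
  full in-plane resolution (≈320 voxels over three slices) leaves the
  short-term CV expectation near its 0.5 % tolerance at SNR 75, while the
  whole-vial ROI (≈1300 voxels) sits comfortably inside it — matching how
  automated conformance analyses behave in practice.
- Organ masks are "contained" only if their source did not clip them
  against the field of view and they touch neither boundary slice;
  non-contained organs are excluded from aggregation (never silently
  zeroed) and day-1-only organs report CV_BS as N/A.

## Conformance battery

Tests A–G follow the Diffusion Profile: A accuracy (|bias| ≤ 3.6 %, water
vial, day-1 first repetition); B short-term repeatability over four same-day
repetitions (RC_ST ≤ 0.015 µm²/ms, CV_ST ≤ 0.5 %); C between-session
repeatability over the first measurements of two consecutive days
(RC_BS ≤ 0.065 µm²/ms, CV_BS ≤ 2.2 %); D linearity over all 13 vials
(R² > 0.9, 0.95 ≤ slope ≤ 1.05); E precision (CV_P < 2 %); F SNR at b = 0
(≥ 50); G b-value dependence (max Dep_b < 2 %). RC = 2.77 × wSD with wSD the
sample SD (n−1 denominator; for n = 2 this is |x1−x2|/√2).

Interpretation choices where the profile's operational definitions are not
public, all switchable and logged:

- **CV_P** is read as the *spatial* within-ROI CV of a single repetition —
  the only reading computable "from the first repetition only".
- **Dep_b** compares each two-point ROI-mean ADC against the all-b fit; the
  maximum pairwise-vs-pairwise spread is reported secondarily. Note that a
  corruption confined to one shell (e.g. a noise floor at b = 2000) drags
  the all-b reference too, so the Dep_b-vs-reference worst pair can be a
  *clean* pair; the per-pair ADCs themselves are exposed for unambiguous
  attribution.
- **Test A basis**: first repetition by default; `bias_basis="mean4"`
  averages the four repetitions instead.
- Missing sessions yield explicit N/A results (value `None`), never silent
  zeros or failures; a degenerate noiseless SNR is reported as infinite
  with a flag.
- Inclusive tolerance bounds accept machine-precision boundary hits (a
  uniform +5 % ADC offset produces a linearity slope of exactly 1.05, which
  must not fail on the last floating-point ulp); strict bounds stay strict.

## Multi-scanner aggregation

Per scanner and vial, the day-1 repetitions are averaged into an
intra-scanner mean ADC and mean bias; per vial, the inter-scanner mean bias
is the unweighted mean of per-scanner biases and the inter-scanner CV is the
CV of the per-scanner day-1 mean ADCs (computed on ADC means, not on bias
values — identical up to the reference constant); the grand row is the
unweighted mean over vials. Aggregating the printed per-vial columns of the
published three-scanner study reproduces its grand row to within the
rounding of the printed inputs (the 13 two-decimal CV entries average to
1.0754, which is consistent with an unrounded mean printing as 1.07).

## The synthetic world

The generator states, rather than measures, a world:

- 13 vials at the packaged reference diffusivities (1.109/0.817/0.579/
  0.380/0.220/0.110 µm²/ms at 0 °C), nominal geometry (15 mm vial radius,
  inner/outer rings at 40/70 mm, ring order clockwise from 12 o'clock,
  40 mm slab), uniform S0 = 1000 in every vial, background at 0.1 % of S0.
- Default grid: 0.859 mm in-plane pixels (256² over a 220 mm FOV) and 5 mm
  slice spacing, mirroring the standardized phantom sequence; only the 9
  central slices covering the vial slab are generated (the clinical stack's
  outer slices hold background only — a pure compute saving).
- Rician noise: equal-SD Gaussian noise on real and imaginary channels,
  then magnitude, with SD = S0/SNR so that mean/SD at b = 0 in the water
  vial equals the requested SNR (default 75, the middle of the 71–79 range
  a conformant 1.5 T system measures).
- Scanner and session effects are multiplicative ADC offsets (bias % per
  scanner, drift % per day, compounded) — the minimal mechanism that
  reproduces inter-scanner bias/CV structure. Noise streams derive
  deterministically from (seed, scanner, day, repetition).
- Toy in vivo volumes are disjoint ellipsoidal "organs" at stated ADCs
  (realistic organ magnitudes run ≈0.6–2.2 µm²/ms); an organ crossing the
  grid boundary is clipped and flagged truncated, which exercises the
  containment rule.

What the generator does **not** emulate — and hence what a green test does
not establish: T2 differences between fills (high-PVP vials keep full S0
here but lose signal on real scanners), susceptibility/eddy-current
distortion, coil shading (a single optional parabolic multiplicative field
exists, labeled non-physical, off by default), perfusion/IVIM at b = 0,
motion, and k-space/EPI reconstruction effects. Conformance pass rates
measured on this world quantify noise-propagation behavior only.

One consequence worth recording: under this minimal world the error profile
across vials for the 4-b-value fit is **U-shaped**, not monotone in
reference ADC. Propagating Rician noise through the log-linear fit gives a
per-voxel ADC SD whose relative size is ≈5.9 % for water (dominated by the
b = 2000 shell at SNR ≈ 8), falls to ≈4 % at mid diffusivities, and rises
again to ≈9.5 % at 0.110 µm²/ms. The monotone "worse at lower diffusivity"
trend that phantom studies report therefore needs mechanisms excluded here
(PVP T2 shortening, distortion near concentrated vials) — except for the
two-b-value 150/500 fit, where decay over the narrow b window is small, the
absolute ADC noise is nearly constant across vials, and the relative error
genuinely blows up as ADC → 0. The degradation trend is accordingly
asserted on the two-b-value fit.

## Determinism and tolerances

Identical (config, seed) pairs reproduce series bit-for-bit; pipeline
outputs (CSV) are byte-identical across reruns. Noiseless round trips are
asserted at ≤10⁻⁹ relative error (closed-form limit), analytic oracles at
10⁻¹⁰–10⁻¹², and Monte-Carlo checks at explicit multiples of their standard
errors, with SNR levels chosen so the systematic effect under test dominates
seed-to-seed scatter.

## Known limitations

- DICOM input requires the optional `pydicom` dependency and supports only
  single-frame series with standard b-value/rescale tags; NIfTI plus
  plain-text sidecars is the canonical dialect.
- The 2022 revision of the conformance protocol (five b-values to 2000
  s/mm²) is not built in; the b-value list and tolerances are configuration,
  so a revised battery can be expressed, but no packaged profile for it is
  provided.
- Reference diffusivities are serial-number specific; the packaged layout
  is a synthetic stand-in carrying the published values and should be
  overridden with the calibration sheet of a physical phantom.
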