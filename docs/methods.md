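# Methods

This note documents the models implemented in `albind`, the defaults they
ship with, what the synthetic-data generators do and do not emulate, and
the numerical choices that matter when reproducing results.

## Fluorescence corrections and window intensities

Raw emission spectra are corrected in two steps. Buffer background is a
pointwise subtraction requiring bit-identical axis grids — the package
never interpolates or resamples, because silent regridding corrupts
quantitative ratios; mismatched grids are an error. The inner-filter
effect (attenuation of excitation light and re-absorption of emitted
light by the optically active titrant) is undone multiplicatively,

    F_cor = F_obs · 10^((A_ex + A_em)/2),

with A_ex and A_em the absorbances of the mixture at the excitation
wavelength and at the emission-window center. Both absorbances are
recorded per titration point in the series manifest, since the absorbing
titrant concentration changes at every addition; A_em is a single scalar
sampled at the window center, matching the single-scalar form of the
correction. Background subtraction happens at manifest load time (the
buffer spectrum lives in the manifest, not in the series), the
inner-filter step inside quenching-curve construction.

All downstream ratios use the *window-integrated* intensity: the sum of
signal samples in a closed 10 nm interval around the emission maximum
(endpoints inclusive; width 0 degenerates to the nearest sample). Summing
rather than trapezoid-integrating matches the usual practice of adding up
a fixed section to suppress noise, and the closed-interval rule makes the
sample count deterministic.

## Stern–Volmer analysis

F₀/F against quencher concentration is fitted by ordinary least squares
over the first `n_points` samples (default 7). The truncation exists
because at extreme quencher concentrations closely spaced
fluorophore–quencher pairs act as instantaneously quenched "dark
complexes" and bend the plot upward; the curvature flag is nevertheless
judged on the *full* curve (sign of a quadratic term, flagged linear when
the quadratic contribution at the top concentration is under 1% of the
curve's span) so the bend is reported even when the fit excludes it. The
intercept is fitted freely rather than pinned at 1: an intercept far from
1 is a diagnostic for correction errors. The Pearson correlation is
reported on the fitted subset via r² = 1 − SS_res/SS_tot, which returns
exactly ±1 on collinear input.

The bimolecular quenching constant is k_q = K_SV/τ₀ with τ₀ = 10⁻⁸ s
(unquenched Trp lifetime), enforced as a constructor identity. Mechanism
classification fits K_SV linearly against temperature: a relative change
across the temperature span below the tolerance (default 5%, explicit and
configurable because "essentially constant" is otherwise subjective) is
called a static+dynamic combination; a larger decrease is static
(ground-state complex dissociating on heating); a larger increase is
dynamic (faster diffusion). With only three temperatures a hypothesis
test is not meaningful, so the call is a sign-plus-tolerance rule, by
design. The diffusion-limit flag trips when k_q at the highest
temperature exceeds 2.0×10¹⁰ M⁻¹s⁻¹, the ceiling for purely collisional
quenching.

## Binding model

At micromolar protein concentrations bound ligand is a sizeable fraction
of total ligand, so free ligand comes from the exact 1:1 mass balance
(quadratic in L_free); the implementation evaluates the
cancellation-free branch of the root formula and agrees with a bisection
solver to better than 10⁻¹⁰ relative error over eight decades of
parameters. The signal model is a two-state fluorophore,

    F/F₀ = 1 + (r_sat − 1) · L_free/(L_free + K_D),

i.e. the ratio is affine in site occupancy with a fitted plateau r_sat
(< 1 for quenching, > 1 for enhancement; the parameterization is
sign-free so both experiment types fit identically). One class of
independent sites with stoichiometry 1 is assumed; no Hill exponent or
Scatchard-style site count is fitted, because a single titration cannot
identify one and linearized binding plots invalidate least-squares
assumptions.

The optimizer is trust-region least squares on (log K_D, r_sat) —
positivity of K_D by construction — initialized at the geometric midpoint
of the sampled nonzero ligand range, with 10⁻¹² relative tolerances.
`free_ligand_at_half`, the interpolated free-ligand concentration at
half-maximal signal change, must equal K_D by construction of the model;
it is reported as an internal consistency check, not an independent
estimate. A titration ending below 95% occupancy sets
`saturation_reached=False` with a warning (the amlodipine design tops out
near 73% occupancy, so its K_D carries a larger standard error — visible
in the fit report). ΔG = −R·T·ln(c⁰/K_D) uses R = 8.314 J mol⁻¹ K⁻¹ and
c⁰ = 1 mol/L, in kJ/mol.

Binary-vs-ternary comparison calls the affinity `unchanged` when the K_D
ratio is within 10% of 1 (default, configurable — a numeric criterion has
to be explicit), `enhanced` when the ternary K_D is smaller beyond the
threshold, `weakened` otherwise. Both fits must share a temperature.

## Circular dichroism

Mean residue ellipticity uses the convention MRE = θ/(10·n·c·l) with θ in
millidegrees, c the molar protein concentration, l the path length in cm
and n = 585 residues for HSA. The α-helix estimate samples MRE at the
grid point nearest 208 nm and applies

    α-helix % = −(MRE₂₀₈ − MRE_β)/(MRE_α − MRE_β) × 100,
    MRE_α = 33,000,  MRE_β = 4,000.

The equation is implemented sign-for-sign as published. Note its
calibration quirk: it returns 100% at MRE₂₀₈ = −25,000, not −33,000, so
strongly helical signals can exceed 100%; out-of-range values raise a
plausibility warning but are returned unclipped. Replicate spectra are
reported as mean ± SD (ddof = 1).

Near-UV spectra (250–340 nm) are brought to a common baseline by
subtracting the ligand-free protein spectrum on an identical grid, then
summarized as the mean signed change in the tyrosine (275–287 nm) and
tryptophan (285–305 nm) closed windows; the 285–287 nm overlap counts in
both, as the windows are conventional, not exclusive.

## FT-IR amide I decomposition

Proprietary Fourier self-deconvolution workflows are not reproducible
from published settings, so the package uses a transparent equivalent:
component candidates are the deepest minima of a Savitzky–Golay-smoothed
second derivative of the 1600–1700 cm⁻¹ envelope, and a sum of Gaussians
(centers bounded to the region, sigmas in (0, 30] cm⁻¹) is refined
jointly by least squares with 10⁻¹⁵ step/cost tolerances. Bands are
returned in decreasing amplitude order; the seed only breaks exact
amplitude ties, the fit itself being deterministic. Assignment maps the
*rounded* center through ordered, non-overlapping closed wavenumber
intervals — default [1645, 1652] random coil, [1652.01, 1662] α-helix,
[1663, 1672] β-turn — configurable per run because published assignments
in this region overlap (1652 cm⁻¹ appears in the literature as both
random coil and α-helix depending on the sample).

Resolvability limit: second-derivative seeding needs each component to
leave a distinct curvature minimum. Components ~4 cm⁻¹ apart with
FWHM ≈ 8 cm⁻¹ (e.g. a 1648/1652/1656 triple) merge into one envelope and
cannot be seeded; the initialization error is raised rather than
guessing. Gaussian (not Voigt) line shapes are used — adequate for
assignment-level conclusions, not for quantitative area fractions, which
are out of scope.

## Synthetic data

The generators emulate the study design the analyses target: 5 μM HSA
titrated with amlodipine (0, 3.9, 7.8, 15.6, 31.25, 62.5, 125, 250,
333.3, 500 μM) or quercetin (0, 1.95, 3.9, 7.8, 10.4, 15.6, 20.8, 31.25,
41.6, 62.5, 83.3 μM) at 298.15/303.15/310.15 K; ligand-into-protein
enhancement titrations; far-UV CD at 1 μM protein and 1 mm path across
molar ratios 0–4; amide-region IR. Titration spectra are Gaussian
emission bands (center 347 nm, σ 25 nm) whose amplitude carries four
factors: the occupancy-linked static term 1 + (r_sat−1)·occupancy, the
collisional term 1/(1 + k_dyn·L_free), an optional sphere-of-action
dark-complex term exp(−V·L_free), and the embedded inner-filter
attenuation 10^(−(A_ex+A_em)/2) with per-point absorbances proportional
to titrant concentration — so the analysis-side correction inverts it
exactly in the noise-free case. The band center shifts blue linearly
with occupancy when enabled. Plateau defaults (r_sat = 0.10 for
quercetin, 0.15 for amlodipine) reflect the near-complete quenching the
titration figures show; extinction scalars put the top-of-series
absorbances near 1 for quercetin (whose inner-filter bias is the reason
the correction exists) and near 0.5 for amlodipine.

Ternary titrations either solve the coupled two-ligand one-site
equilibrium exactly (bracketed root finding on the free-protein
concentration, monotone residual, machine-precision tolerances; mass
balances close to < 10⁻¹² relative) or apply a phenomenological
cooperative K_D multiplier — the cooperative mechanism is a narrative,
not a mechanistic model, and is represented as such. With zero
competitor both modes reduce bitwise to the binary generator.

Noise is multiplicative Gaussian on fluorescence intensities (relative
SD 0.01 by default, the regime of shot-noise-dominated photon counting)
and additive in millidegrees/absorbance on CD/IR. Every generator is
bitwise-deterministic under a fixed seed.

What the generators do **not** emulate: photobleaching, instrument
drift, Raman/scatter peaks, polarization effects, wavelength-dependent
detector response, or deviations from the 1:1 (plus one competitor)
binding scheme. Passing round-trip tests therefore demonstrates that the
analysis inverts its own forward physics correctly — estimator
correctness and robustness to measurement noise — not that real
instrument data are free of the systematic effects above.

## Problem sizes and determinism

Test and acceptance runs use the study-sized designs directly (10–11
titration points, ~200-sample spectra, 20-replicate noise studies,
10⁴-triplet solver cross-checks); all are desk-scale and complete in
seconds. Reports embed the configuration hash and seed, contain no
timestamps, and rerun byte-identically under a fixed configuration.

## Known limitations

- The helix estimator's published end-member calibration saturates at
  −25,000 deg·cm²·dmol⁻¹ (see above); values are reported as defined.
- Mechanism classification from three temperatures is a tolerance rule,
  not an inference; borderline trends land on the configured threshold.
- The amide-I decomposition cannot separate components closer than the
  second-derivative resolvability limit (~½ FWHM), and band areas are not
  interpreted as structure fractions.
- ΔG values computed from rounded published dissociation constants can
  differ from published energies in the third decimal, because rounding
  K_D to 0.01 μM propagates ~0.001–0.005 kJ/mol into R·T·ln K_D.
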