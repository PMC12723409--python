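# Methods

This note documents the models, the numerical choices, what the synthetic
generators emulate, and the known limitations of `axonsf`.

## Signal model for restricted diffusion

The intra-axonal space is modeled as impermeable parallel cylinders.  For a
pulsed-gradient spin-echo (PGSE) experiment with gradient strength G,
duration δ and separation Δ, the diffusion weighting is
`b = γ²G²δ²(Δ − δ/3)`.  Perpendicular to a cylinder of radius R the
Gaussian-phase-distribution (GPD) approximation gives

    −ln S⊥ = γ²G² Σ_m B_m [2κ_m δ − 2 + 2e^{−κ_m δ} + 2e^{−κ_m Δ}
                            − e^{−κ_m (Δ−δ)} − e^{−κ_m (Δ+δ)}] / κ_m²

with κ_m = D₀ a_m²/R², B_m = 2R²/(a_m²(a_m²−1)), and a_m the positive roots
of J₁′.  The series uses the first 20 roots; adding five more changes the
signal by < 1e-8 across the protocol's parameter range (tested).  The same
expression is validated against an independent implementation that
evaluates the underlying phase-variance time integrals by adaptive
quadrature (`tests/oracles.py`); the two agree to better than 1e-7.

Because −ln S⊥ and b are both proportional to G², the apparent
perpendicular diffusivity `D⊥ = −ln S⊥ / b` depends only on (R, δ, Δ, D₀).
Shells sharing the timing therefore share one D⊥ exactly, which is what
justifies fitting a single D⊥ across the three shells.  In the wide-pulse
regime relevant here, −ln S⊥ ∝ R⁴/D₀, so the inverted diameter scales as
D₀^¼ — weakly dependent on the intrinsic diffusivity (tested: doubling D₀
changes the diameter by a factor of ~1.19).

The orientation-averaged (powder / spherical-mean) signal of an axially
symmetric compartment is

    S̄/S₀ = va · e^{−b D⊥} · √(π/(4x)) · erf(√x),   x = b(D∥ − D⊥),

with a 3-term Taylor branch for x < 1e-6 (isotropic limit).  Validated to
1e-4 against a 20 001-direction arithmetic mean.

## Parameter estimation

Per voxel, signals are normalized by the voxel-wise mean of the b = 0
images (b < 50 s/mm² counts as b = 0), averaged per shell across the 30
directions, and fitted by trust-region bounded least squares over
(va ∈ [0,1], D⊥ ∈ [0, D₀]) with tolerances 1e-10 and a 5-point multi-start
grid — the objective has a shallow valley at low D⊥ and a near-degenerate
ridge at the isotropic corner, where va and D⊥ trade off at second order
and the bound is reached only to ~1%.  The diameter is obtained by Brent
bisection of the monotone forward map on R ∈ (0, 10] µm; estimates needing
R > 10 µm are capped at d = 20 µm and flagged.  D⊥ = 0 maps to d = 0 and is
tracked as a distinct "zero" state; 0 < d < 0.1 µm is "discarded"; both are
excluded from distribution summaries but counted.

D₀ is either fitted per brain as the principal eigenvalue of a log-linear
diffusion-tensor fit to the lower-b single-shell data (eigenvalues averaged
over ROI voxels) or taken from configuration.  The configured default is
**0.45 µm²/ms**: this is mid-range for fixed ex vivo white matter at room
temperature (literature ~0.3–0.6; in vivo values are 3–5× higher and do not
apply to fixed tissue), and it reproduces the acquisition's published
sensitivity band (below).

## Sensitivity of the acquisition to diameter

For each ground-truth diameter on a 0.2–15.0 µm grid (0.2 µm steps, 75
points) and 50 repeats, single-cylinder signals are generated for the full
protocol (30 directions × 3 shells + 9 b = 0 images, va = 1), corrupted
with Rician noise (magnitude of complex Gaussian noise, both channels SD
1/SNR, SNR = 50), powder-averaged, fitted, and inverted.  Noise is applied
to each directional measurement *before* averaging by default (mirroring
the acquisition; the alternative, one draw on the powder average, is
available via `noise_on="powder"`).

The accuracy band is summarized as the longest contiguous grid run whose
median estimate stays within 25% of truth — an explicit operationalization
of a visual bound; the threshold is always reported with the result.  At
the defaults this yields roughly 2.2–6.6 µm; below ~2 µm estimates collapse
toward zero (the Rician floor of the many near-extinguished directional
measurements flattens the b-dependence, biasing D⊥ low by ~30% at SNR 50),
and above the band estimates saturate and under-report.  Consequently the
estimator-calibration test perturbs the spherical means with *unbiased*
Gaussian noise of SD 1/(SNR·√30) — the central-limit precision of direction
averaging — which isolates the least-squares machinery from the magnitude
bias; the magnitude pipeline end to end is characterized by the sensitivity
profile itself.

## EM morphometry

Axon components are labeled with 8-connectivity after hole filling; every
myelin pixel is assigned to the nearest axon component, splitting shared
myelin between adjacent fibers along the equidistance line; myelin touching
no axon becomes an orphan candidate.  Exclusion rules, applied in order and
each counted: no axon, no myelin, area < 10 px (a moment ellipse is
meaningless below that), overlap with the 4-pixel image border, myelin
perimeter coverage below threshold, eccentricity above threshold.
Coverage is the fraction of axon outer-boundary pixels with a myelin pixel
in their 8-neighborhood; eccentricity uses the normalized-second-moment
ellipse convention √(1−(b/a)²) on the axon (inner) blob.  Thresholds:
epon (coverage ≥ 0.95, ecc ≤ 0.92), cryo (coverage ≥ 0.85, ecc ≤ 0.975).
Diameters are **minor axes** of moment ellipses (inner: axon pixels;
outer: filled axon+myelin), so obliquely cut axons are not overestimated;
g = inner/outer minor axis.  Pixel size must already include any upstream
downsampling; no resampling happens here.

Distribution summaries: mean, SD (ddof = 1), mode as the argmax of a
Gaussian KDE (Silverman bandwidth, 512-point grid over
[max(0, min−3h), max+3h]), and the linearly interpolated 90th percentile.

## Structure–function conversion and shrinkage

All conversions are exact algebra with units locked at the interface
(L mm, TCT ms, d µm, CV m/s): `CV = L/TCT = (5.5/g)·d`.  Defaults: g = 0.64
(EM group mean) for the rat pathway, g = 0.7 (literature optimum) for the
human extrapolation; L = 11.47 mm.  Shrinkage factors are computed on the
mode and p90, the general factor is their average, and correction divides
by (1 − s/100) — the exact inverse of the definition (a multiplicative
variant is available behind a flag).  The MR-weighted diameter is
`d_w = 2(⟨R⁶⟩/⟨R²⟩)^¼ ≥ mean`, with equality only for monodisperse samples.

## LFP latency detection

Stereotrode channels are averaged per trial, trials averaged, and the
result baseline-corrected (default window −50 to 0 ms; the window length is
a convention, not a measured quantity).  P1 is the first strict local
maximum with positive amplitude in (+1, +9) ms; N1 the global minimum in
(+5, +20) ms.  Peaks must additionally exceed a noise floor of 3× the SD of
the pre-stimulus segment of the averaged trace (0 when no pre-stimulus
samples exist): without it, sample-level noise wiggles at the window edge
masquerade as "first" maxima.  Reliability: CoV = SD/|mean| (ddof = 1) of
the per-trial, baseline-corrected channel-mean amplitude at the N1 latency;
reliable when < 1.00.  The absolute value of the mean is used so that a
sign convention cannot rescue an unstable response.  An N1-onset metric
(first post-P1 negative-going zero crossing) is provided but flagged
experimental — it has no standard operational definition.

## What the generators emulate — and what they do not

* **Diameter laws**: gamma (default) or lognormal, with parameters solved
  numerically from (mode, p90) targets.  Defaults: epon-like mode 0.31 /
  p90 0.66 µm; cryo-like mode 0.39 / p90 1.42 µm.  Real distributions are
  not exactly gamma; the generators encode right-skew and the two
  preparations' calibration targets, nothing more.
* **Masks**: non-overlapping rotated ellipses (minor axis = drawn diameter)
  with annular myelin at per-axon g ~ N(0.64, 0.05) clipped to (0.4, 0.9),
  rendered at 0.005 µm/px on a 2560² canvas, largest first; packing gaps
  exceed the myelin thickness so nearest-axon assignment is provably
  correct.  Diameters below 0.12 µm are resampled — the mask emulates the
  population the pixel grid can represent.  Injectable violations (border,
  unmyelinated, high eccentricity, partial coverage) carry truth flags.
  Real EM texture, debris, touching fibers and segmentation errors are not
  emulated; passing tests show the *rules* are implemented correctly, not
  that any particular segmentation network is accurate.
* **dMRI**: per-voxel single-orientation cylinder signals via the effective
  D⊥ (exact for this acquisition), va = 0.7, Rician noise at SNR 50.  In the
  synthetic study each voxel's truth diameter is the tissue law's d_w — the
  quantity a voxel effectively reports in the wide-pulse limit.  Orientation
  dispersion, exchange, extra-axonal and "dot" water are not simulated (the
  model assumes they are negligible at b ≥ 17 560 s/mm²).
* **LFP**: Gaussian P1 (+15 µV at 5.6 ms, σ 0.8 ms) and N1 (−40 µV at
  11.8 ms, σ 2.5 ms) deflections, per-trial gain jitter (5%), constant
  offsets, two channels with 3% gain mismatch, and band-limited noise
  (white noise smoothed over 0.5 ms — LFP power lives far below the 15 kHz
  Nyquist; unsmoothed white noise makes any first-peak rule meaningless).
  Note the broad N1 flank shifts the composite waveform's true maximum
  ~0.07 ms before the injected P1 center; detection is exact on the
  waveform, and sub-sample recovery is asserted only for isolated bumps.

## Problem sizes and determinism

The shipped study and test sizes — 20 000 diameters per EM-like modality,
4×4×4 dMRI voxels, 75 × 50 sensitivity repeats, 1 000 calibration repeats,
50–60 axons per mask — are chosen so every stochastic check is stable under
its documented seed while the whole suite remains quick to run.  All
randomness flows through `numpy.random.default_rng(seed)`; every generator
returns bit-identical output for a fixed seed, and the study report is
byte-identical JSON for a fixed seed.

## Known limitations

* The uniform (averaged) shrinkage correction cannot restore a tail that
  shrank more than the mode: with the default calibrations the
  corrected epon-like d_w remains ~35–40% below the cryo-like d_w.  This is
  a property of averaging a diameter-dependent shrinkage, not a numerical
  artifact; a diameter-resolved correction would be required to close it.
* The sensitivity band depends on D₀ (as D₀^¼) and on SNR; both are study
  constants here, not estimated per dataset.
* The GPD approximation itself degrades for very large radii and strong
  gradients; within the simulated band its error is far below fitting noise.
* Tract length enters only as a scalar; no tractography is performed.
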