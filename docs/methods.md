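# Methods

This note documents the models, algorithms and numerical choices behind
`cannaqnmr`, and what the synthetic-data tests do and do not demonstrate
about real CBD-oil spectra.

## Signal model of the simulator

A free induction decay is synthesized as a sum of transitions

    s(t) = Σ_k a_k exp(2πi ν_k t) E_k(t) + ε(t)

with `E_k(t) = exp(−t/T2*)`, `T2* = 1/(π·FWHM)` for analyte lines
(Lorentzian lineshape) and a Gaussian envelope for the triglyceride matrix
bands, and ε complex Gaussian white noise. Amplitudes are proportional to
molar concentration × proton count × saturation factor × NS × RG, so the
PULCON algebra holds by construction and acquisition-parameter invariances
can be tested exactly. Multiplets split by J with binomial ratios (doublet
1:1, triplet 1:2:1, quintet 1:4:6:4:1); an unresolved multiplet is modeled
as a narrow symmetric 3-line cluster.

Key defaults, with rationale:

| parameter | default | why |
|---|---|---|
| analyte FWHM | 1.2 Hz | sharp small-molecule lines in CDCl₃; 1.5 Hz after the 0.30 Hz exponential apodization |
| CBD hump FWHM | 40 Hz | broad aromatic resonance from hindered rotation; single Lorentzian at 6.20 ppm, 2 protons |
| noise σ | 72 (complex, per FID point) | places a 140 mg/L Δ⁹-THC doublet at S/N ≈ 50 after default processing, i.e. near the method's practical detection regime |
| shift drift | 0 ppm per g/L CBD (configurable) | the Δ⁹/Δ⁸/hump positions move with CBD content in real oils; sweeps use −0.0004 ppm·(g/L)⁻¹ |
| matrix bands | 7 Gaussians (hemp), 5 (MCT) at the suppression-band centers, ≥100× analyte amplitude | MCT oil lacks the bis-allylic (2.77 ppm) and olefinic (5.34 ppm) bands of hemp seed oil |
| TMS | pseudo-analyte, 324 mg/L × 12 H | 0.05% v/v reference in the solvent; a truly blank composition yields a truly zero FID |
| QR saturation | exactly 1/κ (1.30 TCNB, 1.22 EB) | makes the round trip through the κ-corrected ERETIC factor closed-form; a physical `1 − exp(−TR/T1)` mode exists but is not the default |
| acquisition | SF 400.0 MHz, TD 131,072, SI 262,144, SW 20.5617 ppm, NS 64, RG 16, D1 6 s, 300.0 K | the multiple-suppression quantification experiment; TD counts real+imaginary points (Bruker convention), AQ = TD/(2·SW_Hz) ≈ 7.97 s |

Hz↔ppm conversions of tabulated constants (band edges, drift) use the
nominal 400.0 MHz, at which the printed band conversions (e.g. 2156 Hz =
5.39 ppm) are exact.

The calibration-series generator spikes one analyte over a constant matrix
(default: pure hemp seed oil — a valid matrix choice for the spiking design,
preferred over a CBD-containing oil so the spike is the only varying
component) with independent noise per level and an optional multiplicative
area jitter that emulates integration-level measurement scatter.

### Band suppression

`apply_suppression` emulates the acquisition-time saturation of the lipid
bands as FFT → mask → inverse FFT. Two details matter. The attenuation
profile reaches its residual through raised-cosine skirts *inside* the band,
so out-of-band content is untouched and the notch's impulse response decays
quickly. And the mask is applied to the conjugate-symmetric (two-sided)
extension of the FID, whose spectrum is purely absorptive: masking the
causal FID directly would also clip the 1/f dispersion tails of every
distant signal — a ~2% artifact that physical band saturation does not
produce.

## Processing

`process` applies, in order: exponential apodization (LB 0.30 Hz), zero
filling to SI, FFT with first-point halving (removes the DC offset of the
discrete Lorentzian transform), automatic phasing, automatic baseline
correction, and TMS referencing. Each step is logged in the spectrum's
provenance with its parameters.

* **Auto-phase.** Zeroth + first order, chosen by minimizing the entropy of
  the first derivative of the real part plus a strong (×1000) penalty on
  negative absorption, after a 5° zero-order grid search (Nelder-Mead
  refinement; spectra are subsampled to ≤32k points for the objective). The
  applied angles are recorded; a flat spectrum is returned unchanged and
  flagged.
* **Baseline.** Asymmetric least squares (Whittaker smoother, λ = 10⁷,
  p = 0.001, 10 iterations) with the signal-library windows and the
  external-standard ranges excluded from the anchor set, so the fitted
  baseline interpolates beneath the peaks and beneath the CBD hump rather
  than eating them. Long spectra are decimated to ≤16,384 nodes for the
  sparse solve and the baseline interpolated back — valid because the
  baseline is smooth by construction.
* **TMS referencing.** The axis is shifted so the maximum within ±0.2 ppm of
  0 sits at exactly 0 ppm. The candidate must exceed both 5× the robust
  noise (MAD) and 10⁻³ of the spectrum maximum; TMS is a dominant line
  whenever present, and the floor prevents numerical ripple in a TMS-free
  spectrum (e.g. the external standard) from being mistaken for it. Failure
  leaves the axis unchanged with a `no_tms` flag.

## Integration

Well-separated signals are integrated trapezoidally over fixed windows
(center ± 0.04 ppm; exact bounds are configuration, not physics). Signals
overlapped by the hump or matrix (CBD 4.63, Δ⁹-THC 6.15, Δ⁸-THC 6.12) are
fitted: two equal-area, equal-width Lorentzians separated by the library J,
plus a local polynomial baseline, over the detected maximum ± 0.02 ppm.

Numerical choices:

* **Local baseline degree 2.** A straight line under the shoulder of a
  40 Hz-wide hump leaves a curvature residual comparable to the doublet
  itself once the hump is tens of times taller; a quadratic tracks the
  shoulder to third order and keeps the recovered area within ±5% at 20×
  and ±10% up to 50× hump amplitude.
* **Candidate selection.** Within the search window (± 0.06 ppm hemp,
  ± 0.02 ppm for the Δ⁸/Δ⁹ pair in MCT oils, where isomer swapping was a
  problem), local maxima are detected after removing a line through the
  window edges; the candidate *nearest the library position* wins, with only
  a weak prominence filter (2% of the strongest), so a taller neighbouring
  isomer or the hump crest cannot capture the fit.
* **Significance.** A fitted amplitude below 3× its standard error is
  reported as `converged = False` with area exactly 0 — a noise-only window
  never contributes a concentration.
* **Swap guard.** Converged fits are deduplicated (two searches that locked
  onto the same peak within 0.004 ppm count once), then assigned: with two
  candidates the higher-shift one is Δ⁹ (6.15 ppm target) and the lower Δ⁸
  (6.12 ppm); a lone candidate goes to the nearer target, an exact tie goes
  to Δ⁹ and both entries are flagged ambiguous. The procedure is
  deterministic and order-invariant.

S/N is estimated as peak maximum over twice the noise-region SD, flagged
below the 250 guideline for quantitative work.

## Quantification and reporting

The PULCON relation and unit conversion are given in the README. Both QR and
sample must share the spectrometer frequency, and both must be acquired at
300.0 K (the generic temperature ratio of PULCON is replaced by this hard
equality check). Molar masses are computed from molecular formulas
(CBD/Δ⁹/Δ⁸ 314.47, CBN 310.44, TCNB 260.89, EB 106.17 g/mol) and verified by
an independent formula-mass oracle in the tests. Censoring (below-LOD → 0
with flag, LOD–LOQ → qualitative) is idempotent; CBD aggregates signals 1
and 3 (signal 2 at 4.52 ppm is matrix-biased and kept for QC only); CBN is
the mean of its uncensored signals — a mean was chosen over a per-signal
report and is configurable in the library. A control-sample check passes iff
the result lies within 2 SD of the precision mean.

## Validation statistics

* Calibration: OLS of area vs concentration; process SD `s_x0 = s_y/b`,
  procedural CV `100·s_x0/x̄` (the standard calibration-function definition).
* DIN 32645 calibration-line limits with one-sided t-quantiles, α = 0.05
  (LOD) / 0.025 (LOQ), m = 1 replicate, k = 3; the LOQ solves its implicit
  equation by fixed-point iteration from 3·LOD (tolerance 10⁻⁶, ≤100
  iterations; the iteration is strongly contractive so the converged value
  agrees with an independent brute-force evaluation to 10⁻⁹ relative).
  A property worth knowing: with these quantiles the LOQ/LOD ratio is
  ≈ 3·t(0.975;f)/t(0.95;f) times a factor slightly below 1, i.e. ~3.9 for a
  five-level design and never below ~3.5 for any design in which the LOQ is
  far below the calibration mean. Published per-signal limits for this
  method cluster near 3.1, which implies a different (unpublished)
  convention; this package deliberately keeps the standard-conforming
  formulas above.
* Precision: CV gated on a Shapiro–Wilk normality test at 95%; a failed gate
  flags the CV unreliable rather than suppressing it.
* Stability: pass iff the maximum relative drift from the series mean stays
  within 2× the measurement CV.
* Reference comparison: y = a·x + b regression of NMR on LC-MS/MS values for
  pairs above the LOD; outliers are flagged by *externally* studentized
  residual > 3 with sequential deletion (one gross outlier would otherwise
  mask another through the pooled scatter) and the regression is reported
  both with and without them; a two-sided paired t-test at 95% tests for a
  systematic offset.

## Problem sizes and test design

The acceptance computations run at the full acquisition size (TD 131,072,
SI 262,144). Unit tests use a reduced TD of 16,384 with the same spectral
width; at the resulting ~1 s acquisition time a 1.2 Hz line has not fully
decayed and zero filling would leave truncation ripple, so quantitative
small-size tests use 3 Hz lines, which decay completely. This is a test
design choice, not a method parameter. The Δ⁹/Δ⁸ swap-guard sweep covers 50
seeded cases over both matrices, single/dual/absent isomers, CBD 0–30 g/L
and shift drift.

## What passing tests do and do not show

The simulator reproduces the *structure* of the measurement problem —
relative intensities, overlap topology, suppression, saturation, noise — but
not: real lipid multiplet patterns (bands are single Gaussians), ¹³C
satellites, temperature-dependent lineshape of the CBD hump, solvent
artifacts, pulse-sequence physics of the NOESY presaturation, radiation
damping, or shimming imperfections. Recovery and linearity results on
synthetic data therefore validate the *algorithms* (processing, fitting,
censoring, statistics) under controlled truth, not the instrument method's
field accuracy; the published validation figures (recoveries of 35–135%
depending on concentration and signal) show how much harder real matrices
are. J-coupling constants in the library are field-typical defaults
(aromatic meta 1.7 Hz, CBN ortho 8 Hz), configurable per signal.

## Known limitations

* The doublet fit assumes the hump is locally quadratic over ±0.02 ppm; a
  hump narrower than ~20 Hz directly beneath a doublet would bias the area.
* The swap guard's nearest-target rule is reliable for drifts up to
  ~0.015 ppm; beyond that (CBD ≳ 40 g/L at the sweep's drift rate) Δ⁹ drifts
  into Δ⁸'s half-space and only the narrowed MCT windows protect assignment.
* JCAMP-DX support covers the package's own AFFN `(X++(Y..Y))` export, not
  the full standard; Bruker directory support covers `fid` + `acqus` with
  int32/float64 payloads.
* Auto-phasing assumes mostly-absorptive spectra with several resolved
  peaks; pathological dispersion-only inputs converge to a flagged result.
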