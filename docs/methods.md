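# Methods

This note records the models, parameter choices and numerical conventions
behind `ldctsim`, in the order the pipeline runs them.

## Coordinate and unit conventions

All geometry is metric (mm) with the origin at the center of every grid:
pixel *i* of an *n*-pixel axis sits at `(i − (n−1)/2) · pixel_size`, for
phantoms, detector bins and reconstructed images alike.  Attenuation is
stored in Hounsfield units and converted to linear attenuation via
`µ = µ_water · (1 + HU/1000)` with `µ_water = 0.0192 mm⁻¹`, a typical
effective-energy value for a 100–120 kV beam; the same constant travels
with each sinogram so projection and reconstruction always agree.

## Phantoms

Two digital phantoms stand in for the physical ones, as single 2-D slices
(512 px / 250 mm field of view by default); per-slice ROI analysis makes
the 2-D reduction adequate for noise questions.

* **Water cylinder** (20 cm, 0 HU on −1000 HU air): the noise-calibration
  phantom.
* **Head phantom**: soft-tissue ellipse (semi-axes 65 × 80 mm, +40 HU)
  with a 6-mm skull ring (+1200 HU) and four contrast-filled tubes
  attached laterally in air — syringe-sized, 20 mm diameter, two per side
  at x = ±78 mm, y = ±11.5 mm.  The two dilution levels default to 290 and
  370 HU; the tubes are arranged diagonally so the two dilutions' pixel
  sets are exact mirror images and the pooled tube mean is exactly
  330 HU, a typical contrast-enhanced vessel attenuation.  Tube positions
  and diameters are plausible defaults (no reference geometry exists) and
  fully configurable in `PhantomSpec`.

Phantoms are sampled at pixel centers without anti-aliasing, so a map's
histogram contains only the specified material values (tests rely on
this); `supersample=k` averages a k× finer raster instead when smooth
edges matter more than exact histograms.

## Scanner model

Parallel-beam geometry, views uniform over 180°, detector bins spanning
the scan field of view.  A helical fan/cone beam would change nothing
about photon statistics, which is what dose simulation is about, so the
simplest verifiable geometry is used.  The forward projector is a
rotate-and-sum Radon transform (linear-interpolation resampling onto the
rotated frame, then column sums); it shares the package's symmetric
pixel-center convention with the backprojector.

Measurement: per ray, `λ = N₀·e^(−p)`; detected counts are
`Poisson(λ) + N(0, σₑ)`, floored at 1 count before the log (photon-
starvation guard).  If more than 1% of rays hit the floor the acquisition
warns, or raises in strict mode.  Quantum and electronic draws come from
disjoint substreams of one named seed, so acquisitions are bit-reproducible.

Free parameters, with defaults and rationale:

| parameter | default | meaning / why |
|---|---|---|
| `photons_per_mas` | 1000 | incident photons per ray per eff. mAs; anchored so the 20-cm water phantom at 200 eff. mAs reconstructs with ≈10 HU central-ROI noise under the default kernel — a realistic head-protocol noise level |
| `sigma_e` | 10 counts | electronic noise SD; negligible at full dose (<1% of ray variance), ≈30–50% of the quantum variance on central rays at 6.25% dose, i.e. it matters exactly where it should |
| `eff_mas` | per protocol | dose ∝ eff. mAs; the phantom study uses 160 with reductions to 120/80/40 |
| `kv_label` | "100 kV" | metadata only; the model is energy-agnostic |

## Noise insertion

`insert_noise` degrades a measured sinogram to dose fraction α.

* **gaussian** (default): adds `N(0, c·max(gap, 0))` in the line-integral
  domain, where `gap = v(αλ̂) − v(λ̂)`, `v(λ) = 1/λ + σₑ²/λ²`, and
  `λ̂ = N₀e^(−p̂)` is the plug-in estimate from the measured data (the
  standard practical choice; its bias is O(1/λ), far below Monte Carlo
  resolution here).  The clamp handles the numerically possible negative
  gap at α ≈ 1.  Unbiased by construction; variance matches a direct
  acquisition at α·N₀ to first order (verified against that oracle per
  ray and through reconstruction).
* **poisson**: binomial thinning `N' ~ Binomial(round(λ̂), α)` plus a
  Gaussian top-up of variance `σₑ²(1−α²)` restoring the full electronic
  noise after thinning, then re-log.  Honors count statistics exactly but
  admits no continuous calibration factor, so `calib_factor ≠ 1` is
  rejected in this mode.

Both modes record the reduced protocol (eff. mAs × α) and the cumulative
dose fraction, so composed insertions (α₁ then α₂/α₁) track provenance and
match the single-step result.

## Water-phantom calibration

`calibrate` fixes the factor *c* of the gaussian mode:

1. Acquire the water phantom at full dose `n_base = 8` times; the averaged
   central-ROI (5 cm) SD estimates the full-dose noise level, and the
   first acquisition becomes the base scan for insertion.
2. Predict the target SD at the target dose fraction (default 6.25%) as
   `SD_full · √(v̄_α/v̄_1)`, the ray-variance ratio averaged over the rays
   crossing the ROI, computed from the noiseless line integrals.  With
   σₑ = 0 this is exactly `1/√α`.
3. Iterate: insert noise at the target fraction with the current *c*
   (8 realizations on a fixed seed family), reconstruct, measure; update
   `c ← c · (SD_target² − SD_base²)/(SD_meas² − SD_base²)`.

Because the inserted image variance is linear in *c*, the update is a
one-step solve up to Monte Carlo noise; convergence (relative residual
≤ 1%) typically takes 2 iterations even from a ×4 mis-scaled start, and
failure within `max_iter = 20` raises with the last residual.  Averaging
the full-dose SD while using the base scan's own SD in the update keeps
the single-realization sampling error out of the converged *c* (it enters
with weight ≈ 1/15 at the 6.25% target).

## Reconstruction

Filtered backprojection with the discrete ramp filter built from its
real-space taps (correct DC response, so uniform objects reconstruct
without offset), apodized by choice of `ramp`, `shepp-logan`, or `hann`.
The Hann-apodized ramp is the default soft-tissue kernel: clinical kernel
responses (e.g. B31f) are proprietary, and a smooth apodization reproduces
their qualitative noise/resolution trade-off.  Backprojection uses linear
interpolation on a pixel-centered grid; default reconstruction field of
view is 180 mm, emulating a head-angiography reconstruction.  Requesting a
FOV beyond the detector support raises.  Accuracy at the default desk
scale (256-px raster, 360 views): noiseless water reconstructs to
0.0 ± 0.5 HU; tube attenuation is recovered within 0.5%.

## ROI analysis

An ROI is a disk in image millimeter coordinates; its pixel set is the
pixels whose centers fall inside (deterministic, resolution-dependent).
SD uses the n−1 denominator; SNR = mean/SD, flagged undefined when
SD = 0.  The standard tube ROI set places 10 disks (3+2+3+2, five per
dilution, 6 mm diameter) strictly inside the four tubes with ≈3 mm margin
against edge blur, essentially disjoint so their noise estimates are close
to independent — which the paired sign tests need.
`replicate_rois` applies one ROI set unchanged across a matched dose
series, emulating copy-and-paste ROI replication.

## Phantom experiment

`run_phantom_experiment` compares, per dose fraction (75/50/25% of
160 eff. mAs), true scans acquired at the reduced current against
simulations derived from the reference scan.  A physical study gets one
scan per level; here each level is repeated (`n_realizations`, default 10;
the validation runs use 24) so the comparisons have power at desk scale.
Noise is compared by exact paired sign tests on the per-ROI SDs
(realization-averaged), attenuation by Mann–Whitney tests; because the
per-ROI SD estimate carries ≈3–5% Monte Carlo error even after averaging,
the 5%-equivalence check is applied to the ROI-averaged SD per level,
where the error is ≈1%.  The experiment uses a 256-px raster and
256-px reconstruction (≈35 s for 24 realizations); all randomness flows
from one root seed through named substreams, making reports byte-identical
on re-run.

## Reader-study bookkeeping

The score ledger covers segments × patients × dose levels (40 × 30 × 4 by
default, 4800 cells); ordinal quality scores run 1 (no diagnostic vessel
definition) to 5 (excellent), dichotomized as nondiagnostic (1–2) vs
diagnostic (3–5).  An occluded or resected segment is absent from every
reconstruction of the same acquisition, so each excluded (segment,
patient) pair is removed at all dose levels — 34 pairs give 136 excluded
and 4664 scorable cells.  `synth_scores` fills a ledger from
`score = clip(round(a·ln(SNR) + b + ε), 1, 5)` with reader noise
ε ~ N(0, reader_sd²); defaults (a = 2, b = −2.5, reader_sd = 0.5) put a
full-dose vessel SNR ≈ 33 near "excellent" and a quarter-dose SNR near
"moderate".  This is a fixture standing in for human readers in end-to-end
runs — it models no real observer and supports no claims about human
performance.

## Statistics

* **Sign test**: exact binomial on sign counts, ties dropped, two-sided by
  doubling the smaller tail (capped at 1); all-tied input is vacuous
  (p = 1, warning).
* **Mann–Whitney U**: midranks; exact by full enumeration of group
  assignments for combined n ≤ 12 (two-sided extremity |U − n₁n₂/2|),
  normal approximation with tie-corrected variance and no continuity
  correction above that; the method note on each result records which
  path ran.
* **Cohen's κ**: unweighted, from the raters' confusion matrix, with the
  conventional agreement bands (≤0 none, ≤0.2 slight, ≤0.4 fair, ≤0.6
  moderate, ≤0.8 substantial, ≤1 almost perfect); undefined (NaN) when
  both raters use a single category.

All three are implemented from first principles and tested against
brute-force enumeration (n ≤ 10), scipy and scikit-learn.

## What passing tests do and do not show

The phantoms are piecewise-constant and artifact-free, the beam is
monochromatic and parallel, and there is no bowtie filtration, tube-current
modulation, scatter, beam hardening or detector cross-talk.  Passing the
true-vs-simulated equivalence here shows the noise-insertion mathematics is
correct under the stated measurement model; it does not show that real
scanner raw data, with modulated flux and filtered spectra, would be
simulated equally well — that requires the vendor-side corrections this
package deliberately leaves out.  Iterative reconstruction is likewise out
of scope (it would entangle de-noising with the inserted noise), as are
DICOM/vendor raw-data formats and dose metrics (CTDIvol/DLP).
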