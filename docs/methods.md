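# Methods

## The photophysical model

Dendra2 is tracked as a conserved molecular pool per cell (or pixel):
unconverted green protein *g*, converted red protein *r*, and
photodestroyed protein. Under illumination of irradiance *I* (W/cm²) the
pool evolves as a linear system,

    dg/dt = −(k_conv + k_bleach_g) · I · g
    dr/dt =  k_conv · I · g − k_bleach_r · I · r

with the bleached compartment accruing the balance, so
*g + r + bleached* is exactly conserved. Conversion is strictly one-way
(no red protein ever reverts), and the conversion cross-section at the
488-nm imaging line is zero by default, so imaging bleaches green protein
without converting it. Integration is fixed-step RK4; the contract is
that halving the step changes the endpoint by under 0.1 %, and the
constant-irradiance case is checked against the closed-form solution.

On the day scale, turnover replaces photochemistry: red protein decays
exponentially at `k_turnover_r`, and green protein relaxes toward the
synthesis/degradation steady state `k_synth_g / k_turnover_r`.

### Rate constants

No rate values are published for this system, so the defaults are
calibrated once to the qualitative behaviors the experiments establish,
and all are exposed in configuration:

| rate          | default | units  | calibration target |
|---------------|---------|--------|--------------------|
| `k_conv`      | 0.5     | cm²/J  | ≈99 % conversion at the 9 J/cm² retinal dose; a clear majority at half that dose |
| `k_bleach_g`  | 0.05    | cm²/J  | visible baseline bleaching over 20 imaging scans; residual green always > 0 (conversion is never complete) |
| `k_bleach_r`  | 0.01    | cm²/J  | red loss slow relative to conversion during a 405-nm exposure |
| `k_conv_488`  | 0.0     | cm²/J  | no appreciable conversion by the imaging beam |
| `k_turnover_r`| 0.45    | /day   | red signal ≤ 5 % of its starting value at day 7 (baseline by one week) |
| `k_synth_g`   | 0.45    | amount/day | green expression returns to its pre-conversion steady state |

### Spectra and filters

Only the peak wavelengths are published (gD2 ex 490 / em 507 nm, rD2 ex
553 / em 573 nm), so excitation and emission curves are asymmetric
split-width Gaussians pinned to those peaks, with widths chosen so the
green emission resembles GFP (~30 nm FWHM) with the characteristic red
tail. Autofluorescence is a broad hump peaking near 600 nm — weak below
520 nm, as lipofuscin-like retinal autofluorescence is through a 503-nm
long-pass — which also keeps the green 10-nm peak bin dominated by real
signal. Detection paths are logistic-edged long-pass filters (503 LP for
488-nm excitation, 561 LP for 561-nm excitation; 2-nm transition width).

The red form's molecular brightness defaults to 2× the green form's.
This makes an equal molecule transfer raise the red emission peak faster
than it lowers the green one, the asymmetry seen in conversion traces;
the value is a modeling choice, not a measured constant, and is
configurable.

### Dosimetry

Radiant exposure is power × duration ÷ area with µW→W and µm²→cm²
conversions. The ocular-media (cornea + lens) transmittance at 405 nm
defaults to 0.4, which maps the published corneal fluence range
(7.5–22.5 J/cm²) exactly onto the published retinal range (3–9 J/cm²);
the underlying measured value is not reproduced here, so the factor is
configuration. Two ex vivo presets are retained because the source
protocol descriptions disagree (3 µW for 2 min at the stage vs. 19 µW
yielding 2175 J/cm²); neither is treated as ground truth, and the second
back-computes its illuminated area (≈105 µm²) from the printed numbers.

## The synthetic-data generator

The generator's role is to produce every input the analysis consumes
with known ground truth. It emulates:

* **Cell mosaics** — minimum-distance rejection sampling (default 80
  cells, 80 µm exclusion radius in a 1456-µm field), somata as 2-D
  Gaussian blobs (σ = 5 µm) with 3–5 polyline processes when ramified,
  a larger bare soma when amoeboid; log-normal per-cell expression.
* **Hyperspectral conversion series** — 20 baseline scans (~1 s each)
  under the 488-nm imaging beam, then 405-nm conversion restricted to a
  rectangular region; per-pixel spectra are the summed 488- and
  561-nm-excited, filter-passed emissions of the local pool. Because the
  kinetics are linear in the pool, all pixels of a region share one
  trajectory scaled by local protein density.
* **Longitudinal scenarios** — day-0 conversion followed by daily
  turnover, plus: *injury* — converted cells drift toward the damage
  locus at 10 µm/h (240 µm/day), reaching the 728-µm response field
  within a day and clustering inside the ~150-µm locus by day 3, then
  dispersing after day 7 with cell count conserved; *degeneration* —
  green-only cells appear at vessel positions from day 1 (monocyte
  extravasation); *healthy* — turnover only. The first frame is a
  pre-conversion baseline. The injury time course (red signal peaking
  on day 1–2, decaying to a few percent of peak by day 7) emerges from
  the geometry — the conversion field straddles the edge of the
  injury-centered quantification region, so migration moves red signal
  into the measured field while turnover removes it.
* **Flow samples** — 200,000 events with multinomially assigned classes
  (green-only microglia, green/red double-positive microglia, peripheral
  monocytes, debris, doublets, dead cells) and log-normal channel
  clusters. Doublets carry FSC-A ≈ 2× FSC-H; dead cells a high
  viability-dye signal; converted microglia keep residual green protein
  (median 30 % of unconverted), which is what holds them above the
  high-green gate. Green→red bleedthrough (1 %) is calibrated so
  unconverted controls gate ~1–2 % red-positive. The converted presets
  place 16 % of microglia in the red-positive class.

Noise is Poisson shot noise (200 photons per signal unit), Gaussian read
noise, a flat autofluorescence floor (0.02 of a soma peak) and linear
green↔red bleedthrough. With noise disabled, rendered signal is exactly
linear in pool amounts.

What the generator does **not** emulate: optical PSF and eye-motion
blur, spatial autofluorescence texture, instrument-specific flow channel
scales, spectral (rather than linear) bleedthrough, and any real
migration mechanics — the drift speed and clustering radii are
narrative-consistent stand-ins. Passing tests therefore demonstrate that
the analysis chain recovers known ground truth under this idealized
forward model, not that it is robust to every artifact of real data.

## Analysis components

**Unmixing.** Observed 561-nm-excited spectra are decomposed by
non-negative least squares (active-set NNLS) against the filter-corrected
rD2 reference and the autofluorescence reference; a gD2 column is
optional and off by default because the 561-nm detection path suppresses
green emission. The reported quantity is the rD2 coefficient divided by
the autofluorescence coefficient, which cancels multiplicative gain
(laser power, alignment) exactly; a day with a zero autofluorescence
coefficient is flagged missing rather than zero. The residual is RMS
misfit over the detection band only (below-cutoff wavelengths carry no
information).

**Timecourse.** Spectra are summed into contiguous 10-nm bins anchored
at 350 nm, so the 500–510 nm bin holds the green peak (505–507 nm) and
the 570–580 nm bin the red peak (571–573 nm). A sample falling exactly
on an interior bin edge is shared half-half between the adjacent bins
(trapezoid rule): this keeps bin values stable under wavelength-grid
refinement (1 nm vs 0.5 nm agree within ~0.1 %) while conserving total
signal exactly. Peak bins are located from the reference-model peaks
rather than the per-dataset argmax, which is unstable at low SNR.
Baseline bleaching is the least-squares slope of log green over the
pre-onset scans — accurate when the bin is signal-dominated, i.e. for
cell-centered fields; a strong autofluorescence pedestal biases it low.
The red-trace flatness statistic is the baseline red slope with its 95 %
confidence interval. Turnover is a mono-exponential log-linear fit
(non-positive points excluded; at least 3 positive points required); no
multi-compartment model is attempted because only a monotone week-scale
decay is established.

**Imaging.** The background estimator is the classical rolling ball:
grayscale opening with a ball structuring element, with two standard
pre-conditioning steps. Brightness is normalized so the image mean maps
to a fixed working level (100), because the ball's intensity curvature
must be shallow relative to real features for the opening to strip them
— this is the regime the classical 8-bit implementation assumes — and a
brightness-proportional scale makes the estimate, and hence the
signal-strength ratio, exactly invariant under multiplicative gain.
A Gaussian pre-smoothing (σ = 2 px) precedes the opening, the
counterpart of the mean filter in the classical implementation; without
it the erosion chases shot-noise minima instead of the background. The
background is clamped below the raw image pointwise (anti-extensivity).
Note the opening *decreases* pointwise as the ball radius grows — a
larger ball fits less far into valleys and peaks.

Signal strength is mean ROI intensity ÷ mean background value, computed
per timepoint with each frame's own background so per-session laser
differences cancel. The default ROI is a 728 × 728 µm square centered on
the injury field, with a 50-px ball radius. Cell counting is Gaussian
smoothing plus local-maximum detection with a threshold relative to the
frame's 99.5th-percentile robust maximum, preserving gain invariance.

**Cytometry.** The gate chain is singlets (FSC-A/FSC-H within 0.7–1.4)
→ live (viability ≤ 2,000) → CD45⁺ CD11b⁺ (≥ 1,000 each) → high green
(≥ 1,000), then classification by red ≥ 500 into green-only vs.
double-positive microglia. The published work names the gates but no
cutoffs; the defaults sit in the valleys between the generator's
log-normal clusters and every cutoff is configuration — the reproducible
content is the gating logic validated against simulator ground truth,
not any specific threshold. Because the denominator of "percent
red-positive" is ambiguous in such experiments, both the final-gate
fraction (`frac_rd2`) and the CD45⁺CD11b⁺-denominated fraction
(`frac_rd2_of_myeloid`) are reported. Compensation is a linear 2×2
spillover inversion with negative results clipped to zero; it is off by
default since the synthetic bleedthrough is small, and documented for
real-data use. Group comparison reports per-retina mean ± SE; in tests
comparing two-sample groups, the pooled SE is floored at the binomial
counting error, since an empirical SE from two samples is a noisy lower
bound.

## Problem sizes

The shipped demo and test suite use deliberately compact scenes: a
single-soma 60-µm field (20 × 20 px at 3 µm/px, 40 scans, 401
wavelengths) for kinetics recovery, a 1456-µm field with 80 cells
(182 × 182 px at 8 µm/px, 9 timepoints) for the injury scenario, 1,000
random mixtures for unmixing recovery, 20 replicates for turnover
recovery, and full 200,000-event flow samples. These sizes were chosen
as the smallest at which each statistical check is well powered.

## Numerical notes and edge cases

* All randomness derives from one integer seed through named
  `SeedSequence` substreams; equal seeds give byte-identical outputs.
* An all-zero observed spectrum unmixes to all-zero coefficients with
  zero residual, flagged (normalized rD2 undefined) rather than zero.
* A zero image background makes signal strength undefined and raises.
* A constant decay series fits rate 0 with an infinite baseline-crossing
  day rather than failing.
* Degenerate pool states (g = 0 or r = 0) are valid throughout; pool
  components are clamped at zero inside the integrator to absorb
  rounding.

## Known limitations

* The fitted turnover rate is an effective decay: protein loss and cell
  departure from the field are indistinguishable at this resolution, by
  design.
* Per-pixel hyperspectral unmixing maps are out of scope; unmixing
  operates on small-field averaged spectra.
* The bleach-slope estimator assumes the green peak bin is
  signal-dominated; it is accurate for cell-centered small fields, not
  for sparse wide fields where the autofluorescence pedestal is a large
  fraction of the bin.
* Injury-response magnitudes (green-loss and red-gain folds across
  conversion) scale with the ratio of cell signal to autofluorescence in
  the measured region and with mosaic density; their qualitative shape,
  not their exact fold values, is the modeled content.
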