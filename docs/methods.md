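# Methods

This note documents the models and numerical choices behind reefwave, the
defaults that matter, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Series container and quality control

An `EnvironmentalSeries` is one variable at one site: strictly increasing UTC
timestamps, float values, and an explicit boolean validity mask. Missing data
are always represented by the mask, never by sentinel values, so no stage can
silently consume a gap.

QC proceeds as: trim → outlier removal → uniform resampling → one-hour
low-pass.

* **Outlier rules.** Out-of-range removal uses per-variable physical ranges
  (pH 7–9, temperature 10–40 °C, salinity 20–40, depth 0–50 m, voltage ±2 V,
  all overridable). Spikes are samples whose deviation from the centered
  rolling median (6 h window) exceeds k = 6 times the rolling median absolute
  deviation (raw MAD; samples with zero local MAD are never spike-flagged).
  Real deployments use sensor-specific criteria, so both rules are
  configurable; the defaults are deliberately conservative.
* **Resampling.** Linear interpolation of valid samples onto a uniform grid.
  Grid points whose bracketing valid samples are more than 3×dt apart stay
  invalid: interpolation never invents data inside an excluded segment.
* **Low-pass.** 4th-order Butterworth with cutoff 1/3600 s⁻¹ applied
  forward–backward (`sosfiltfilt`), so the magnitude response is effectively
  8th order and the phase is exactly zero. Zero phase matters because wavelet
  phase and coherence downstream encode the timing of diel extrema. Measured
  response: a 10-minute oscillation is attenuated below 10 % residual
  amplitude; a 24-hour oscillation passes within 1 %. Each contiguous valid
  segment is filtered independently and re-centered to its input mean (the
  filter's DC gain is one; re-centering cancels the small mean drift that
  edge transients would otherwise introduce). Segments too short for the
  filter's edge padding are left unfiltered.

## ISFET calibration

The electrode model is Nernstian: V = E* + k(T)·pH with
k(T) = R·T·ln(10)/F (R = 8.314462618 J mol⁻¹ K⁻¹, F = 96485.332 C mol⁻¹;
k ≈ 59.16 mV per pH unit at 25 °C). One bottle sample per deployment
determines E*; with a single calibration point, sensor drift is statistically
unidentifiable and no drift model is attempted (the interface accepts a list
of bottles so a multi-point regression can be added, but currently errors for
more than one). The bottle's bench pH at 25 °C is converted to in-situ
temperature through the carbonate system (below) before solving for E*, and
the slope uses the synchronized thermistor series rather than a constant
temperature.

## Carbonate system

Inputs are total-scale pH and total alkalinity, the pair for which the system
is explicit algebra (no iteration): with [H⁺] = 10^(−pH),

    CA      = A_T − [B(OH)₄⁻] − [OH⁻] + [H⁺]_F + [HSO₄⁻] + [HF]
    [CO₃²⁻] = CA·K₂/([H⁺] + 2K₂),   [HCO₃⁻] = CA·[H⁺]/([H⁺] + 2K₂)
    [CO₂*]  = [HCO₃⁻]·[H⁺]/K₁,      fCO₂ = [CO₂*]/K₀,  pCO₂ = fCO₂/φ
    Ω       = [Ca²⁺][CO₃²⁻]/K_sp

Constant set (the classic CO2SYS/CO2CALC choices for reef work of this era):
K₁/K₂ of Mehrbach et al. refit by Dickson & Millero (measured on the seawater
scale; converted to total via the sulfate/fluoride equilibria), K_B of
Dickson, K_W of Millero, K_S of Dickson, K_F of Dickson & Riley, aragonite
and calcite K_sp of Mucci, total boron of Uppström (Lee et al. available as an
option; the difference in derived quantities is <0.5 %), K₀ and the fugacity
coefficient φ of Weiss. No pressure correction is applied: the deployments
this targets sit at 3–6 m, where the correction is negligible and surface
behavior is the convention.

Temperature conversion of pH (bench 25 °C ↔ in situ) holds DIC and A_T fixed:
DIC is computed at the source temperature, then the pH at the target
temperature is the root of the alkalinity equation, bracketed on pH ∈ [3, 13]
and solved by Brent's method to 1e-7 pH. Round trips recover the input to
better than 1e-6.

Range-based uncertainty is defined as half the two-sided spread:
d_x = |x(p+h) − x(p−h)|/2 for x ∈ {pCO₂, Ω_arag} and p ∈ {alkalinity,
salinity}. This central form is symmetric in the sign of h and first-order
consistent with the derivative; whether a one-sided offset was intended by
any particular study is absorbed by the few-percent tolerances used in tests.

Verification: speciation closure (recomputing A_T from the solved species
reproduces the input to < 0.05 μmol/kg), Ω_arag/Ω_cal = K_sp,cal/K_sp,arag
exactly, monotonicity in pH, and agreement with independently computed
published values at two sites' mean conditions (pCO₂ within 0.6 %, Ω within
0.3 %, alkalinity-range uncertainties within 1 % and 6 %). No independent
CO2-system implementation is bundled, so those published values are the
external anchor.

## Wavelet suite

Morlet mother wavelet with ω₀ = 6; scales s_j = s₀·2^(j·dj) with dj = 1/12
octave, s₀ = 2·dt, covering Fourier periods (4πs/(ω₀+√(2+ω₀²)) ≈ 1.033·s) up
to one third of the record length by default. Cone of influence at the
e-folding time √2·s. Cells outside the COI are always reported and flagged,
never dropped.

* **Transform.** Computed in the frequency domain. Two deliberate choices
  make the FFT route *exactly* the linear convolution of the data with the
  time-sampled Morlet (verified to ~1e-12 relative against brute-force
  convolution, all scales, inside the COI): (i) the daughter spectrum is
  Poisson-periodized (summed over ±1 alias of the sampling frequency), i.e.
  it is the exact DFT of the sampled kernel — this only matters at scales
  below ~4·dt, where the plain Gaussian spectrum has mass beyond Nyquist;
  (ii) zero-padding extends past the wavelet's effective support
  (8·s_max) so circular wraparound never touches the data, at any scale.
* **Gaps** are linearly bridged before transforming (hard zeros would leak
  across scales) and the affected times flagged in `time_valid`; global
  spectra exclude them, exports carry the flag.
* **Red-noise significance.** AR(1) parameters are fitted by the lag-1
  autocorrelation (clipped to [0, 0.999]); at n in the thousands the
  difference from maximum likelihood is negligible and the null stays exactly
  reproducible. The background spectrum
  P(f) = σ²_series·(1−α²)/(1+α²−2α·cos 2πf) is evaluated at each scale's
  Fourier frequency and the pointwise threshold is P·χ²₂(0.95)/2. Measured
  false-positive rate on pure AR(1) input: 5 % ± 1 % of in-COI cells.
* **Scale-averaged power** uses the variance-preserving weighting
  (dj·dt/C_δ)·Σ_j P(t, s_j)/s_j with C_δ = 0.776; on stationary AR(1) input
  its time mean reproduces the series variance within 15 % (the residual is
  the finite scale range).
* **Coherence.** R² = |S(W_xy/s)|²/(S(|W_x|²/s)·S(|W_y|²/s)) with a smoothing
  operator S that is Gaussian in time and boxcar in scale. Because S is
  linear with identical nonnegative weights for every field, Cauchy–Schwarz
  guarantees R² ∈ [0, 1] everywhere, boundaries included. The smoothing
  widths are declared in `WaveletParams`: time Gaussian std = 2·scale and
  scale boxcar = 1.2 octaves. These widths were chosen so the estimator has
  roughly 6 equivalent degrees of freedom per cell: with the narrower windows
  some packages use (std = scale, 0.6 octave), the null coherence floor sits
  near 0.35 and partial coherence *cannot* fall much below ~0.4 even when the
  conditioning variable is the exact shared driver — the estimator bias
  swamps the signal. With the defaults, independent white noise gives mean
  in-COI R² ≈ 0.14, and conditioning on an exact shared driver pulls the
  partial coherence band mean below 0.2 while a 2 h lag on a diel cycle is
  still resolved to ~0.01 rad. Halve both fields to reproduce the narrow
  behavior.
* **Partial coherence.** With complex smoothed coherencies γ_ab,
  RP²_{xy·z} = |γ_xy − γ_xz·γ_zy|²/((1−|γ_xz|²)(1−|γ_zy|²)) — the local
  analogue of the squared partial correlation. Cells where the conditioning
  series is numerically perfectly coherent with x or y (denominator < 1e-6)
  are masked NaN rather than reported.
* **Surrogate significance.** AR(1) models fitted per input series;
  each Monte Carlo iteration draws independent stationary surrogates and
  recomputes the (partial) coherence. A cell is significant when
  p = (1 + #{surrogate ≥ observed})/(n_surrogates + 1) ≤ α. The count-based
  form needs O(cells) memory regardless of the surrogate count and equals the
  95th-percentile rule with the (b+1)/(m+1) convention. Default 999
  surrogates for one-off maps (19 is the minimum that can resolve α = 0.05);
  the pipeline defaults to 199 to keep a full two-site run in minutes.
  Measured null rate for independent AR(1) pairs: ~4–6 % of in-COI cells.

## Site comparison

Randomization tests pool the two sites' values and reassign them at random,
preserving the original group sizes — no subsampling, so unequal record
lengths are handled exactly. p-values are two-tailed with the +1 convention
(never exactly zero; resolution 1/(n_rand+1)); the raw exceedance proportion
is also reported. The per-percentile test uses an integer 1–99 grid with
linearly interpolated quantiles and reuses one shuffle set across the grid
(the induced dependence across percentiles mirrors the data's own); p-values
are deliberately uncorrected for multiple testing and flagged as such in the
result metadata. The KS test is the standard two-sample statistic with the
asymptotic p-value. Measured type-I error of the mean-difference test under
the null: 5 % ± 1 % over 500 synthetic datasets.

## Synthetic reef generator

Each variable is baseline + diel sinusoid (24 h) + semidiurnal sinusoid
(M2 period, 12.4206 h) whose amplitude is modulated by the 14.77-day
spring–neap cycle + episodic depressions + stationary AR(1) noise (state-space
draw with a stationary initial condition, so early samples are not
transient-biased). Events are half-cosine (Hann) pulses or
instant-drop/exponential-recovery windows, placed at fixed fractions of the
deployment so short test scenarios keep the same structure.

Two scenarios ship as defaults, sized to the deployments this package models:
a "moorea-like" site (33.3 days at 6-minute sampling; steady diel pH cycle,
amplitude 0.042; constant salinity 35.65; pH baseline 7.989, temperature
28.76 °C, A_T 2353 μmol/kg) and a "taiwan-like" site (45.9 days; mixed
diurnal+semidiurnal depth tide with spring–neap modulation; two
typhoon/upwelling-like depressions of temperature (3 and 6.5 °C) and salinity
(1.2 and 2.5); pH baseline 7.976, A_T 2181 μmol/kg). Amplitudes and noise
parameters were set once so that means, SDs and ranges fall in the published
summary-statistics ballpark of the corresponding deployments; the published
record does not quantify typhoon depression magnitudes, so those depths are
calibrated only to reproduce range-scale behavior.

What the generator does **not** emulate: sensor drift and biofouling,
thermal hysteresis, salinity–temperature covariation from water-mass mixing,
tidal harmonic families beyond one semidiurnal + one diurnal line, asymmetric
diel shapes from photosynthesis/respiration, and measurement quantization.
Passing tests therefore demonstrate the correctness of the computational
chain on data with known ground truth, not robustness to every field
pathology.

## Pipeline

The two-site pipeline derives per-stage seeds from one run seed
(`numpy.random.SeedSequence`), logs input/removal counts and the parameters
actually used, writes all outputs as CSV/JSON, and finishes with a manifest
of SHA-256 content checksums: two runs with the same configuration are
byte-identical (the manifest's wall-clock timestamps aside). Synthetic-
scenario sites exercise the full raw-voltage path: the voltage record the
sensor would have produced is synthesized from the true pH, and a bottle
record exactly consistent with the generated series at the calibration
instant is constructed (its bench value via the in-situ → 25 °C conversion),
so calibration errors would be visible as end-to-end failures. On any stage
failure the partial outputs are renamed with a `.partial` suffix and the
error is re-raised tagged with the stage name.

## Test and benchmark problem sizes

The suite exercises the statistical calibrations at sizes chosen to make
Monte Carlo error small while keeping the default run fast: χ² red-noise
calibration on 50 AR(1) records of n = 2048; surrogate-coherence calibration
aggregated over 20 runs of 199 surrogates at n = 288; permutation type-I
error over 500 datasets of 200 samples per site at 999 shuffles;
transform-vs-convolution equivalence on n = 512. These sizes are the
package's own benchmark definitions; all scale up without code changes.

## Known limitations

* Single-point calibration means any sensor drift aliases into the pH record
  undetected; the QC layer cannot compensate.
* The carbonate solver covers the pH + A_T input pair only (the pair this
  pipeline produces); other pairs (DIC + pCO₂, etc.) are out of scope.
* Wavelet power is reported without bias rectification, and only the Morlet
  mother is implemented; no reconstruction/denoising.
* Gap bridging before the transform slightly smooths power at gap edges;
  bridged cells are flagged but neighboring cells inside the wavelet support
  are not.
* Per-percentile p-values are uncorrected; treat the percentile panel as a
  descriptive pattern, not 99 independent hypotheses.
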