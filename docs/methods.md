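# Methods

This note documents the models implemented in `speckleflow`, the defaults
and why they were chosen, what the synthetic data do and do not emulate,
and the numerical choices that matter.

## Forward theory

**Semi-infinite correlation diffusion.** The field autocorrelation uses
the extrapolated-boundary half-space solution with an isotropic source at
depth z0 = 1/μs′ and a negative image at z0 + 2zb, zb =
2(1+Reff)/(3μs′(1−Reff)). The decay parameter is

K(τ) = sqrt(3 μa (μa+μs′) + 6 (μa+μs′) μs′ k0² αDb τ),

carrying units of 1/cm so that K·r exponentiates distances. The effective
reflection coefficient Reff uses the standard diffuse-optics polynomial in
the index ratio n = n_in/n_out (−1.440/n² + 0.710/n + 0.668 + 0.0636 n);
it can be overridden wherever a geometry is built. Units throughout:
lengths cm, times s, Db in cm²/s, wavelengths entered in nm; temperatures
kelvin unless `unit="C"` is passed.

**Exposure-integrated contrast.** κ²(T) = (2β/T)∫₀ᵀ|g1|²(1−τ/T)dτ is
evaluated by composite Simpson quadrature on 2048 log-spaced nodes plus
τ = 0 (|g1|² varies fastest near zero); an optional convergence check
against a 2× finer grid enforces ≤1e−8 relative agreement. Against the
closed form for exponential |g1|² the quadrature agrees to ~1e−9.

**Brownian ground truth.** Db(T) = kB·T/(6π a η(T)) with η from Vogel's
water-viscosity equation (pole at 137.546 K guarded); the 195 nm-diameter
(a = 97.5 nm) microsphere default gives Db ≈ 1.50e−8 cm²/s at 7 °C and
2.32e−8 cm²/s at 22 °C.

## Synthetic detector records

The simulators impose statistics rather than propagating optics: speckle
fields are stationary circular complex Gaussian processes whose temporal
autocovariance equals the theoretical g1 (circulant-embedding spectral
synthesis, padded to a fast FFT length; negative spectral mass is clipped
with a warning above 5% of total and an error above 20%). Spatial speckle
correlation (iDWS pixels, SCOS images) is a Gaussian blur of the complex
field; for SCOS the blur is set so that the FWHM of the spatial intensity
autocovariance equals the configured speckle-to-pixel ratio (default 2.3),
for iDWS so that the fluctuation autocorrelation has the configured HWHM
(default 1.5 px).

Detector models: DCS channels draw Poisson counts from single-speckle
intensities (default 3e5 counts/s/channel at 1 μs bins — chosen so shot
noise is visible but not dominant; no photon budget is prescribed by the
protocol itself); iDWS records are ⟨IR⟩ + 2√⟨IR⟩ Re E_S with shot noise,
Gaussian read noise and 8-bit quantization (reference 100 counts, sample
2 counts — comfortably heterodyne); SCOS frames are
round(g·Poisson(flux·T·J) + read + offset) clipped to 16 bits with
g = 9.64 counts/photoelectron, 1 ms exposure, 120 Hz.

**Exposure integration.** The within-exposure intensity integral J is
represented by `substeps` point samples of the field (default 512 — a
pre-registered convergence study showed 32 substeps bias κ² by +10% at
in-vivo and +50% at phantom decorrelation times, while 512 is accurate to
<0.1%). For efficiency the Toeplitz field covariance over the exposure is
diagonalized once per flow level (cached): the integrated intensity is a
weighted sum of squared moduli of independent spatially-blurred complex
Gaussian modes. Eigenvalues covering 95% of the mass are kept as
stochastic modes; the long tail of tiny eigenvalues enters as a
deterministic pedestal with the kept weights rescaled so that the mean and
variance of J — hence the theoretical contrast — are preserved exactly.

**Effective SCOS coherence parameter.** Because pixels within a 7×7
window are correlated at speckle/pixel 2.3, the expected unbiased sample
variance is reduced by a computable factor
(`effective_beta_spatial(2.3, 7) ≈ 0.92`). This plays the role of β_SCOS
for the synthetic camera and makes *absolute* recovery testable; with an
assumed β the output is flagged relative, as camera-contrast flowmetry is
normally reported. A residual ≈ +3.5% bias in absolute SCOS recovery
remains: it is the ratio-estimator bias of κ = s/μ̄ at only ~9 independent
speckles per window, partially offset by the 1/N_avg residual of the
spatial-noise correction. Both are properties of the estimator itself, not
of the simulation.

**Flow programs.** The cuff protocol defaults to 60 s baseline, 120 s
occlusion (exponential decay to a floor, no cardiac modulation), 120 s
recovery with a hyperemic overshoot rescaled to attain the configured
peak rBFi (default 2.5). The cardiac waveform is a mean-one harmonic
series (fundamental + 2 overtones, default 1.2 Hz) whose oscillation is
centered and scaled on the sampled baseline so the baseline pulsatility
index equals the configured value (default 0.4) exactly by construction; a
0.25 Hz multiplicative "respiration" is optional. The phantom ramp is a
linear 7→22 °C sweep with BFi(t) = Db(T(t)), α = 1.

**What the synthetic data do not emulate:** physical beam propagation,
polarization mixing, laser mode hops and intensity drift, detector
afterpulsing/dead time, tissue heterogeneity and probe-position
differences between modalities, motion artifacts. Passing recovery tests
therefore demonstrates the correctness of the estimators under the stated
statistical model, not robustness to every artifact of real instruments.
In the cuff scenario the fast records are *block-stationary*: BFi is held
constant within each 0.05 s analysis window (one exposure for SCOS) and
the field is regenerated independently per block; this discards only the
unused cross-window field correlation.

## Pipelines

**DCS.** g2(τ) = ⟨I(t)I(t+τ)⟩/⟨I⟩² per 0.05 s window per channel on a
quasi-logarithmic lag grid (16 consecutive lags, then doubling steps);
every lag is computed by direct products at native resolution via one FFT,
so the estimator is *identical* to the naive direct sum (no cascaded
rebinning). Zero-count windows are flagged, channels averaged unweighted.
β is calibrated once by a joint (β, BFi) fit of the curve averaged over
the first minute (or the whole record if shorter) and then frozen; a
per-window joint mode exists for robustness checks. Fits are bounded
nonlinear least squares in log10 BFi ∈ [−12, −4], initialized from a
48-point grid scan, restricted to lags whose contrast exceeds 3× the
late-lag noise floor (all lags when noise-free).

**iDWS.** 0.1 s centered rolling-mean subtraction (shrinking edges; the
first/last half-window is flagged and excluded from segments), spatial
convolution with an unnormalized Gaussian (peak 1, σ = 0.9669 px,
reflective edges), per-pixel Wiener–Khinchin autocorrelation of
non-overlapping 0.05 s segments (zero-padded to ≥2× length, so the FFT
estimator equals the direct lag sum), pixel summation, subtraction of an
identically processed reference-only run (10 s, sample arm blocked), then
a two-parameter (A, BFi) least-squares fit. The default cost compares
G2² with (A g1)², summed from lag 1 (lag 0 carries the noise-variance
spike) up to the first lag where the measured normalized correlation goes
negative — the theoretical g1 is strictly positive, so the range rule can
only refer to the measured curve. `g1_all` and `g1_over_1e` fit modes
reproduce the alternative-cost comparison; Monte-Carlo runs at matched
noise confirm the squared cost has the lower BFi variance.

**SCOS.** Unbiased (n−1) spatial variance over 7×7 non-overlapping
windows of dark-corrected counts (per-window scalar dark offset; edge
windows discarded), decomposed as κf² = κMeas² − κRead² − g/μ − 1/(12μ²)
− κSpatial², with κSpatial² from the shot-corrected variance of an
N_avg = 100-frame temporal average, recomputed every N_avg frames and
applied forward. The identity holds exactly for every window; windows
with κf² < 0 are flagged invalid, never clipped, and a run with invalid
post-occlusion frames is flagged for exclusion. Frame-mean κf² is
inverted for BFi through the exposure integral using a cached, vectorized
κ²(log BFi) table with a bracketed bisection refinement (round-trip
accurate to ~1e−7); κf² ≤ 0 or ≥ β is invalid. A gain-sensitivity sweep
re-runs the full pipeline per assumed gain.

**Flow analysis.** rBFi divides by the baseline mean (output baseline
mean exactly 1). Beat detection estimates the cardiac frequency from the
dominant periodogram peak in 0.5–3 Hz, smooths with a zero-phase ~1/4
cycle Hann window (so noise cannot pull maxima off the systolic crest),
picks peaks ≥ 0.5/f apart and trims edge artifacts. Waveforms are
resampled to a 64-point phase grid, divided by their own mean, and
summarized by pointwise median and IQR; PI = (max−min)/mean, with per-beat
PIs filtered by a median ± 3×scaled-MAD rule (when the MAD is zero —
identical beats — anything off the median is an outlier, matching the
common removal routine). Nonparametric Bland–Altman uses percent
differences relative to the reference: bias = median, limits of agreement
= 2.5th/97.5th percentiles, reproducibility coefficient = half their
span. Group comparisons: Friedman, pairwise Wilcoxon signed-rank, Pearson
correlations and linear fits (α = 0.05, two-sided; fully tied ranks
report p = 1).

## Scenarios, seeding, problem sizes

`run_scenario` drives simulate → process → compare for the cuff and
phantom-ramp protocols, writing CSV series and a JSON report; every stage
draws from `SeedSequence(master, spawn_key=(stage_index, k))`, so outputs
are byte-identical under a fixed master seed. The phantom report includes
per-modality regression against Db,Theo, nonparametric agreement, and a
dispersion (CV) summary; SCOS dispersion is additionally quoted at the
common 20 Hz bandwidth (6-frame block averages), the matched-rate framing
under which camera contrast attains interferometric precision.

Default desk-scale record sizes — 1e5 DCS bins (0.1 s), 64 iDWS pixels ×
0.5 s, 120 SCOS frames of 128×128 — keep a full recovery trial under
~15 s on one core; real instruments record 512-pixel × hours datasets
that are configurable but not defaults. The test suite and
`scripts/acceptance.py` further scale ramp points (8 temperatures) and
trial counts; all such sizes are stated in the configs they use.

## Known limitations

* Absolute SCOS recovery carries the few-percent ratio-estimator bias
  discussed above; relative flow (the quantity reported in practice) is
  unaffected.
* The block-stationary cuff records have no field correlation across
  0.05 s windows, so methods that exploit longer coherence cannot be
  studied with them.
* Heterogeneous or layered media, frequency-domain optical-property
  fitting, and multi-exposure β_SCOS estimation are out of scope; optical
  properties are inputs (with a power-law/linear wavelength extrapolation
  helper for moving between calibration and measurement wavelengths).
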