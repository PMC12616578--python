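# Methods

## Signal model and unmixing

A two-channel recording is modeled as

    G(t) = V(t) + H(t),        H(t) = (F ∗ R)(t)

where G is the GEVI-channel fluorescence, V the voltage signal, R the
voltage-insensitive reference channel, and F a stationary linear filter
mapping reference-channel artifact content into the GEVI channel. The
physical motivation is that both channels see the same hemodynamic
state (oxy/deoxyhemoglobin content, blood volume, motion) through
different spectral sensitivities, and a linear dynamical relation
between the two appearances is a convolution.

The filter is estimated in the frequency domain from N overlapping
segments of duration τ: each segment is Hann-windowed and transformed,
and f(ω) = ⟨g_k r_k*⟩ / ⟨r_k r_k*⟩. Key numerical choices:

- **Segmentation.** τ defaults to 1.0 s with 75% overlap; segments
  start every (1−overlap)·τ and a trace must supply at least two. The
  frequency grid is the DFT grid of one segment, no zero padding, so
  the average combines like-for-like bins. τ controls the
  resolution/robustness trade-off: longer τ resolves narrower artifact
  lines, shorter τ averages more segments.
- **Amplitude limiting.** After averaging, any bin with
  |f| > α·|f(ω₀)| is scaled down to that bound with its phase kept
  (α default 1.1). ω₀ is the heartbeat fundamental, detected from the
  largest Welch-spectrum peak of the reference in 6–16 Hz (a peak at
  half that frequency with ≥ 50% of its power is preferred as the
  fundamental; no clear peak raises an error asking for an explicit
  value). |f(ω₀)| is the raw averaged value at the ω₀ bin.
- **Degenerate bins.** Bins where the reference has no power get gain
  0 (logged, not an error). The DC gain is forced to 0 — inputs are
  assumed detrended, and this prevents baseline leakage.
- **Kernel and edges.** F(t) is the inverse transform, centered at lag
  zero (support τ). The convolution H = F∗R uses reflection padding;
  the first and last τ/2 are edge-affected and flagged in the result
  metadata. On short recordings this edge region dominates the residual
  artifact error; recordings much longer than τ make it negligible.
- **Reconstruction.** Every unmixing result satisfies
  G = V + H (+ H_avg) to float round-off by construction; tests assert
  it at 1e-12.

The frequency-independent baseline `regression_unmix`
(V = G − βR, β the OLS slope) is provided for comparison: with any
nonzero cross-channel phase at the artifact frequency it must leave
more artifact-band residual, and with an uncorrelated reference it
transfers β²·Var(R) of noise, which the convolutional filter avoids.

**Movies** unmix in two stages because single-pixel reference traces
can be noisier than the GEVI traces. Stage 1 averages the reference
over disks of radius `prefilter_scale_mm` (default 1.0 mm; a scale at
or beyond the field of view, or None, selects the global mean), fits
one filter between the field-averaged traces, and subtracts
H_avg = F∗R_avg at every pixel. Stage 2 fits an individual filter per
pixel between its raw reference trace and the stage-1 residual. Since
non-neuronal activity is spatially smooth and does not travel, spatial
averaging boosts the reference SNR without blurring the wave content of
V.

**Train/test parameter selection** (`select_parameters`) estimates the
filter on the first half of a recording and scores each (τ, α) by the
artifact-band residual power of the unmixed second half (heartbeat
fundamental ± 2 Hz plus harmonics); ties break toward the smallest τ,
then the smallest α, for determinism.

A caution learned from the synthetic studies: with a line-spectrum
artifact, the *absolute* residual after unmixing depends on whether the
artifact frequency falls on a DFT bin of the chosen τ (off-bin, the
finite kernel interpolates across bins and couples the noise-driven
gains of artifact-free bins into the artifact frequency). Suppression
stays ≥ 20 dB everywhere on the recommended grid (τ 1.0–1.5 s,
α 1.0–1.3), but the residual's numerical value can vary several-fold —
on real recordings, where the reference carries broadband hemodynamic
power and the in-band residual is dominated by genuine signal, the
score is much flatter in (τ, α).

## Preprocessing

- `notch`: zero-phase Butterworth band-stop (total order 8, default
  ±1 Hz) applied forward–backward; narrow stop bands ring for roughly
  1/bandwidth seconds at the recording edges (steady-state attenuation
  is > 40 dB).
- `detrend_lowpass`: F₀(t) from a 4th-order zero-phase Butterworth
  low-pass (0.5 Hz); returns F/F₀.
- `detrend_exponential`: F₀(t) = Σ aᵢ·exp(−t/τᵢ) + c fit by
  bound-constrained nonlinear least squares with log-spaced multi-start
  time constants (1–3 components; amplitudes and offset non-negative —
  the free offset is included because fluorescence decays to a plateau,
  not to zero). The half-life is solved from the fitted model by
  bisection to 1e-6 relative tolerance.
- `highpass`: symmetric FIR (Kaiser design, 80 dB stopband, transition
  width cutoff/2) built by spectral inversion of a unit-DC-gain
  low-pass, so the DC gain is exactly zero and the kernel is exactly
  linear-phase. One implementation serves traces and movies; it
  commutes with spatial binning to float precision.
- `decrosstalk`: both traces are band-passed (3rd-order Butterworth,
  zero-phase; default 3–7 Hz, the band with reliable oscillations and
  few artifacts), β is the in-band least-squares slope, and β times the
  *unfiltered* contaminant is subtracted from the unfiltered
  contaminated trace.
- `bin_movie`: factor×factor box averaging (default 8), trailing
  partial blocks dropped to avoid edge bias in wave fits; pixel pitch
  scales by the factor.
- `svd_denoise`: per 2500-frame segment, the movie (frames × pixels)
  is projected onto its top-k (default 5) left singular vectors; each
  coefficient row, reshaped to an image, passes through a pluggable 2-D
  denoiser (default deterministic Gaussian blur; identity makes the
  operation an orthogonal projection, hence idempotent). The pluggable
  contract replaces a pretrained network denoiser so the architecture
  is testable without trained weights.

## Spectral analyses

- `coherence`: Welch estimate on 1-s segments overlapping by 0.8 s;
  the reported magnitude is the square root of the magnitude-squared
  coherence (documented because plot axes labeled "coherence" are
  ambiguous); phase from the averaged cross-spectrum.
- `wavelet_spectrogram`: analytic Morlet-class transform implemented
  in the frequency domain — per probe frequency f₀ a Gaussian analytic
  filter of width σ_f = f₀/n_cycles (default 7 cycles) with unit peak
  gain, so a tone of amplitude a reports amplitude a at every probed
  frequency (flat response). This normalization is what the amplitude
  comparisons across frequencies in cross-frequency analyses require.
- `band_envelope`: zero-phase band-pass then Hilbert analytic signal.
  Phase convention: **0° is the carrier trough** (maximal
  hyperpolarization); the reported phase is the analytic phase shifted
  by 180°.
- `cross_correlation`: normalized, with parabolic sub-sample peak
  interpolation. The `per_lag_norm` option normalizes each lag by the
  energies of the actually overlapping samples; on short narrow-band
  excerpts the default whole-trace normalization tapers the correlation
  triangularly and biases the peak toward zero lag by roughly
  1/(L·(2πf)²) — per-lag normalization removes this exactly (a pure
  delay correlates at exactly 1 at its true lag), and the bout-delay
  estimator uses it.
- `cfc`: carrier phase from `band_envelope`, modulated-band amplitude
  from the wavelet spectrogram averaged over the band, amplitude binned
  into 36 10° phase bins over complete carrier cycles (delimited at
  phase wraps; at least 10 required). Preferred phase is the
  amplitude-weighted circular mean; modulation depth is
  (max − min)/mean of the binned profile. Raw (not z-scored) amplitude
  is used; z-scoring is an option left to the caller.
- `segment_by_band_power`: theta-band (5–9 Hz) power envelope smoothed
  over 1 s, thresholded at its median (or a fixed value); epochs
  shorter than 2 s merge into their neighbors; labels run/rest.

## Event detection

Sharp-wave ripples use the normalized squared signal (NSS): band-pass
120–200 Hz (3rd-order Butterworth, zero-phase) → square → centered
20 ms moving maximum → 20 ms moving average → min–max rescale to
[0, 1]. Local maxima are gated by prominence ≥ 0.10 (on the rescaled
trace, so "10%" is absolute), distance ≥ 10 ms, and half-prominence
width within 10–200 ms; each event carries a 300 ms window. The min-max
rescale makes detections exactly invariant to input gain. It also
means the detector *presupposes that ripples are present*: on
burst-free noise the rescaled NSS maxima are noise excursions that pass
the 10% prominence gate, so noise-only recordings yield spurious
events. The intended workflow keeps a human review of exported event
snippets; no automatic curation surrogate is attempted. Ictal spikes:
25 Hz 6th-order zero-phase high-pass, peaks gated by 2–20 ms
half-prominence width and 1000 µV prominence (inputs in µV).

## Traveling-wave velocimetry

Delay maps correlate every pixel against a seed pixel (FFT-based, with
parabolic sub-sample lag refinement); `corr` is the correlation maximum
within ±max_lag and `delay_s` is positive where the pixel lags the
seed. The plane fit τ(x,y) = Ax + By + C runs over pixels with
corr > X_min (0.6–0.9). A wave propagates toward increasing arrival
delay, so the default velocity is the gradient form
v⃗ = (A, B)/(A² + B²), speed 1/√(A²+B²), direction atan2(B, A) — this
reproduces ground-truth directions of synthetic plane waves at all
angles. The component-inverse pair (1/A, 1/B) is available behind
`literal_formula` for comparability, but its direction is wrong except
on axes and diagonals. Near-zero delay gradients are rejected as
"synchronous".

The wavenumber route detects wave windows (field-averaged signal
beyond 3 s.d. of its mean; gaps < 50 ms merged), projects the movie
onto x and y, takes each position's sub-sample peak time within the
window, and regresses peak time on position with a Huber M-estimator
(statsmodels RLM); slopes are the wavenumbers αx, αy (s/mm) with
normal-approximation p-values. Literal acceptance requires both
p < 0.01 — which necessarily rejects perfectly axis-aligned waves,
whose transverse wavenumber is exactly zero; the `any_axis` option
accepts one significant axis and sets the other wavenumber to zero.
Both behaviors are provided because the literal rule's intent for
axis-aligned waves is not determinable. An optional band-pass of the
projections before peak extraction (e.g. the wave band) matters at low
SNR and whenever residual artifact lines survive unmixing; the
low-SNR validation applies segmented SVD denoising first, mirroring
the intended movie pipeline.

Pairwise speeds are distance/|delay difference| for admissible pairs
(both correlations above X_min, delay difference above one sample).
Note the pairwise estimator reads v/cos(θ) for pairs at angle θ to the
propagation axis, so only pairs along the propagation direction
estimate the true speed; the plane fit and wavenumber regression do
not share this bias.

## Delay model

Voltage indicators low-pass membrane potential with indicator- and
cell-type-specific kinetics, so the apparent cross-correlation delay
between two cell types imaged with two indicators is
Δ + d_A − d_B, with Δ the physiological delay and d the
indicator/cell-type lags (6 unknowns: 3 indicators × 2 cell types).
The fit minimizes the inverse-variance-weighted squared error over the
7 experiments plus λ·‖d‖₂ (λ = 0.01; the un-squared Euclidean norm is
the literal penalty definition, an L1-style alternative is available)
subject to d ≥ 0, via L-BFGS-B from two warm starts (clipped weighted
least squares, and zero lags). Observations are resampled 100 times
from Normal(mean, sd/√n_bouts) and the mean/s.d. of the fits reported.

The shipped 7-row design uses row 1 = the dual-GEVI experiment
(Δ + d₁ − d₂ across cell types) and rows 2–7 = calibration of each of
the six lags against a kinetics-free timing reference (an
electrophysiological or fast-indicator timestamp). This choice is
deliberate: any design built purely from indicator *pairings* leaves Δ
unidentifiable, because adding a constant to all of one cell type's
lags can be absorbed into Δ (and a constant added to *all* lags is
invisible entirely) — regularization would then pick the minimum-norm
gauge and bias Δ by the smallest true lag difference. The design
constructor verifies identifiability (rank 7, Δ outside the span of
the lag columns) and rejects difference-only designs. Users can supply
their own design; `swapped()` exchanges the indicator assignments
between cell types for the symmetry check (the recovered Δ must be
unchanged).

## Synthetic data: what it does and does not emulate

`gen_trace` builds gevi = trend·(baseline + V + H_g + noise) and
reference = trend·(baseline + H_r + noise). The heartbeat artifact is
a sum of harmonics of a fixed fundamental (default 11 Hz, 2 harmonics)
with random phases; the GEVI-channel copy of each harmonic is scaled
and *delayed* (default 20 ms) — a pure delay + gain per harmonic, an
analytically checkable special case of the convolutional model. Slow
hemodynamic drift is shared band-limited (0.1–1 Hz) noise scaled per
channel. Oscillations are Gaussian noise band-limited by 4th-order
zero-phase Butterworth filters (so phases are irregular, as in real
bouts); optional nesting multiplies one band by
(1 + depth·cos(carrier phase − preferred))/(1 + depth) using the
trough-zero phase convention. Photobleaching is Σ aᵢ·exp(−t/τᵢ).
`gen_movie` adds a plane wave cos(2πft − 2π(x·cosθ + y·sinθ)/Λ) per
pixel with an optional raised-cosine temporal bout (a single
well-defined peak per pixel, which the peak-time wave estimator
needs), plus a spatially uniform artifact. `gen_ripple_trace` injects
Hann-windowed ripple-band bursts into white or 1/f noise at a given
peak-to-noise s.d. ratio, centers at least 0.3 s apart.

Not emulated: broadband (1/f) hemodynamic power between heartbeat
lines, heart-rate variability, spatially non-uniform artifacts, motion
artifacts, photon shot-noise scaling with intensity, curved or
colliding waves. Consequently, passing tests demonstrate algorithmic
correctness under the stated model — exact reconstruction, closed-form
filter recovery, detector operating points — not performance on real
tissue; in particular the absolute residual levels after unmixing are
idealized (see the τ-bin caution above).

`snr_bound` implements the shot-noise design rule for detecting a
wave of wavelength Λ and fractional amplitude ΔF/F: photons are pooled
over half a wavelength (the wave's correlation length — averaging
further cancels the wave) and n_f frames of pixels at well capacity
W_C, giving n_max = (M·Λ/(2·I_px))²·n_f·W_C photoelectrons, shot noise
σ_ε = √n_max, and SNR ≤ (ΔF/F)·√n_max. The stepwise derivation
(n_max, then σ_ε, then the bound) is the normative form; magnification
M is dimensionless, Λ and the pixel pitch I_px share units after
conversion.

## Pipelines and reproducibility

`run_trace_pipeline` (notch → detrend → decrosstalk → unmix) and
`run_movie_pipeline` (bin → [registration/motion hooks] → decrosstalk
→ detrend → unmix → svd_denoise → waves) validate stage order against
these templates unless explicitly overridden, log every stage's
parameters to a JSON sidecar, and are deterministic for a fixed seed —
reruns are byte-identical. Registration and motion correction are
declared no-op hook stages: external tools own them, but the pipeline
acknowledges their position.

## Problem sizes used in validation

The validation suite and `scripts/acceptance.py` use desk-scale
problems chosen to exercise each estimator in its intended regime:
60 s / 1 kHz traces for unmixing, coupling and ripple studies; 2 s /
300 fps / 64×64 px movies (0.05 mm/px) at speeds 30–220 mm/s for wave
velocimetry, with the wave frequency chosen per speed (5/15/20 Hz) so
the arrival-delay span across the field stays within half a period of
the seed pixel (the unambiguous range of a periodic delay map);
16–32 px movies for the two-stage movie unmixing; 20 replicate designs
for the delay model.

## Known limitations

- The filter is stationary over a recording; slowly drifting artifact
  coupling is not tracked (no adaptive or time-varying form).
- Kernel-edge regions (τ/2 at each end) carry elevated residuals.
- The ripple detector requires events to be present (see above).
- The literal both-axes significance rule rejects axis-aligned waves;
  use `any_axis` where that is not intended.
- Pairwise velocities are upper-biased for oblique pixel pairs by
  construction.
- Independent-component or other multivariate unmixing is out of
  scope, as are image registration, motion correction and atlas
  alignment.
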