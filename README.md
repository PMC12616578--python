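# voltwave

Analysis toolkit for two-channel optical voltage recordings: a
genetically encoded voltage indicator (GEVI) channel that mixes neural
membrane-potential signals with hemodynamic and motion artifacts, and a
voltage-insensitive reference fluor channel that reports the artifacts
alone. The package removes the shared artifacts by frequency-dependent
convolutional (Wiener) unmixing and provides the downstream analyses
such recordings call for: coherence with electrophysiology,
phase–amplitude cross-frequency coupling, sharp-wave-ripple detection,
traveling-wave velocimetry on voltage movies, and a regression model
that separates physiological delays between cell types from
indicator-kinetics lags.

It is aimed at labs doing fiber photometry or widefield (mesoscope)
voltage imaging in vivo, and at anyone who wants to test these
algorithms against synthetic data with known ground truth — the
`voltwave.synth` module generates traces and movies that reproduce the
statistical structure the analyses assume (heartbeat artifact lines
plus harmonics with a cross-channel lag, slow shared hemodynamic drift,
multi-exponential photobleaching, band-limited oscillations with
optional theta–gamma nesting, traveling plane waves, ripple bursts).

## The core method

The GEVI channel is modeled as G(t) = V(t) + H(t), where V is the
voltage signal and the artifact is a linear convolution of the
reference channel, H(t) = (F ∗ R)(t). Both channels are split into
overlapping windowed segments of duration τ (default 1 s, 75% overlap,
Hann window), and the filter is estimated per frequency as the
cross-spectrum to auto-spectrum ratio

    f(ω) = ⟨g_k(ω) r_k*(ω)⟩_k / ⟨r_k(ω) r_k*(ω)⟩_k ,

a frequency-dependent complex regression coefficient. To forbid
unbounded amplification where the reference has little power, |f(ω)| is
capped at α·|f(ω₀)| (α ≈ 1.1), where ω₀ is the heartbeat fundamental —
phases are preserved. The inverse transform F(t) is convolved with R(t)
and subtracted: V = G − F∗R. Because the heartbeat artifact has
different amplitude *and phase* in the two channels, a
frequency-independent regression (V = G − βR) cannot cancel it; the
convolutional filter can, and — unlike regression forced to a nonzero β
— it does not transfer reference noise into the voltage estimate.

For movies, unmixing runs in two stages: a spatially averaged reference
(disk radius ~0.5–1.5 mm) first removes the spatially smooth artifact
at every pixel, then a per-pixel filter removes the remainder.
Traveling waves in the resulting voltage movies are characterized two
ways: seed-pixel cross-correlation delay maps fit with a plane
τ(x,y) = Ax + By + C (speed 1/√(A²+B²), direction atan2(B,A)), and a
wavenumber regression that projects the movie onto the x and y axes and
robustly regresses each position's peak time on position (slopes αx,
αy in s/mm; speed 1/√(αx²+αy²)).

## Worked example

```python
import numpy as np
from voltwave import synth
from voltwave.unmix import (unmix_trace, regression_unmix,
                            artifact_band_power, band_power)

art = synth.ArtifactSpec(heart_hz=11.0, n_harmonics=2,
                         amp_gevi=(1.0, 0.5), amp_ref=(1.0, 0.5),
                         phase_lag_s=(0.02, 0.02),
                         slow_amp_gevi=0.0, slow_amp_ref=0.0,
                         noise_sd_gevi=0.02, noise_sd_ref=0.02)
osc = synth.OscillationSpec(bands=[(30.0, 60.0, 0.3)])
trace, truth = synth.gen_trace(artifact=art, osc=osc, duration_s=60.0,
                               rate_hz=1000.0, baseline=0.0, seed=11)

res = unmix_trace(trace, tau_s=1.0, alpha=1.1, heart_hz=11.0)
p_in = artifact_band_power(trace.gevi, 1000.0, 11.0, n_harmonics=2)
p_out = artifact_band_power(res.voltage, 1000.0, 11.0, n_harmonics=2)
print(f"heartbeat-band suppression: {10*np.log10(p_in/p_out):.1f} dB")
print(f"gamma-band power recovered: "
      f"{100*band_power(res.voltage, 1000., 30., 60.)/band_power(truth.voltage, 1000., 30., 60.):.1f}%"
      " of ground truth")
reg = regression_unmix(trace)
p_reg = artifact_band_power(reg.voltage, 1000.0, 11.0, n_harmonics=2)
print(f"frequency-independent regression suppression: "
      f"{10*np.log10(p_in/p_reg):.1f} dB")
```

prints

```
heartbeat-band suppression: 47.1 dB
gamma-band power recovered: 99.6% of ground truth
frequency-independent regression suppression: 0.0 dB
```

The synthetic heartbeat artifact reaches the GEVI channel 20 ms after
the reference channel, so it is ~80° out of phase at 11 Hz: the
frequency-independent regression finds a near-zero slope and removes
essentially nothing, while the convolutional filter captures the lag
and suppresses the artifact by almost five orders of magnitude in
power, leaving the 30–60 Hz voltage band intact.

A command-line interface mirrors the library
(`voltwave simulate | preprocess | unmix | coherence | cfc | ripples |
waves | delays | pipeline`); every subcommand takes `--config` with a
YAML/JSON file and writes a JSON parameter sidecar next to its output.

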