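"""Synthetic two-channel recordings with known ground truth.

The generator reproduces the statistical structure the analyses assume:
heartbeat artifacts (fundamental ~8-14 Hz plus harmonics) present in both
channels with per-harmonic gain and time lag, slow shared hemodynamic
drift, multi-exponential photobleaching, band-limited neural oscillations
with optional phase-amplitude nesting, traveling plane waves on a pixel
grid, ripple-band bursts, and white per-channel noise.  It also provides
the mesoscope shot-noise design calculator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .types import ElectricalTrace, EventTable, TwoChannelMovie, TwoChannelTrace

__all__ = [
    "ArtifactSpec",
    "OscillationSpec",
    "PlaneWaveSpec",
    "DesignParams",
    "GroundTruth",
    "gen_trace",
    "gen_movie",
    "gen_ripple_trace",
    "gen_delay_experiments",
    "snr_bound",
    "band_limited_noise",
    "quiet_artifact",
]


@dataclass
class ArtifactSpec:
    """Heartbeat + slow hemodynamic artifact model shared by both channels.

    Each heartbeat harmonic h (h = 1..n_harmonics, frequency h*heart_hz)
    appears in the reference channel with amplitude ``amp_ref[h-1]`` and in
    the GEVI channel with amplitude ``amp_gevi[h-1]`` delayed by
    ``phase_lag_s[h-1]`` seconds -- a pure per-harmonic delay + gain map,
    a special case of a linear convolution between the channels.
    """

    heart_hz: float = 11.0
    n_harmonics: int = 2
    amp_gevi: tuple[float, ...] = (1.0, 0.5)
    amp_ref: tuple[float, ...] = (1.0, 0.5)
    phase_lag_s: tuple[float, ...] = (0.02, 0.02)
    slow_hz: float = 0.5
    slow_amp_gevi: float = 0.5
    slow_amp_ref: float = 0.5
    noise_sd_gevi: float = 0.05
    noise_sd_ref: float = 0.05

    def __post_init__(self) -> None:
        if not self.heart_hz > 0:
            raise ValueError("heart_hz must be positive")
        amps = (*self.amp_gevi, *self.amp_ref, self.slow_amp_gevi,
                self.slow_amp_ref, self.noise_sd_gevi, self.noise_sd_ref)
        if any(a < 0 for a in amps):
            raise ValueError("all amplitudes must be non-negative")
        for name in ("amp_gevi", "amp_ref", "phase_lag_s"):
            if len(getattr(self, name)) < self.n_harmonics:
                raise ValueError(f"{name} needs >= n_harmonics entries")


@dataclass
class OscillationSpec:
    """Band-limited neural oscillations, optionally phase-amplitude nested.

    ``bands`` is a list of (low_hz, high_hz, amplitude).  ``nesting``
    optionally couples one band's amplitude to another's phase:
    (carrier_index, modulated_index, preferred_phase_deg, depth), with
    depth in [0, 1] and the preferred phase in the trough-zero convention
    (0 deg = carrier trough).
    """

    bands: list[tuple[float, float, float]] = field(default_factory=list)
    nesting: tuple[int, int, float, float] | None = None

    def __post_init__(self) -> None:
        for low, high, _amp in self.bands:
            if not 0 < low < high:
                raise ValueError(f"invalid band ({low}, {high})")
        if self.nesting is not None:
            _, _, _, depth = self.nesting
            if not 0 <= depth <= 1:
                raise ValueError("modulation depth must be in [0, 1]")


@dataclass
class PlaneWaveSpec:
    """A plane wave traveling across the field of view.

    direction_deg is measured from the +X axis, counter-clockwise toward
    +Y; speed in mm/s, temporal frequency in Hz.
    """

    speed_mm_s: float = 100.0
    direction_deg: float = 0.0
    freq_hz: float = 20.0
    amplitude: float = 1.0
    # temporal bout envelope (onset_s, duration_s); a raised-cosine (Hann)
    # bout, so each pixel has a single well-defined signal maximum
    envelope: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if min(self.speed_mm_s, self.freq_hz, self.amplitude) <= 0:
            raise ValueError("speed, freq and amplitude must be positive")

    @property
    def wavelength_mm(self) -> float:
        return self.speed_mm_s / self.freq_hz


@dataclass
class DesignParams:
    """Inputs to the mesoscope shot-noise SNR bound."""

    dff: float
    mag: float
    lambda_mm: float
    freq_hz: float
    n_frames: float
    well_capacity: float
    pixel_pitch_um: float

    def __post_init__(self) -> None:
        vals = (self.mag, self.lambda_mm, self.freq_hz,
                self.n_frames, self.well_capacity, self.pixel_pitch_um)
        if any(v <= 0 for v in vals):
            raise ValueError("all design parameters must be positive")
        if self.dff < 0:
            raise ValueError("dff must be non-negative")


@dataclass
class GroundTruth:
    """True components of a generated recording."""

    voltage: np.ndarray
    artifact: np.ndarray
    trend: np.ndarray | None = None
    event_times_s: np.ndarray | None = None
    wave_params: PlaneWaveSpec | None = None
    reference_artifact: np.ndarray | None = None
    baseline: float = 0.0


def quiet_artifact() -> ArtifactSpec:
    """An all-zero artifact spec (no heartbeat, drift or noise)."""
    return ArtifactSpec(amp_gevi=(0.0, 0.0), amp_ref=(0.0, 0.0),
                        slow_amp_gevi=0.0, slow_amp_ref=0.0,
                        noise_sd_gevi=0.0, noise_sd_ref=0.0)


def band_limited_noise(rng: np.random.Generator, n: int, rate_hz: float,
                       low_hz: float, high_hz: float) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited by a 4th-order zero-phase
    Butterworth bandpass."""
    if high_hz >= rate_hz / 2:
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz at/above Nyquist {rate_hz / 2} Hz"
        )
    x = rng.standard_normal(n)
    sos = signal.butter(4, [low_hz, high_hz], btype="bandpass", fs=rate_hz,
                        output="sos")
    y = signal.sosfiltfilt(sos, x)
    sd = y.std()
    return y / sd if sd > 0 else y


def _harmonic_pair(rng, t, spec: ArtifactSpec):
    """Reference-channel heartbeat and its gain/delay-mapped GEVI image."""
    h_ref = np.zeros_like(t)
    h_gevi = np.zeros_like(t)
    for h in range(1, spec.n_harmonics + 1):
        f = h * spec.heart_hz
        phi = rng.uniform(0, 2 * np.pi)
        lag = spec.phase_lag_s[h - 1]
        h_ref += spec.amp_ref[h - 1] * np.cos(2 * np.pi * f * t + phi)
        h_gevi += spec.amp_gevi[h - 1] * np.cos(2 * np.pi * f * (t - lag) + phi)
    return h_ref, h_gevi


def _voltage(rng, n, rate_hz, osc: OscillationSpec) -> np.ndarray:
    comps = [amp * band_limited_noise(rng, n, rate_hz, low, high)
             for (low, high, amp) in osc.bands]
    if osc.nesting is not None:
        ci, mi, pref_deg, depth = osc.nesting
        carrier = comps[ci]
        # carrier phase in the trough-zero convention (analytic phase + pi)
        phase = np.angle(signal.hilbert(carrier)) + np.pi
        envelope = (1.0 + depth * np.cos(phase - np.deg2rad(pref_deg)))
        envelope /= 1.0 + depth
        comps[mi] = comps[mi] * envelope
    return np.sum(comps, axis=0) if comps else np.zeros(n)


def _trend(t, bleach) -> np.ndarray:
    if not bleach:
        return np.ones_like(t)
    out = np.zeros_like(t)
    for amp, tau in bleach:
        if tau <= 0:
            raise ValueError("bleach time constants must be positive")
        out += amp * np.exp(-t / tau)
    return out


def gen_trace(artifact: ArtifactSpec | None = None,
              osc: OscillationSpec | None = None,
              duration_s: float = 60.0,
              rate_hz: float = 1000.0,
              bleach: list[tuple[float, float]] | None = None,
              baseline: float = 1.0,
              seed: int = 0) -> tuple[TwoChannelTrace, GroundTruth]:
    """Generate a paired GEVI/reference trace with known ground truth.

    gevi = trend * (baseline + V + H_gevi + noise);
    reference = trend * (baseline + H_ref + noise).
    """
    artifact = artifact or ArtifactSpec()
    osc = osc or OscillationSpec()
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate_hz))
    if n < 2 * rate_hz:
        raise ValueError("need at least 2 s of data")
    nyq = rate_hz / 2
    top_harmonic = artifact.n_harmonics * artifact.heart_hz
    if top_harmonic >= nyq:
        raise ValueError(f"harmonic {top_harmonic} Hz at/above Nyquist {nyq} Hz")
    for low, high, _ in osc.bands:
        if high >= nyq:
            raise ValueError(f"band edge {high} Hz at/above Nyquist {nyq} Hz")
    t = np.arange(n) / rate_hz

    h_ref, h_gevi = _harmonic_pair(rng, t, artifact)
    if artifact.slow_amp_ref > 0 or artifact.slow_amp_gevi > 0:
        lo = max(0.1, artifact.slow_hz / 5)
        hi = min(max(2 * artifact.slow_hz, 1.0), nyq * 0.9)
        slow = band_limited_noise(rng, n, rate_hz, lo, hi)
        h_ref = h_ref + artifact.slow_amp_ref * slow
        h_gevi = h_gevi + artifact.slow_amp_gevi * slow

    v = _voltage(rng, n, rate_hz, osc)
    trend = _trend(t, bleach)
    noise_g = artifact.noise_sd_gevi * rng.standard_normal(n)
    noise_r = artifact.noise_sd_ref * rng.standard_normal(n)

    gevi = trend * (baseline + v + h_gevi + noise_g)
    reference = trend * (baseline + h_ref + noise_r)
    trace = TwoChannelTrace(gevi=gevi, reference=reference, rate_hz=rate_hz,
                            meta={"seed": seed})
    truth = GroundTruth(voltage=v, artifact=h_gevi, trend=trend,
                        reference_artifact=h_ref, baseline=baseline)
    return trace, truth


def gen_movie(wave: PlaneWaveSpec,
              artifact: ArtifactSpec | None = None,
              shape: tuple[int, int, int] = (600, 64, 64),
              rate_hz: float = 300.0,
              pixel_pitch_mm: float = 0.05,
              noise_sd: float = 0.0,
              seed: int = 0) -> tuple[TwoChannelMovie, GroundTruth]:
    """Generate a movie containing a traveling plane wave plus a spatially
    uniform artifact.

    Per-pixel voltage: amplitude * cos(2*pi*f*t - 2*pi*(x cos(th) +
    y sin(th)) / wavelength) * envelope, with x, y in mm.
    """
    artifact = artifact or ArtifactSpec(noise_sd_gevi=0.0, noise_sd_ref=0.0,
                                        slow_amp_gevi=0.0, slow_amp_ref=0.0)
    rng = np.random.default_rng(seed)
    nt, ny, nx = shape
    lam = wave.wavelength_mm
    if lam < 2 * pixel_pitch_mm:
        raise ValueError(
            f"wavelength {lam:.3g} mm below spatial Nyquist bound "
            f"{2 * pixel_pitch_mm:.3g} mm"
        )
    if 1.0 / wave.freq_hz < 2.0 / rate_hz:
        raise ValueError(
            f"wave period {1 / wave.freq_hz:.3g} s below temporal Nyquist "
            f"bound {2 / rate_hz:.3g} s"
        )
    t = np.arange(nt) / rate_hz
    y = np.arange(ny)[:, None] * pixel_pitch_mm
    x = np.arange(nx)[None, :] * pixel_pitch_mm
    theta = np.deg2rad(wave.direction_deg)
    spatial_phase = 2 * np.pi * (x * np.cos(theta) + y * np.sin(theta)) / lam
    phase = 2 * np.pi * wave.freq_hz * t[:, None, None] - spatial_phase[None]
    v = wave.amplitude * np.cos(phase)
    if wave.envelope is not None:
        onset, dur = wave.envelope
        env = np.zeros_like(t)
        inside = (t >= onset) & (t < onset + dur)
        env[inside] = 0.5 * (1 - np.cos(2 * np.pi * (t[inside] - onset) / dur))
        v *= env[:, None, None]

    h_ref, h_gevi = _harmonic_pair(rng, t, artifact)
    gevi = v + h_gevi[:, None, None]
    reference = np.broadcast_to(h_ref[:, None, None], shape).copy()
    if noise_sd > 0:
        gevi = gevi + noise_sd * rng.standard_normal(shape)
        reference = reference + noise_sd * rng.standard_normal(shape)
    movie = TwoChannelMovie(gevi=gevi, reference=reference, rate_hz=rate_hz,
                            pixel_pitch_mm=pixel_pitch_mm, meta={"seed": seed})
    truth = GroundTruth(voltage=v, artifact=h_gevi, reference_artifact=h_ref,
                        wave_params=wave)
    return movie, truth


def _pink_noise(rng, n: int) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise."""
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n)
    scale = np.ones_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n)
    return x / x.std()


def gen_ripple_trace(rate_hz: float = 1000.0,
                     duration_s: float = 60.0,
                     n_events: int = 20,
                     ripple_hz: float = 150.0,
                     width_s: float = 0.060,
                     amp_sd_ratio: float = 6.0,
                     noise_color: str = "pink",
                     noise_sd_uv: float = 100.0,
                     min_separation_s: float = 0.3,
                     seed: int = 0) -> tuple[ElectricalTrace, EventTable]:
    """LFP-like noise plus Hann-windowed ripple-band bursts.

    Burst peak amplitude is ``amp_sd_ratio`` times the noise standard
    deviation; true burst centers are returned in the event table.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate_hz))
    if noise_color == "pink":
        noise = noise_sd_uv * _pink_noise(rng, n)
    elif noise_color == "white":
        noise = noise_sd_uv * rng.standard_normal(n)
    else:
        raise ValueError(f"unknown noise_color {noise_color!r}")

    margin = width_s / 2 + 0.05
    span = duration_s - 2 * margin
    if n_events > 0:
        if span < (n_events - 1) * min_separation_s:
            raise ValueError(
                f"cannot place {n_events} events >= {min_separation_s} s apart "
                f"in {duration_s} s"
            )
        jitter_max = max(
            0.0, (span / max(n_events - 1, 1) - min_separation_s) / 2)
        slots = np.linspace(margin + jitter_max,
                            duration_s - margin - jitter_max, n_events)
        centers = slots + rng.uniform(-jitter_max, jitter_max, n_events)
        centers.sort()
    else:
        centers = np.empty(0)

    x = noise.copy()
    half = int(round(width_s * rate_hz / 2))
    win = signal.windows.hann(2 * half + 1)
    for c in centers:
        i0 = int(round(c * rate_hz))
        idx = np.arange(i0 - half, i0 + half + 1)
        tt = (idx - i0) / rate_hz
        burst = amp_sd_ratio * noise_sd_uv * win * np.cos(
            2 * np.pi * ripple_hz * tt)
        x[idx] += burst
    return (ElectricalTrace(samples=x, rate_hz=rate_hz),
            EventTable(times_s=centers))


def gen_delay_experiments(true_delay_s: float,
                          indicator_delays_s,
                          design,
                          n_bouts: int = 100,
                          noise_sd_s: float = 0.0005,
                          seed: int = 0) -> np.ndarray:
    """Draw per-bout apparent delays for each experiment of a delay design.

    Returns an array (n_experiments, n_bouts).  Each experiment's mean is
    true_delay * includes + d_A - d_B per its design row; bouts add
    Gaussian noise of s.d. ``noise_sd_s``.
    """
    from .delays import DelayDesign  # local import to avoid cycle

    if not isinstance(design, DelayDesign):
        raise TypeError("design must be a DelayDesign")
    d = np.asarray(indicator_delays_s, dtype=float)
    if d.min() < 0:
        raise ValueError("indicator delays must be non-negative")
    rng = np.random.default_rng(seed)
    means = design.predict(true_delay_s, d)
    return means[:, None] + noise_sd_s * rng.standard_normal(
        (len(means), n_bouts))


def snr_bound(p: DesignParams) -> dict[str, float]:
    """Shot-noise-limited SNR bound for detecting a traveling wave.

    Photons are pooled over half a spatial wavelength (the wave's
    correlation length) and ``n_frames`` frames of pixels at well
    capacity:  n_max = (M * lambda / (2 * pitch))**2 * nf * WC, the shot
    noise is sigma_eps = sqrt(n_max), and the amplitude resolution bound
    is  SNR <= (dF/F) * sqrt(n_max).
    """
    lam_um = p.lambda_mm * 1000.0
    n_pixels = (p.mag * lam_um / (2.0 * p.pixel_pitch_um)) ** 2
    n_max = n_pixels * p.n_frames * p.well_capacity
    sigma_eps = np.sqrt(n_max)
    return {"snr": p.dff * sigma_eps, "n_max": n_max, "sigma_eps": sigma_eps}
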