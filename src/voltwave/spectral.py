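"""Coherence, spectrograms, envelopes, cross-correlation, event-triggered
averaging, cross-frequency coupling, and behavioral-state segmentation.

Phase convention for carrier oscillations: 0 degrees is the trough (the
greatest hyperpolarization), i.e. the reported phase is the analytic
phase of the band-passed signal shifted by 180 degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats
from scipy.fft import fft, ifft

from .types import ElectricalTrace, EventTable

__all__ = [
    "CoherenceResult",
    "CFCResult",
    "coherence",
    "wavelet_spectrogram",
    "band_envelope",
    "cross_correlation",
    "event_triggered_average",
    "cfc",
    "segment_by_band_power",
]


@dataclass
class CoherenceResult:
    """Frequency-resolved coherence magnitude and phase between two
    signals.  magnitude = sqrt of the magnitude-squared coherence."""

    freqs_hz: np.ndarray
    magnitude: np.ndarray
    phase_rad: np.ndarray
    n_segments: int


@dataclass
class CFCResult:
    """Phase-amplitude coupling profile: mean modulated-band amplitude in
    bins of carrier phase (trough = 0 degrees)."""

    carrier_band_hz: tuple[float, float]
    modulated_band_hz: tuple[float, float]
    phase_grid_deg: np.ndarray
    amplitude_by_phase: np.ndarray
    preferred_phase_deg: float
    modulation_depth: float
    n_cycles: int


def coherence(x, y, rate_hz: float, seg_s: float = 1.0,
              overlap_s: float = 0.8) -> CoherenceResult:
    """Welch coherence over seg_s-long segments overlapping by overlap_s.

    Magnitude is the square root of the magnitude-squared coherence;
    phase comes from the averaged cross-spectrum.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("inputs must share length")
    nperseg = int(round(seg_s * rate_hz))
    noverlap = int(round(overlap_s * rate_hz))
    step = nperseg - noverlap
    n_segments = (len(x) - nperseg) // step + 1 if len(x) >= nperseg else 0
    if n_segments < 3:
        raise ValueError(f"{n_segments} segment(s); need >= 3")
    freqs, cxy2 = signal.coherence(x, y, fs=rate_hz, nperseg=nperseg,
                                   noverlap=noverlap)
    _, pxy = signal.csd(x, y, fs=rate_hz, nperseg=nperseg, noverlap=noverlap)
    return CoherenceResult(freqs_hz=freqs,
                           magnitude=np.sqrt(np.clip(cxy2, 0.0, 1.0)),
                           phase_rad=np.angle(pxy),
                           n_segments=n_segments)


def wavelet_spectrogram(x, rate_hz: float, freqs_hz,
                        n_cycles: float = 7.0) -> np.ndarray:
    """Analytic Morlet-class time-frequency amplitude (freqs x time).

    Each row is |analytic bandpass| with a Gaussian frequency-domain
    profile of width sigma_f = f0 / n_cycles and unit peak gain, so a
    pure tone of amplitude a reports amplitude a at its own frequency.
    """
    x = np.asarray(x, dtype=float)
    freqs_hz = np.atleast_1d(np.asarray(freqs_hz, dtype=float))
    if freqs_hz.size == 0:
        raise ValueError("empty frequency list")
    if np.any((freqs_hz <= 0) | (freqs_hz >= rate_hz / 2)):
        raise ValueError("probe frequencies must lie in (0, Nyquist)")
    n = len(x)
    xf = fft(x)
    f_grid = np.fft.fftfreq(n, 1.0 / rate_hz)
    out = np.empty((len(freqs_hz), n))
    for i, f0 in enumerate(freqs_hz):
        sigma_f = f0 / n_cycles
        # analytic filter: positive frequencies only, unit gain at f0
        h = np.exp(-0.5 * ((f_grid - f0) / sigma_f) ** 2)
        h[f_grid < 0] = 0.0
        h *= 2.0
        out[i] = np.abs(ifft(xf * h))
    return out


def band_envelope(x, rate_hz: float, band_hz: tuple[float, float],
                  order: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Carrier phase (trough = 0 rad) and amplitude via a zero-phase
    bandpass and the Hilbert analytic signal.

    Returns (phase_rad in (-pi, pi], amplitude).  A near-zero-power band
    returns near-zero amplitude (warning flag is the amplitude itself).
    """
    x = np.asarray(x, dtype=float)
    if band_hz[1] >= rate_hz / 2:
        raise ValueError("band at/above Nyquist")
    sos = signal.butter(order, band_hz, btype="bandpass", fs=rate_hz,
                        output="sos")
    bf = signal.sosfiltfilt(sos, x)
    analytic = signal.hilbert(bf)
    # analytic phase is 0 at the cosine peak; shift so the trough maps to 0
    phase = np.angle(analytic * np.exp(1j * np.pi))
    return phase, np.abs(analytic)


def cross_correlation(x, y, rate_hz: float, max_lag_s: float,
                      signed_peak: bool = True,
                      per_lag_norm: bool = False
                      ) -> tuple[np.ndarray, np.ndarray, float]:
    """Normalized cross-correlation on a lag grid with sub-sample peak
    localization by parabolic interpolation.

    Positive peak lag means y lags x (y(t) ~ x(t - lag)).  With
    ``signed_peak`` the maximum of the correlation is taken; otherwise
    the maximum of its absolute value (sign reported in the sequence).
    ``per_lag_norm`` normalizes each lag by the energies of the actual
    overlapping samples instead of the whole traces, which removes the
    taper that pulls narrow-band peaks toward zero lag on short excerpts
    (a pure delay then correlates at exactly 1 at its true lag).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("inputs must share length")
    n = len(x)
    max_lag = int(round(max_lag_s * rate_hz))
    if max_lag >= n // 2:
        raise ValueError("max_lag must be below half the duration")
    x0 = x - x.mean()
    y0 = y - y.mean()
    denom = np.sqrt(np.dot(x0, x0) * np.dot(y0, y0))
    if denom <= 0:
        raise ValueError("zero-variance input")
    full = signal.correlate(y0, x0, mode="full")
    mid = n - 1
    lags = np.arange(-max_lag, max_lag + 1)
    corr = full[mid - max_lag: mid + max_lag + 1]
    if per_lag_norm:
        cx = np.concatenate([[0.0], np.cumsum(x0 ** 2)])
        cy = np.concatenate([[0.0], np.cumsum(y0 ** 2)])
        dens = np.empty(len(lags))
        for k, ell in enumerate(lags):
            if ell >= 0:  # y shifted left: x[0:n-ell] vs y[ell:n]
                ex = cx[n - ell] - cx[0]
                ey = cy[n] - cy[ell]
            else:
                ex = cx[n] - cx[-ell]
                ey = cy[n + ell] - cy[0]
            dens[k] = np.sqrt(ex * ey)
        corr = np.divide(corr, dens, out=np.zeros_like(corr),
                         where=dens > 0)
    else:
        corr = corr / denom
    metric = corr if signed_peak else np.abs(corr)
    i = int(np.argmax(metric))
    # parabolic refinement around the integer-lag maximum
    if 0 < i < len(corr) - 1:
        y0_, y1, y2 = metric[i - 1], metric[i], metric[i + 1]
        denom2 = y0_ - 2 * y1 + y2
        delta = 0.5 * (y0_ - y2) / denom2 if denom2 != 0 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    lag_at_peak_s = (lags[i] + delta) / rate_hz
    return lags / rate_hz, corr, float(lag_at_peak_s)


def event_triggered_average(x, rate_hz: float, event_times_s,
                            window_s: tuple[float, float] = (-0.5, 0.5),
                            t0_s: float = 0.0):
    """Mean of event-locked excerpts of a trace or a (freq x time)
    spectrogram, with a per-time 95% t-interval.

    Events whose window runs off an edge are dropped (counted in
    n_dropped).  Returns (times_rel_s, mean, ci95_halfwidth, n_used).
    """
    x = np.asarray(x, dtype=float)
    time_axis = x.ndim - 1
    n = x.shape[time_axis]
    pre = int(round(-window_s[0] * rate_hz))
    post = int(round(window_s[1] * rate_hz))
    excerpts = []
    for t_ev in np.atleast_1d(event_times_s):
        i = int(round((t_ev - t0_s) * rate_hz))
        if i - pre < 0 or i + post + 1 > n:
            continue
        sl = [slice(None)] * x.ndim
        sl[time_axis] = slice(i - pre, i + post + 1)
        excerpts.append(x[tuple(sl)])
    if not excerpts:
        raise ValueError("no events fully inside the recording")
    stack = np.stack(excerpts)
    mean = stack.mean(axis=0)
    n_used = len(excerpts)
    if n_used > 1:
        sem = stack.std(axis=0, ddof=1) / np.sqrt(n_used)
        ci = sem * stats.t.ppf(0.975, n_used - 1)
    else:
        ci = np.zeros_like(mean)
    times = np.arange(-pre, post + 1) / rate_hz
    return times, mean, ci, n_used


def cfc(x, rate_hz: float, carrier_band_hz: tuple[float, float],
        modulated_band_hz: tuple[float, float],
        n_phase_bins: int = 36, n_freqs: int = 8) -> CFCResult:
    """Phase-amplitude cross-frequency coupling.

    Carrier phase comes from the band-passed analytic signal (trough =
    0 degrees); modulated-band amplitude is the wavelet spectrogram of
    the raw signal averaged across the modulated band.  Amplitude is
    binned by carrier phase over complete carrier cycles (delimited at
    phase wraps); the preferred phase is the amplitude-weighted circular
    mean.
    """
    x = np.asarray(x, dtype=float)
    if carrier_band_hz[1] >= modulated_band_hz[0]:
        raise ValueError("carrier band must lie below the modulated band")
    phase, _ = band_envelope(x, rate_hz, carrier_band_hz)
    freqs = np.linspace(modulated_band_hz[0], modulated_band_hz[1], n_freqs)
    amp = wavelet_spectrogram(x, rate_hz, freqs).mean(axis=0)

    # complete cycles delimited at wraps from +pi to -pi
    wraps = np.flatnonzero(np.diff(phase) < -np.pi)
    n_cycles = max(len(wraps) - 1, 0)
    if n_cycles < 10:
        raise ValueError(f"only {n_cycles} carrier cycles; need >= 10")
    sel = slice(wraps[0] + 1, wraps[-1] + 1)
    phase_deg = np.degrees(phase[sel]) % 360.0
    amp_sel = amp[sel]

    edges = np.linspace(0.0, 360.0, n_phase_bins + 1)
    which = np.clip(np.digitize(phase_deg, edges) - 1, 0, n_phase_bins - 1)
    sums = np.bincount(which, weights=amp_sel, minlength=n_phase_bins)
    counts = np.bincount(which, minlength=n_phase_bins)
    profile = np.divide(sums, counts, out=np.zeros(n_phase_bins),
                        where=counts > 0)
    centers = edges[:-1] + np.diff(edges) / 2
    vec = np.sum(profile * np.exp(1j * np.radians(centers)))
    preferred = float(np.degrees(np.angle(vec)) % 360.0)
    mean_amp = profile.mean()
    depth = float((profile.max() - profile.min()) / mean_amp) \
        if mean_amp > 0 else 0.0
    return CFCResult(carrier_band_hz=tuple(carrier_band_hz),
                     modulated_band_hz=tuple(modulated_band_hz),
                     phase_grid_deg=centers, amplitude_by_phase=profile,
                     preferred_phase_deg=preferred, modulation_depth=depth,
                     n_cycles=n_cycles)


def segment_by_band_power(lfp: ElectricalTrace,
                          band_hz: tuple[float, float] = (5.0, 9.0),
                          threshold: float | str = "auto-median",
                          smooth_s: float = 1.0,
                          min_epoch_s: float = 2.0) -> EventTable:
    """Label run/rest epochs from band (theta) power.

    The band-power envelope is smoothed over ``smooth_s``; samples above
    the threshold (the envelope median for "auto-median") are "run",
    below "rest".  Epochs shorter than ``min_epoch_s`` are merged into
    their neighbors.  Returns an EventTable of epoch starts with labels
    and an ``end_s`` extras column.
    """
    if lfp.duration_s < 30:
        raise ValueError("need >= 30 s of data for state segmentation")
    _, amp = band_envelope(lfp.samples, lfp.rate_hz, band_hz)
    power = amp ** 2
    w = max(int(round(smooth_s * lfp.rate_hz)), 1)
    smoothed = np.convolve(power, np.ones(w) / w, mode="same")
    if threshold == "auto-median":
        thr = float(np.median(smoothed))
    else:
        thr = float(threshold)
    is_run = smoothed > thr
    if is_run.all() or (~is_run).all():
        label = "run" if is_run.all() else "rest"
        return EventTable(times_s=np.array([0.0]), labels=[label],
                          extras={"end_s": np.array([lfp.duration_s])})
    # epoch boundaries, then merge short epochs into the previous one
    change = np.flatnonzero(np.diff(is_run.astype(int))) + 1
    bounds = np.concatenate([[0], change, [len(is_run)]])
    min_len = int(round(min_epoch_s * lfp.rate_hz))
    segs = [[bounds[i], bounds[i + 1], bool(is_run[bounds[i]])]
            for i in range(len(bounds) - 1)]
    merged = [segs[0]]
    for s in segs[1:]:
        if s[1] - s[0] < min_len:
            merged[-1][1] = s[1]
        elif s[2] == merged[-1][2]:
            merged[-1][1] = s[1]
        else:
            merged.append(s)
    if len(merged) > 1 and merged[0][1] - merged[0][0] < min_len:
        merged[1][0] = merged[0][0]
        merged.pop(0)
    starts = np.array([s[0] for s in merged]) / lfp.rate_hz
    ends = np.array([s[1] for s in merged]) / lfp.rate_hz
    labels = ["run" if s[2] else "rest" for s in merged]
    return EventTable(times_s=starts, labels=labels, extras={"end_s": ends})
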