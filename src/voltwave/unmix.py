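"""Frequency-dependent convolutional (Wiener) unmixing.

The GEVI channel is modeled as G(t) = V(t) + H(t) with the artifact
H(t) = (F * R)(t) a linear convolution of the voltage-insensitive
reference channel.  The filter is estimated per frequency from windowed,
overlapping segments as the cross- to auto-spectrum ratio

    f(w) = <g_k(w) r_k*(w)>_k / <r_k(w) r_k*(w)>_k,

its magnitude is capped at alpha times the magnitude at the heartbeat
fundamental (phases preserved), and the time-domain kernel F(t) is the
inverse transform.  Subtraction of H = F * R then recovers V.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.fft import irfft, next_fast_len, rfft, rfftfreq

from .types import TwoChannelTrace

__all__ = [
    "SegmentedSpectra",
    "SpectralFilter",
    "UnmixResult",
    "segment_spectra",
    "estimate_filter",
    "detect_heartbeat",
    "unmix_trace",
    "regression_unmix",
    "select_parameters",
    "unmix_movie",
    "artifact_band_power",
    "band_power",
]

log = logging.getLogger(__name__)


@dataclass
class SegmentedSpectra:
    """Windowed per-segment spectra of both channels (segments x freqs)."""

    freqs_hz: np.ndarray
    g: np.ndarray
    r: np.ndarray
    n_segments: int
    tau_s: float
    overlap_frac: float
    window: str
    rate_hz: float
    seg_len: int


@dataclass
class SpectralFilter:
    """Estimated complex Wiener filter and its time-domain kernel."""

    freqs_hz: np.ndarray
    f: np.ndarray          # complex gain per frequency
    F_t: np.ndarray        # real kernel, zero lag at index len//2
    alpha: float
    heart_hz: float
    tau_s: float
    overlap_frac: float
    rate_hz: float

    @property
    def kernel_center(self) -> int:
        return len(self.F_t) // 2


@dataclass
class UnmixResult:
    """Voltage estimate with the removed artifact components.

    The reconstruction invariant holds to float precision:
    input G = voltage + artifact_estimate (+ prefilter_artifact).
    """

    voltage: np.ndarray
    artifact_estimate: np.ndarray
    prefilter_artifact: np.ndarray | None = None
    filter: SpectralFilter | None = None
    residual_metrics: dict = field(default_factory=dict)


def _segment_starts(n_samples: int, seg: int, step: int) -> np.ndarray:
    n_seg = (n_samples - seg) // step + 1
    return np.arange(n_seg) * step


def segment_spectra(trace: TwoChannelTrace, tau_s: float = 1.0,
                    overlap_frac: float = 0.75,
                    window: str = "hann") -> SegmentedSpectra:
    """Split both channels into overlapping segments of duration tau_s
    (successive starts every (1 - overlap_frac) * tau_s) and return the
    windowed DFT of every segment."""
    rate = trace.rate_hz
    seg = int(round(tau_s * rate))
    if seg < 8:
        raise ValueError(f"segment of {seg} samples too short (need >= 8)")
    if not 0 <= overlap_frac < 1:
        raise ValueError("overlap_frac must be in [0, 1)")
    step = int(round((1.0 - overlap_frac) * seg))
    step = max(step, 1)
    starts = _segment_starts(len(trace), seg, step)
    if len(starts) < 2:
        raise ValueError(
            f"trace yields {len(starts)} segment(s); need >= 2 for averaging"
        )
    win = signal.get_window(window, seg, fftbins=True)
    g = np.empty((len(starts), seg // 2 + 1), dtype=complex)
    r = np.empty_like(g)
    for i, s0 in enumerate(starts):
        g[i] = rfft(trace.gevi[s0:s0 + seg] * win)
        r[i] = rfft(trace.reference[s0:s0 + seg] * win)
    return SegmentedSpectra(
        freqs_hz=rfftfreq(seg, 1.0 / rate), g=g, r=r, n_segments=len(starts),
        tau_s=tau_s, overlap_frac=overlap_frac, window=window, rate_hz=rate,
        seg_len=seg)


def _finalize_filter(f: np.ndarray, freqs: np.ndarray, alpha: float,
                     heart_hz: float, seg_len: int, tau_s: float,
                     overlap_frac: float, rate_hz: float) -> SpectralFilter:
    """Cap magnitudes at alpha * |f(heart bin)| (phases kept), zero DC and
    build the centered real kernel."""
    f = f.copy()
    f[0] = 0.0  # detrended inputs: no DC transfer
    bin0 = int(np.argmin(np.abs(freqs - heart_hz)))
    limit = alpha * np.abs(f[bin0])
    if limit > 0:
        mag = np.abs(f)
        over = mag > limit
        if np.any(over):
            f[over] = limit * np.exp(1j * np.angle(f[over]))
    kernel = np.fft.fftshift(irfft(f, seg_len))
    return SpectralFilter(freqs_hz=freqs, f=f, F_t=kernel, alpha=alpha,
                          heart_hz=float(freqs[bin0]), tau_s=tau_s,
                          overlap_frac=overlap_frac, rate_hz=rate_hz)


def estimate_filter(spectra: SegmentedSpectra, alpha: float = 1.1,
                    heart_hz: float | None = None) -> SpectralFilter:
    """Estimate the per-frequency Wiener gain from segmented spectra.

    Frequencies where the reference has no power get gain 0 (logged).
    If heart_hz is None it is detected from the averaged reference
    spectrum within the default search band.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    num = np.mean(spectra.g * np.conj(spectra.r), axis=0)
    den = np.mean(np.abs(spectra.r) ** 2, axis=0)
    if heart_hz is None:
        heart_hz = _heartbeat_from_power(spectra.freqs_hz, den.real)
    dead = den <= den.max() * 1e-15
    if np.any(dead):
        log.info("zero reference power at %d bins; gain set to 0",
                 int(dead.sum()))
    f = np.zeros_like(num)
    np.divide(num, den, out=f, where=~dead)
    return _finalize_filter(f, spectra.freqs_hz, alpha, heart_hz,
                            spectra.seg_len, spectra.tau_s,
                            spectra.overlap_frac, spectra.rate_hz)


def _heartbeat_from_power(freqs: np.ndarray, power: np.ndarray,
                          search_band_hz: tuple[float, float] = (6.0, 16.0),
                          min_peak_ratio: float = 3.0) -> float:
    in_band = (freqs >= search_band_hz[0]) & (freqs <= search_band_hz[1])
    if not np.any(in_band):
        raise ValueError("search band contains no frequency bins")
    band_power = power[in_band]
    band_freqs = freqs[in_band]
    i_peak = int(np.argmax(band_power))
    peak_power = band_power[i_peak]
    if peak_power < min_peak_ratio * np.median(band_power):
        raise ValueError(
            "no clear heartbeat peak in the search band; pass heart_hz"
        )
    f_peak = band_freqs[i_peak]
    # prefer the fundamental if a strong peak sits at ~half the frequency
    half = f_peak / 2
    near_half = np.abs(freqs - half) <= max(0.1 * half, freqs[1] - freqs[0])
    if np.any(near_half):
        p_half = power[near_half].max()
        if p_half >= 0.5 * peak_power and half >= search_band_hz[0] / 2:
            return float(freqs[near_half][np.argmax(power[near_half])])
    return float(f_peak)


def detect_heartbeat(reference, rate_hz: float,
                     search_band_hz: tuple[float, float] = (6.0, 16.0)
                     ) -> float:
    """Heartbeat fundamental from the largest Welch-spectrum peak in the
    search band, preferring the fundamental over a harmonic."""
    reference = np.asarray(reference, dtype=float)
    if len(reference) < 5 * rate_hz:
        raise ValueError("need >= 5 s of data for heartbeat detection")
    nperseg = int(min(len(reference), 4 * rate_hz))
    freqs, power = signal.welch(reference - reference.mean(), fs=rate_hz,
                                nperseg=nperseg)
    return _heartbeat_from_power(freqs, power, search_band_hz)


def _apply_kernel(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """'Same'-length linear convolution along axis 0 with a centered
    kernel, reflection-padded edges."""
    n = len(kernel)
    center = n // 2
    pad = center
    L = x.shape[0]
    left = x[pad:0:-1]
    right = x[-2:-pad - 2:-1]
    xp = np.concatenate([left, x, right], axis=0)
    nfft = next_fast_len(xp.shape[0] + n - 1)
    kf = rfft(kernel, nfft)
    if x.ndim == 1:
        full = irfft(rfft(xp, nfft) * kf, nfft)
    else:
        shape = (nfft,) + (1,) * (x.ndim - 1)
        full = irfft(rfft(xp, nfft, axis=0)
                     * kf.reshape((-1,) + (1,) * (x.ndim - 1)), nfft, axis=0)
    return full[pad + center: pad + center + L]


def unmix_trace(trace: TwoChannelTrace, tau_s: float = 1.0,
                alpha: float = 1.1, overlap_frac: float = 0.75,
                heart_hz: float | None = None,
                window: str = "hann") -> UnmixResult:
    """Full unmixing of a two-channel trace: estimate the filter, form
    H = F * R and return V = G - H."""
    if heart_hz is None:
        heart_hz = detect_heartbeat(trace.reference, trace.rate_hz)
    spectra = segment_spectra(trace, tau_s=tau_s, overlap_frac=overlap_frac,
                              window=window)
    filt = estimate_filter(spectra, alpha=alpha, heart_hz=heart_hz)
    h = _apply_kernel(trace.reference, filt.F_t)
    v = trace.gevi - h
    metrics = {
        "artifact_band_power_in": artifact_band_power(
            trace.gevi, trace.rate_hz, heart_hz),
        "artifact_band_power_out": artifact_band_power(
            v, trace.rate_hz, heart_hz),
        "edge_flag_s": tau_s / 2,
    }
    return UnmixResult(voltage=v, artifact_estimate=h, filter=filt,
                       residual_metrics=metrics)


def regression_unmix(trace: TwoChannelTrace) -> UnmixResult:
    """Frequency-independent baseline: V = G - b R with b the ordinary
    least-squares slope of G on R."""
    r = trace.reference - trace.reference.mean()
    g = trace.gevi - trace.gevi.mean()
    var = np.dot(r, r)
    if var <= 0:
        raise ValueError("reference has zero variance")
    b = float(np.dot(g, r) / var)
    h = b * trace.reference
    return UnmixResult(voltage=trace.gevi - h, artifact_estimate=h,
                       residual_metrics={"beta": b})


def band_power(x, rate_hz: float, low_hz: float, high_hz: float) -> float:
    """Integrated Welch power spectral density over [low, high] Hz."""
    x = np.asarray(x, dtype=float)
    nperseg = int(min(len(x), 4 * rate_hz))
    freqs, psd = signal.welch(x - x.mean(), fs=rate_hz, nperseg=nperseg)
    sel = (freqs >= low_hz) & (freqs <= high_hz)
    return float(np.trapezoid(psd[sel], freqs[sel]))


def artifact_band_power(x, rate_hz: float, heart_hz: float,
                        n_harmonics: int = 3,
                        half_width_hz: float = 2.0) -> float:
    """Summed power in heart_hz +/- half_width and its harmonics."""
    total = 0.0
    for h in range(1, n_harmonics + 1):
        f = h * heart_hz
        if f + half_width_hz >= rate_hz / 2:
            break
        total += band_power(x, rate_hz, f - half_width_hz, f + half_width_hz)
    return total


def select_parameters(trace: TwoChannelTrace,
                      tau_grid_s=(0.5, 1.0, 1.5, 2.0),
                      alpha_grid=(1.0, 1.1, 1.2, 1.3),
                      overlap_frac: float = 0.75,
                      heart_hz: float | None = None
                      ) -> tuple[float, float, pd.DataFrame]:
    """Train/test selection of (tau, alpha).

    The filter is estimated on the first half of the recording and scored
    by the artifact-band residual power of the unmixed second half; the
    grid argmin is returned (ties broken toward the lowest tau, then the
    lowest alpha).
    """
    tau_grid_s = list(tau_grid_s)
    alpha_grid = list(alpha_grid)
    if not tau_grid_s or not alpha_grid:
        raise ValueError("parameter grids must be non-empty")
    if trace.duration_s < 8 * max(tau_grid_s):
        raise ValueError("recording too short for train/test selection")
    if heart_hz is None:
        heart_hz = detect_heartbeat(trace.reference, trace.rate_hz)
    mid = len(trace) // 2
    train = TwoChannelTrace(trace.gevi[:mid], trace.reference[:mid],
                            trace.rate_hz)
    test_g, test_r = trace.gevi[mid:], trace.reference[mid:]
    rows = []
    for tau in tau_grid_s:
        spectra = segment_spectra(train, tau_s=tau, overlap_frac=overlap_frac)
        num = np.mean(spectra.g * np.conj(spectra.r), axis=0)
        den = np.mean(np.abs(spectra.r) ** 2, axis=0)
        dead = den <= den.max() * 1e-15
        raw = np.zeros_like(num)
        np.divide(num, den, out=raw, where=~dead)
        for alpha in alpha_grid:
            filt = _finalize_filter(raw, spectra.freqs_hz, alpha, heart_hz,
                                    spectra.seg_len, tau, overlap_frac,
                                    trace.rate_hz)
            v = test_g - _apply_kernel(test_r, filt.F_t)
            score = artifact_band_power(v, trace.rate_hz, heart_hz)
            rows.append({"tau_s": tau, "alpha": alpha, "score": score})
    table = pd.DataFrame(rows)
    best = table.sort_values(["score", "tau_s", "alpha"]).iloc[0]
    return float(best["tau_s"]), float(best["alpha"]), table


def _disk_average(frames: np.ndarray, radius_px: float) -> np.ndarray:
    """Per-frame mean over a disk neighborhood (edge-normalized)."""
    r = int(np.ceil(radius_px))
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    disk = (yy ** 2 + xx ** 2 <= radius_px ** 2).astype(float)
    norm = signal.fftconvolve(np.ones(frames.shape[1:]), disk, mode="same")
    out = signal.fftconvolve(frames, disk[None], mode="same", axes=(1, 2))
    return out / norm[None]


def _estimate_filters_pixels(g2d: np.ndarray, r2d: np.ndarray, rate_hz: float,
                             tau_s: float, overlap_frac: float, alpha: float,
                             heart_hz: float, window: str = "hann"):
    """Per-pixel Wiener gains for flattened (time x pixels) movies.

    Returns the centered kernels as an array (kernel_len, n_pixels).
    """
    seg = int(round(tau_s * rate_hz))
    step = max(int(round((1.0 - overlap_frac) * seg)), 1)
    starts = _segment_starts(g2d.shape[0], seg, step)
    if len(starts) < 2:
        raise ValueError("movie too short for filter averaging")
    win = signal.get_window(window, seg, fftbins=True)[:, None]
    n_freq = seg // 2 + 1
    num = np.zeros((n_freq, g2d.shape[1]), dtype=complex)
    den = np.zeros((n_freq, g2d.shape[1]))
    for s0 in starts:
        gk = rfft(g2d[s0:s0 + seg] * win, axis=0)
        rk = rfft(r2d[s0:s0 + seg] * win, axis=0)
        num += gk * np.conj(rk)
        den += np.abs(rk) ** 2
    freqs = rfftfreq(seg, 1.0 / rate_hz)
    dead = den <= den.max() * 1e-15
    f = np.zeros_like(num)
    np.divide(num, den, out=f, where=~dead)
    f[0] = 0.0
    bin0 = int(np.argmin(np.abs(freqs - heart_hz)))
    limit = alpha * np.abs(f[bin0])
    mag = np.abs(f)
    over = mag > limit[None, :]
    scale = np.ones_like(mag)
    with np.errstate(invalid="ignore", divide="ignore"):
        np.divide(limit[None, :], mag, out=scale, where=over)
    f = f * scale
    kernels = np.fft.fftshift(irfft(f, seg, axis=0), axes=0)
    return kernels


def _apply_kernels_pixels(x2d: np.ndarray, kernels: np.ndarray) -> np.ndarray:
    """Convolve each pixel trace with its own centered kernel."""
    n = kernels.shape[0]
    center = n // 2
    pad = center
    L = x2d.shape[0]
    xp = np.concatenate([x2d[pad:0:-1], x2d, x2d[-2:-pad - 2:-1]], axis=0)
    nfft = next_fast_len(xp.shape[0] + n - 1)
    full = irfft(rfft(xp, nfft, axis=0) * rfft(kernels, nfft, axis=0),
                 nfft, axis=0)
    return full[pad + center: pad + center + L]


def unmix_movie(movie, tau_s: float = 1.0, alpha: float = 1.1,
                overlap_frac: float = 0.75, heart_hz: float | None = None,
                prefilter_scale_mm: float | None = 1.0) -> UnmixResult:
    """Two-stage unmixing of a movie.

    Stage 1 removes the spatially smooth artifact: the reference movie is
    averaged over disks of radius ``prefilter_scale_mm`` (or globally when
    the scale reaches the field of view, or when None), one filter is fit
    between the field-averaged traces, and Havg = F * Ravg is subtracted
    per pixel.  Stage 2 fits an individual filter per pixel between its
    raw reference trace and the stage-1 residual.  The per-pixel
    reconstruction G = V + H + Havg holds to float precision.
    """
    nt, ny, nx = movie.shape
    if heart_hz is None:
        heart_hz = detect_heartbeat(movie.reference.mean(axis=(1, 2)),
                                    movie.rate_hz)
    fov_mm = max(ny, nx) * movie.pixel_pitch_mm
    if prefilter_scale_mm is not None and prefilter_scale_mm < movie.pixel_pitch_mm:
        raise ValueError("prefilter_scale_mm below pixel pitch")

    # stage 1: spatially averaged reference
    if prefilter_scale_mm is None or prefilter_scale_mm >= fov_mm:
        ravg = np.broadcast_to(
            movie.reference.mean(axis=(1, 2))[:, None, None], movie.shape)
    else:
        ravg = _disk_average(movie.reference,
                             prefilter_scale_mm / movie.pixel_pitch_mm)
    g_mean = movie.gevi.mean(axis=(1, 2))
    r_mean = movie.reference.mean(axis=(1, 2))
    spectra = segment_spectra(
        TwoChannelTrace(g_mean, r_mean, movie.rate_hz),
        tau_s=tau_s, overlap_frac=overlap_frac)
    filt_avg = estimate_filter(spectra, alpha=alpha, heart_hz=heart_hz)
    havg = _apply_kernel(ravg.reshape(nt, -1), filt_avg.F_t)
    vres = movie.gevi.reshape(nt, -1) - havg

    # stage 2: per-pixel filters against the raw reference
    r2d = movie.reference.reshape(nt, -1)
    kernels = _estimate_filters_pixels(vres, r2d, movie.rate_hz, tau_s,
                                       overlap_frac, alpha, heart_hz)
    h2 = _apply_kernels_pixels(r2d, kernels)
    v = (vres - h2).reshape(movie.shape)
    return UnmixResult(voltage=v,
                       artifact_estimate=h2.reshape(movie.shape),
                       prefilter_artifact=havg.reshape(movie.shape),
                       filter=filt_avg,
                       residual_metrics={"heart_hz": heart_hz,
                                         "tau_s": tau_s, "alpha": alpha})
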