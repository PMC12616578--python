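"""Trace and movie conditioning before unmixing.

Notch filtering, photobleaching detrending (low-pass baseline or
multi-exponential fits), zero-phase high-pass, cross-channel
decrosstalking, spatial binning, and segmented low-rank (SVD) movie
denoising.  All temporal filters are zero-phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize, signal

__all__ = [
    "TrendFit",
    "notch",
    "detrend_lowpass",
    "detrend_exponential",
    "highpass",
    "decrosstalk",
    "bin_movie",
    "svd_denoise",
    "gaussian_blur_denoiser",
]


@dataclass
class TrendFit:
    """Fitted slow baseline F0(t) used for dF/F normalization."""

    model: str  # "lowpass_baseline" or "exponential_sum"
    baseline_trace: np.ndarray
    components: list[tuple[float, float]] | None = None  # (amplitude, tau_s)
    offset: float = 0.0
    half_life_s: float | None = None


def notch(x, rate_hz: float, center_hz: float, half_width_hz: float = 1.0,
          order: int = 8):
    """Zero-phase Butterworth band-stop of total order ``order`` centered
    on ``center_hz`` with stop edges at center +/- half_width."""
    nyq = rate_hz / 2
    if center_hz + half_width_hz >= nyq:
        raise ValueError(
            f"notch band {center_hz}+/-{half_width_hz} Hz at/above Nyquist"
        )
    sos = signal.butter(order // 2,
                        [center_hz - half_width_hz, center_hz + half_width_hz],
                        btype="bandstop", fs=rate_hz, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float))


def detrend_lowpass(x, rate_hz: float, cutoff_hz: float = 0.5,
                    order: int = 4) -> tuple[np.ndarray, TrendFit]:
    """Normalize by the slow baseline F0 from a zero-phase low-pass
    (Butterworth, 4th order, 0.5 Hz by default).  Returns F/F0."""
    x = np.asarray(x, dtype=float)
    if len(x) < 3 * rate_hz / cutoff_hz:
        raise ValueError(
            f"recording shorter than 3/cutoff = {3 / cutoff_hz:.1f} s"
        )
    sos = signal.butter(order, cutoff_hz, btype="lowpass", fs=rate_hz,
                        output="sos")
    f0 = signal.sosfiltfilt(sos, x)
    if np.any(f0 <= 0):
        raise ValueError("baseline F0 non-positive; raw data invalid for dF/F")
    return x / f0, TrendFit(model="lowpass_baseline", baseline_trace=f0)


def _exp_sum(t, params, n_components):
    out = np.full_like(t, params[-1])
    for i in range(n_components):
        a, log_tau = params[2 * i], params[2 * i + 1]
        out += a * np.exp(-t / np.exp(log_tau))
    return out


def _half_life(components, offset, t_max):
    """First t with F0(t) = F0(0)/2 by bisection (1e-6 relative)."""
    def f0(t):
        return offset + sum(a * np.exp(-t / tau) for a, tau in components)

    target = f0(0.0) / 2
    if f0(t_max) > target:  # does not decay to half within 100x slowest tau
        t_max = 100 * max(tau for _, tau in components)
        if f0(t_max) > target:
            return None
    lo, hi = 0.0, t_max
    while (hi - lo) > 1e-6 * max(hi, 1.0):
        mid = (lo + hi) / 2
        if f0(mid) > target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def detrend_exponential(x, rate_hz: float, n_components: int = 2
                        ) -> tuple[np.ndarray, TrendFit]:
    """Fit F0(t) = sum_i a_i exp(-t/tau_i) + offset by multi-start
    nonlinear least squares and return (F/F0, TrendFit).

    Amplitudes and the offset are constrained non-negative; time constants
    are fit in log space from log-spaced starting values.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("trace must be positive for photobleaching fits")
    if n_components not in (1, 2, 3):
        raise ValueError("n_components must be 1, 2 or 3")
    t = np.arange(len(x)) / rate_hz
    duration = t[-1]
    scale = x.mean()

    tau_starts = np.geomspace(duration / 50, duration * 10, 6)
    best = None
    for start_idx in range(len(tau_starts) - n_components + 1):
        taus0 = tau_starts[start_idx:start_idx + n_components]
        p0 = []
        for tau in taus0:
            p0 += [scale / n_components, np.log(tau)]
        p0.append(0.0)
        lb = ([0.0, np.log(duration / 1e4)] * n_components) + [0.0]
        ub = ([np.inf, np.log(duration * 1e4)] * n_components) + [np.inf]
        try:
            res = optimize.least_squares(
                lambda p: _exp_sum(t, p, n_components) - x, p0,
                bounds=(lb, ub), max_nfev=2000)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("exponential trend fit failed to converge")

    components = sorted(
        ((best.x[2 * i], float(np.exp(best.x[2 * i + 1])))
         for i in range(n_components)),
        key=lambda at: at[1])
    offset = float(best.x[-1])
    f0 = _exp_sum(t, best.x, n_components)
    if np.any(f0 <= 0):
        raise RuntimeError("fitted baseline non-positive")
    fit = TrendFit(model="exponential_sum", baseline_trace=f0,
                   components=[(float(a), float(tau)) for a, tau in components],
                   offset=offset,
                   half_life_s=_half_life(components, offset, duration * 1e3))
    return x / f0, fit


def _highpass_kernel(rate_hz: float, cutoff_hz: float) -> np.ndarray:
    """Symmetric FIR high-pass (spectral inversion of a unit-DC-gain
    low-pass), so DC is removed exactly."""
    nyq = rate_hz / 2
    if cutoff_hz >= nyq:
        raise ValueError(f"cutoff {cutoff_hz} Hz at/above Nyquist {nyq} Hz")
    width = cutoff_hz / 2  # transition width
    numtaps, beta = signal.kaiserord(80.0, width / nyq)
    numtaps |= 1  # odd length, type-I symmetric
    h_lp = signal.firwin(numtaps, cutoff_hz, window=("kaiser", beta),
                         fs=rate_hz)
    h_lp /= h_lp.sum()
    h_hp = -h_lp
    h_hp[numtaps // 2] += 1.0
    return h_hp


def highpass(x, rate_hz: float, cutoff_hz: float):
    """Zero-phase symmetric-FIR high-pass along the time axis.

    Works on 1-D traces and T x Y x X movies (axis 0 = time).  Edges are
    reflection padded.
    """
    x = np.asarray(x, dtype=float)
    h = _highpass_kernel(rate_hz, cutoff_hz)
    pad = len(h) // 2
    if x.shape[0] <= pad:
        raise ValueError(
            f"input too short ({x.shape[0]} samples) for a "
            f"{len(h)}-tap kernel at cutoff {cutoff_hz} Hz"
        )
    xp = np.concatenate([x[pad:0:-1], x, x[-2:-pad - 2:-1]], axis=0)
    if x.ndim == 1:
        out = signal.fftconvolve(xp, h, mode="valid")
    else:
        shape = [len(h)] + [1] * (x.ndim - 1)
        out = signal.fftconvolve(xp, h.reshape(shape), mode="valid", axes=0)
    return out


def decrosstalk(contaminated, contaminant, rate_hz: float,
                band_hz: tuple[float, float] = (3.0, 7.0),
                order: int = 3) -> tuple[np.ndarray, float]:
    """Remove bleedthrough by band-limited regression.

    Both traces are band-passed (3rd-order Butterworth, zero-phase); beta
    is the least-squares slope of the band-passed contaminated trace on
    the band-passed contaminant; the unfiltered contaminant scaled by
    beta is subtracted from the unfiltered contaminated trace.
    """
    contaminated = np.asarray(contaminated, dtype=float)
    contaminant = np.asarray(contaminant, dtype=float)
    if contaminated.shape != contaminant.shape:
        raise ValueError("inputs must share length")
    sos = signal.butter(order, band_hz, btype="bandpass", fs=rate_hz,
                        output="sos")
    bf_ed = signal.sosfiltfilt(sos, contaminated)
    bf_ant = signal.sosfiltfilt(sos, contaminant)
    denom = np.dot(bf_ant, bf_ant)
    if denom <= 1e-12 * len(bf_ant) * max(contaminant.var(), 1e-300):
        raise ValueError("contaminant has ~zero in-band power; "
                         "regression ill-posed")
    beta = float(np.dot(bf_ed, bf_ant) / denom)
    return contaminated - beta * contaminant, beta


def bin_movie(movie, factor: int = 8):
    """Box-average spatial binning by ``factor``; trailing partial blocks
    are dropped and pixel pitch scales by ``factor``.

    Accepts a TwoChannelMovie (returns one) or a bare T x Y x X array.
    """
    from .types import TwoChannelMovie

    if factor < 1:
        raise ValueError("factor must be >= 1")

    def _bin(arr):
        nt, ny, nx = arr.shape
        by, bx = ny // factor, nx // factor
        if by == 0 or bx == 0:
            raise ValueError(
                f"factor {factor} exceeds frame dimensions {ny}x{nx}"
            )
        arr = arr[:, : by * factor, : bx * factor]
        return arr.reshape(nt, by, factor, bx, factor).mean(axis=(2, 4))

    if isinstance(movie, TwoChannelMovie):
        return TwoChannelMovie(
            gevi=_bin(movie.gevi), reference=_bin(movie.reference),
            rate_hz=movie.rate_hz,
            pixel_pitch_mm=movie.pixel_pitch_mm * factor,
            meta=dict(movie.meta))
    return _bin(np.asarray(movie, dtype=float))


def gaussian_blur_denoiser(sigma_px: float = 1.0):
    """Default deterministic 2-D coefficient-image denoiser (Gaussian
    blur).  Any callable mapping an image to a same-shape image works."""
    def denoise(img: np.ndarray) -> np.ndarray:
        return ndimage.gaussian_filter(img, sigma_px)
    return denoise


def identity_denoiser(img: np.ndarray) -> np.ndarray:
    return img


def svd_denoise(channel: np.ndarray, k: int = 5, segment_len: int = 2500,
                image_denoiser=None) -> np.ndarray:
    """Segmented low-rank movie denoising.

    Per temporal segment: reshape to frames x pixels M, take the top-k
    left singular vectors U, form coefficients C = U.T @ M, denoise each
    coefficient row as a 2-D image with ``image_denoiser``, and rebuild
    the segment as U @ C_hat.  Segments are re-concatenated preserving
    length.  With the identity denoiser this is an orthogonal projection
    onto the top-k temporal subspace.
    """
    channel = np.asarray(channel, dtype=float)
    if channel.ndim != 3:
        raise ValueError("channel must be T x Y x X")
    if image_denoiser is None:
        image_denoiser = identity_denoiser
    nt, ny, nx = channel.shape
    out = np.empty_like(channel)
    starts = list(range(0, nt, segment_len))
    # fold a tiny trailing remainder into the previous segment
    if len(starts) > 1 and nt - starts[-1] < k:
        starts.pop()
    for i, s0 in enumerate(starts):
        s1 = starts[i + 1] if i + 1 < len(starts) else nt
        seg = channel[s0:s1].reshape(s1 - s0, ny * nx)
        if seg.shape[0] < k:
            raise ValueError(
                f"segment of {seg.shape[0]} frames shorter than k={k}"
            )
        u, _, _ = np.linalg.svd(seg, full_matrices=False)
        u = u[:, :k]
        coeff = u.T @ seg
        denoised = np.stack([
            np.asarray(image_denoiser(c.reshape(ny, nx))).ravel()
            for c in coeff
        ])
        out[s0:s1] = (u @ denoised).reshape(s1 - s0, ny, nx)
    return out
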