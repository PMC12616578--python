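"""Detection of discrete electrophysiological events.

Sharp-wave ripples are detected on the normalized squared signal (NSS):
the ripple-band (120-200 Hz, 3rd-order Butterworth, zero-phase) LFP is
squared, passed through a centered 20 ms moving maximum, smoothed with a
20 ms moving average, and min-max rescaled to [0, 1]; local maxima are
then gated by prominence (10% of the rescaled range), distance (10 ms),
and half-prominence width (10-200 ms).  Ictal spikes are found on the
25 Hz high-passed LFP by width/prominence gating in physical units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .types import ElectricalTrace, EventTable

__all__ = ["RippleEvent", "detect_ripples", "detect_ictal_spikes"]


@dataclass
class RippleEvent:
    """One detected ripple: NSS peak time, height, width and the
    extraction window bounds."""

    center_s: float
    nss_peak: float
    width_s: float
    window_s: tuple[float, float]


def compute_nss(lfp: ElectricalTrace,
                band_hz: tuple[float, float] = (120.0, 200.0),
                movmax_s: float = 0.020,
                smooth_s: float = 0.020,
                order: int = 3) -> np.ndarray:
    """Normalized squared signal in [0, 1]."""
    rate = lfp.rate_hz
    if rate < 2 * band_hz[1]:
        raise ValueError(
            f"sampling rate {rate} Hz too low for band {band_hz}"
        )
    sos = signal.butter(order, band_hz, btype="bandpass", fs=rate,
                        output="sos")
    bf = signal.sosfiltfilt(sos, lfp.samples)
    sq = bf ** 2
    w_max = max(int(round(movmax_s * rate)), 1)
    mm = ndimage.maximum_filter1d(sq, size=w_max, mode="nearest")
    w_sm = max(int(round(smooth_s * rate)), 1)
    sm = ndimage.uniform_filter1d(mm, size=w_sm, mode="nearest")
    lo, hi = sm.min(), sm.max()
    if hi <= lo:
        return np.zeros_like(sm)
    return (sm - lo) / (hi - lo)


def detect_ripples(lfp: ElectricalTrace,
                   band_hz: tuple[float, float] = (120.0, 200.0),
                   movmax_s: float = 0.020,
                   smooth_s: float = 0.020,
                   min_prom: float = 0.10,
                   min_dist_s: float = 0.010,
                   min_width_s: float = 0.010,
                   max_width_s: float = 0.200,
                   window_s: float = 0.300
                   ) -> tuple[EventTable, np.ndarray]:
    """Detect sharp-wave ripples on the NSS.

    Returns an EventTable (times plus nss_peak / width_s / window bounds
    extras) and the NSS itself.  Detections are invariant to any affine
    gain on the input because the NSS is min-max rescaled.
    """
    if lfp.duration_s < max(window_s, 1.0):
        raise ValueError("recording shorter than the extraction window")
    rate = lfp.rate_hz
    nss = compute_nss(lfp, band_hz=band_hz, movmax_s=movmax_s,
                      smooth_s=smooth_s)
    peaks, props = signal.find_peaks(
        nss,
        prominence=min_prom,
        distance=max(int(round(min_dist_s * rate)), 1),
        width=(min_width_s * rate, max_width_s * rate),
        rel_height=0.5,
    )
    times = peaks / rate
    widths = props["widths"] / rate
    starts = np.clip(times - window_s / 2, 0, lfp.duration_s)
    ends = np.clip(times + window_s / 2, 0, lfp.duration_s)
    table = EventTable(
        times_s=times,
        extras={
            "nss_peak": nss[peaks],
            "width_s": widths,
            "window_start_s": starts,
            "window_end_s": ends,
        },
    )
    return table, nss


def ripple_events(table: EventTable) -> list[RippleEvent]:
    """Expand a detection table into RippleEvent records."""
    return [
        RippleEvent(center_s=float(t),
                    nss_peak=float(table.extras["nss_peak"][i]),
                    width_s=float(table.extras["width_s"][i]),
                    window_s=(float(table.extras["window_start_s"][i]),
                              float(table.extras["window_end_s"][i])))
        for i, t in enumerate(table.times_s)
    ]


def detect_ictal_spikes(lfp: ElectricalTrace,
                        highpass_hz: float = 25.0,
                        min_width_s: float = 0.002,
                        max_width_s: float = 0.020,
                        min_prom_uv: float = 1000.0,
                        order: int = 6) -> EventTable:
    """Detect interictal/ictal spikes on the high-passed LFP.

    Samples must be in microvolts.  Peaks are gated by width at half
    prominence (2-20 ms) and absolute prominence (1000 uV).
    """
    rate = lfp.rate_hz
    if rate < 1000.0:
        raise ValueError("need >= 1 kHz sampling to resolve 2 ms spikes")
    sos = signal.butter(order, highpass_hz, btype="highpass", fs=rate,
                        output="sos")
    hf = signal.sosfiltfilt(sos, lfp.samples)
    peaks, props = signal.find_peaks(
        hf,
        prominence=min_prom_uv,
        width=(min_width_s * rate, max_width_s * rate),
        rel_height=0.5,
    )
    return EventTable(times_s=peaks / rate,
                      extras={"peak_uv": hf[peaks],
                              "width_s": props["widths"] / rate})
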