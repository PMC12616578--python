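"""Spatiotemporal characterization of traveling voltage waves.

Two velocity estimators are provided.  The seed-pixel route builds a
cross-correlation delay map against a seed pixel and fits a plane
tau(x, y) = A x + B y + C; a wave propagates toward increasing arrival
delay, so speed = 1 / |grad tau| and direction = atan2(B, A).  The
wavenumber route projects the movie onto the x and y axes, regresses
each position's peak time on position (robust M-estimation), and converts
the slope pair (wavenumbers, s/mm) to a polar velocity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import signal, stats
from scipy.fft import irfft, next_fast_len, rfft

__all__ = [
    "DelayMap",
    "WaveEvent",
    "seed_delay_map",
    "fit_plane_velocity",
    "pairwise_velocities",
    "detect_wave_events",
    "spacetime_project",
    "fit_wavenumbers",
    "flow_map",
]


@dataclass
class DelayMap:
    """Peak correlation and sub-sample delay of every pixel vs a seed."""

    corr: np.ndarray           # Y x X peak correlation
    delay_s: np.ndarray        # Y x X delay (positive = pixel lags seed)
    seed_yx: tuple[int, int]
    pixel_pitch_mm: float
    xmin: float | None = None
    valid_mask: np.ndarray | None = None


@dataclass
class WaveEvent:
    """A characterized traveling-wave episode."""

    t_window_s: tuple[float, float]
    alpha_x: float             # s/mm
    alpha_y: float
    alpha_x_se: float
    alpha_y_se: float
    p_x: float
    p_y: float
    speed_mm_s: float
    direction_deg: float
    method: str
    accepted: bool
    reject_reason: str | None = None
    velocity_mm_s: tuple[float, float] | None = None


def seed_delay_map(voltage: np.ndarray, rate_hz: float,
                   pixel_pitch_mm: float, seed_yx: tuple[int, int],
                   max_lag_s: float,
                   band_hz: tuple[float, float] | None = None,
                   xmin: float | None = None) -> DelayMap:
    """Cross-correlate every pixel against the seed pixel.

    corr is the correlation maximum within +/- max_lag_s; delay is the
    sub-sample (parabolic) lag of that maximum, positive when the pixel
    lags the seed.
    """
    v = np.asarray(voltage, dtype=float)
    nt, ny, nx = v.shape
    if nt < 4 * max_lag_s * rate_hz:
        raise ValueError("movie too short for the requested max lag")
    if band_hz is not None:
        sos = signal.butter(4, band_hz, btype="bandpass", fs=rate_hz,
                            output="sos")
        v = signal.sosfiltfilt(sos, v, axis=0)
    flat = v.reshape(nt, -1)
    flat = flat - flat.mean(axis=0)
    seed_idx = seed_yx[0] * nx + seed_yx[1]
    seed = flat[:, seed_idx]
    seed_energy = np.dot(seed, seed)
    if seed_energy <= 0:
        raise ValueError("zero-variance seed pixel")
    max_lag = int(round(max_lag_s * rate_hz))
    nfft = next_fast_len(2 * nt - 1)
    sf = rfft(seed, nfft)
    pf = rfft(flat, nfft, axis=0)
    # cc[l] = sum_t seed(t) * pix(t + l); a pixel lagging the seed by d
    # samples peaks at l = d
    cc_full = irfft(np.conj(sf)[:, None] * pf, nfft, axis=0)
    lags = np.arange(-max_lag, max_lag + 1)
    cc = np.concatenate([cc_full[nfft - max_lag:], cc_full[:max_lag + 1]],
                        axis=0)
    energies = np.einsum("ij,ij->j", flat, flat)
    with np.errstate(invalid="ignore", divide="ignore"):
        cc_norm = cc / np.sqrt(seed_energy * energies)[None, :]
    cc_norm = np.nan_to_num(cc_norm, nan=0.0)
    i_pk = np.argmax(cc_norm, axis=0)
    cols = np.arange(flat.shape[1])
    corr = cc_norm[i_pk, cols]
    # parabolic sub-sample refinement where the peak is interior
    delta = np.zeros_like(corr)
    interior = (i_pk > 0) & (i_pk < len(lags) - 1)
    y0 = cc_norm[np.clip(i_pk - 1, 0, None), cols]
    y1 = corr
    y2 = cc_norm[np.clip(i_pk + 1, None, len(lags) - 1), cols]
    denom = y0 - 2 * y1 + y2
    ok = interior & (denom != 0)
    delta[ok] = np.clip(0.5 * (y0[ok] - y2[ok]) / denom[ok], -0.5, 0.5)
    delay = (lags[i_pk] + delta) / rate_hz  # positive = pixel lags the seed
    corr_map = corr.reshape(ny, nx)
    delay_map = delay.reshape(ny, nx)
    delay_map[seed_yx] = 0.0
    valid = corr_map > xmin if xmin is not None else None
    return DelayMap(corr=corr_map, delay_s=delay_map, seed_yx=seed_yx,
                    pixel_pitch_mm=pixel_pitch_mm, xmin=xmin,
                    valid_mask=valid)


def _polar(alpha_x: float, alpha_y: float) -> tuple[float, float]:
    norm2 = alpha_x ** 2 + alpha_y ** 2
    speed = 1.0 / np.sqrt(norm2)
    direction = float(np.degrees(np.arctan2(alpha_y, alpha_x)) % 360.0)
    return float(speed), direction


def fit_plane_velocity(dmap: DelayMap, xmin: float = 0.7,
                       spatial_bin: int | None = None,
                       t_window_s: tuple[float, float] = (0.0, 0.0),
                       literal_formula: bool = False,
                       min_grad_s_per_mm: float = 1e-4) -> WaveEvent:
    """Least-squares plane fit tau(x, y) = A x + B y + C over pixels with
    corr > xmin; velocity from the delay gradient.

    Default: speed = 1/sqrt(A^2 + B^2), direction = atan2(B, A) (toward
    increasing delay), velocity vector (A, B)/(A^2 + B^2).  With
    ``literal_formula`` the component-inverse pair (1/A, 1/B) is reported
    as the velocity vector instead.
    """
    corr = dmap.corr
    delay = dmap.delay_s
    if spatial_bin and spatial_bin > 1:
        b = spatial_bin
        ny, nx = corr.shape
        ny2, nx2 = ny // b, nx // b
        corr = corr[:ny2 * b, :nx2 * b].reshape(ny2, b, nx2, b).mean((1, 3))
        delay = delay[:ny2 * b, :nx2 * b].reshape(ny2, b, nx2, b).mean((1, 3))
        pitch = dmap.pixel_pitch_mm * b
    else:
        pitch = dmap.pixel_pitch_mm
    mask = corr > xmin
    if mask.sum() < 10:
        raise ValueError(f"only {int(mask.sum())} pixels above xmin={xmin}")
    yy, xx = np.nonzero(mask)
    x_mm = xx * pitch
    y_mm = yy * pitch
    design = np.column_stack([x_mm, y_mm, np.ones_like(x_mm)])
    tau = delay[mask]
    coef, res_ss, _, _ = np.linalg.lstsq(design, tau, rcond=None)
    a, b_, _c = coef
    dof = max(len(tau) - 3, 1)
    sigma2 = (res_ss[0] / dof) if len(res_ss) else 0.0
    cov = sigma2 * np.linalg.inv(design.T @ design)
    se_a, se_b = np.sqrt(np.diag(cov)[:2])

    grad = float(np.hypot(a, b_))
    if grad < min_grad_s_per_mm:
        return WaveEvent(t_window_s=t_window_s, alpha_x=float(a),
                         alpha_y=float(b_), alpha_x_se=float(se_a),
                         alpha_y_se=float(se_b), p_x=1.0, p_y=1.0,
                         speed_mm_s=np.inf, direction_deg=0.0,
                         method="plane_fit", accepted=False,
                         reject_reason="synchronous")
    speed, direction = _polar(a, b_)
    if literal_formula:
        vel = (1.0 / a if a != 0 else np.inf,
               1.0 / b_ if b_ != 0 else np.inf)
    else:
        vel = (a / grad ** 2, b_ / grad ** 2)
    def _p(coefv, se):
        if se <= 0:
            return 0.0 if abs(coefv) > 0 else 1.0
        return float(2 * stats.t.sf(abs(coefv / se), dof))
    return WaveEvent(t_window_s=t_window_s, alpha_x=float(a),
                     alpha_y=float(b_), alpha_x_se=float(se_a),
                     alpha_y_se=float(se_b), p_x=_p(a, se_a),
                     p_y=_p(b_, se_b), speed_mm_s=speed,
                     direction_deg=direction, method="plane_fit",
                     accepted=True, velocity_mm_s=vel)


def pairwise_velocities(dmap: DelayMap, xmin: float = 0.7,
                        point_set=None, rate_hz: float | None = None,
                        min_delay_s: float = 0.0):
    """Speed and direction samples from admissible pixel pairs.

    For each pair with both correlations above xmin and |delay
    difference| above one sample (``min_delay_s``), speed = separation /
    |delay difference| and direction points from the earlier toward the
    later pixel.  Returns (speeds_mm_s, directions_deg).
    """
    if point_set is None:
        yy, xx = np.nonzero(dmap.corr > xmin)
        point_set = list(zip(yy.tolist(), xx.tolist()))
    if len(point_set) < 2:
        raise ValueError("need >= 2 points")
    pts = np.asarray(point_set)
    # only pixels whose waveform resembles the seed's are admissible
    keep = dmap.corr[pts[:, 0], pts[:, 1]] > xmin
    pts = pts[keep]
    if len(pts) < 2:
        return np.empty(0), np.empty(0)
    delays = dmap.delay_s[pts[:, 0], pts[:, 1]]
    speeds, dirs = [], []
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            dtau = delays[j] - delays[i]
            if abs(dtau) <= min_delay_s:
                continue
            dy = (pts[j, 0] - pts[i, 0]) * dmap.pixel_pitch_mm
            dx = (pts[j, 1] - pts[i, 1]) * dmap.pixel_pitch_mm
            dist = float(np.hypot(dx, dy))
            if dist == 0:
                continue
            speeds.append(dist / abs(dtau))
            sign = 1.0 if dtau > 0 else -1.0
            dirs.append(float(np.degrees(np.arctan2(sign * dy, sign * dx))
                              % 360.0))
    return np.asarray(speeds), np.asarray(dirs)


def detect_wave_events(voltage: np.ndarray, rate_hz: float,
                       threshold_sd: float = 3.0,
                       merge_gap_s: float = 0.050,
                       pad_s: float = 0.0) -> list[tuple[float, float]]:
    """Intervals where the field-averaged signal deviates from its mean
    by more than threshold_sd standard deviations."""
    net = np.asarray(voltage, dtype=float).reshape(voltage.shape[0], -1) \
        .mean(axis=1)
    dev = np.abs(net - net.mean())
    thr = threshold_sd * net.std()
    above = dev > thr
    if not above.any():
        return []
    idx = np.flatnonzero(above)
    splits = np.flatnonzero(np.diff(idx) > 1)
    runs = np.split(idx, splits + 1)
    windows = [(r[0] / rate_hz, (r[-1] + 1) / rate_hz) for r in runs]
    # merge windows separated by less than merge_gap_s
    merged = [list(windows[0])]
    for w0, w1 in windows[1:]:
        if w0 - merged[-1][1] < merge_gap_s:
            merged[-1][1] = w1
        else:
            merged.append([w0, w1])
    dur = voltage.shape[0] / rate_hz
    return [(max(0.0, w0 - pad_s), min(dur, w1 + pad_s))
            for w0, w1 in merged]


def spacetime_project(voltage: np.ndarray, axis: str,
                      pixel_pitch_mm: float
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Project a movie onto one spatial axis (mean over the other).

    Returns (projection time x position, positions_mm).  axis="x" keeps
    columns (mean over rows); axis="y" keeps rows.
    """
    v = np.asarray(voltage, dtype=float)
    if axis == "x":
        proj = v.mean(axis=1)
    elif axis == "y":
        proj = v.mean(axis=2)
    else:
        raise ValueError("axis must be 'x' or 'y'")
    return proj, np.arange(proj.shape[1]) * pixel_pitch_mm


def _peak_times(proj: np.ndarray, rate_hz: float,
                i0: int, i1: int) -> np.ndarray:
    """Sub-sample peak time per position within a frame window."""
    win = proj[i0:i1]
    i_pk = np.argmax(win, axis=0)
    cols = np.arange(win.shape[1])
    delta = np.zeros(win.shape[1])
    interior = (i_pk > 0) & (i_pk < win.shape[0] - 1)
    y0 = win[np.clip(i_pk - 1, 0, None), cols]
    y1 = win[i_pk, cols]
    y2 = win[np.clip(i_pk + 1, None, win.shape[0] - 1), cols]
    denom = y0 - 2 * y1 + y2
    ok = interior & (denom != 0)
    delta[ok] = np.clip(0.5 * (y0[ok] - y2[ok]) / denom[ok], -0.5, 0.5)
    return (i0 + i_pk + delta) / rate_hz


def _robust_slope(pos_mm: np.ndarray, t_peak: np.ndarray
                  ) -> tuple[float, float, float]:
    """Huber M-estimate of peak time on position: (slope, se, p)."""
    if np.ptp(t_peak) == 0:
        return 0.0, 0.0, 1.0
    design = sm.add_constant(pos_mm)
    try:
        fit = sm.RLM(t_peak, design, M=sm.robust.norms.HuberT()).fit()
        slope, se = float(fit.params[1]), float(fit.bse[1])
    except Exception:
        coef = np.polyfit(pos_mm, t_peak, 1)
        slope = float(coef[0])
        resid = t_peak - np.polyval(coef, pos_mm)
        denom = np.sum((pos_mm - pos_mm.mean()) ** 2)
        se = float(np.sqrt(resid.var(ddof=2) / denom)) if denom > 0 else 0.0
    if se <= 0:
        p = 0.0 if slope != 0 else 1.0
    else:
        p = float(2 * stats.norm.sf(abs(slope / se)))
    return slope, se, p


def fit_wavenumbers(projected_x: np.ndarray, projected_y: np.ndarray,
                    rate_hz: float, pixel_pitch_mm: float,
                    t_window_s: tuple[float, float],
                    p_thresh: float = 0.01,
                    any_axis: bool = False,
                    band_hz: tuple[float, float] | None = None) -> WaveEvent:
    """Wavenumber-regression velocity estimate within a wave window.

    Per axis, each position's (sub-sample) peak time is regressed on
    position with a Huber M-estimator; the slope is the Cartesian
    wavenumber alpha (s/mm).  Literal acceptance requires both p-values
    < p_thresh; ``any_axis`` accepts a single significant axis and
    treats the other wavenumber as 0.  When ``band_hz`` is given the
    projections are zero-phase band-passed before peak extraction.
    """
    if band_hz is not None:
        sos = signal.butter(4, band_hz, btype="bandpass", fs=rate_hz,
                            output="sos")
        projected_x = signal.sosfiltfilt(sos, projected_x, axis=0)
        projected_y = signal.sosfiltfilt(sos, projected_y, axis=0)
    i0 = int(round(t_window_s[0] * rate_hz))
    i1 = int(round(t_window_s[1] * rate_hz))
    if i1 <= i0 or i1 > projected_x.shape[0]:
        raise ValueError("window outside the recording")
    if projected_x.shape[1] < 5 or projected_y.shape[1] < 5:
        raise ValueError("need >= 5 positions per axis")
    tx = _peak_times(projected_x, rate_hz, i0, i1)
    ty = _peak_times(projected_y, rate_hz, i0, i1)
    if np.ptp(tx) == 0 and np.ptp(ty) == 0:
        return WaveEvent(t_window_s=t_window_s, alpha_x=0.0, alpha_y=0.0,
                         alpha_x_se=0.0, alpha_y_se=0.0, p_x=1.0, p_y=1.0,
                         speed_mm_s=np.inf, direction_deg=0.0,
                         method="wavenumber_regression", accepted=False,
                         reject_reason="synchronous")
    pos_x = np.arange(projected_x.shape[1]) * pixel_pitch_mm
    pos_y = np.arange(projected_y.shape[1]) * pixel_pitch_mm
    ax, se_x, p_x = _robust_slope(pos_x, tx)
    ay, se_y, p_y = _robust_slope(pos_y, ty)

    sig_x, sig_y = p_x < p_thresh, p_y < p_thresh
    if any_axis:
        accepted = sig_x or sig_y
        if accepted and not sig_x:
            ax = 0.0
        if accepted and not sig_y:
            ay = 0.0
    else:
        accepted = sig_x and sig_y
    reason = None
    if not accepted:
        reason = ("wavenumber not significant on both axes"
                  if not any_axis else "no significant axis")
    if accepted and (ax != 0 or ay != 0):
        speed, direction = _polar(ax, ay)
        norm2 = ax ** 2 + ay ** 2
        vel = (ax / norm2, ay / norm2)
    else:
        speed, direction, vel = np.inf, 0.0, None
        accepted = False
        reason = reason or "synchronous"
    return WaveEvent(t_window_s=t_window_s, alpha_x=float(ax),
                     alpha_y=float(ay), alpha_x_se=float(se_x),
                     alpha_y_se=float(se_y), p_x=float(p_x), p_y=float(p_y),
                     speed_mm_s=speed, direction_deg=direction,
                     method="wavenumber_regression", accepted=accepted,
                     reject_reason=reason, velocity_mm_s=vel)


def flow_map(dmap_or_field, grid_spacing: int = 1) -> np.ndarray:
    """Unit-vector direction field of the local velocity.

    For a DelayMap, local velocity direction is the local delay gradient
    direction (toward increasing delay).  Returns an array (ny, nx, 2) of
    (ux, uy) unit vectors, NaN where invalid.
    """
    if isinstance(dmap_or_field, DelayMap):
        delay = dmap_or_field.delay_s
        mask = dmap_or_field.valid_mask
        gy, gx = np.gradient(delay, dmap_or_field.pixel_pitch_mm)
    else:
        field = np.asarray(dmap_or_field, dtype=float)
        if field.ndim == 3 and field.shape[2] == 2:
            gx, gy = field[..., 0], field[..., 1]
            mask = None
        else:
            gy, gx = np.gradient(field)
            mask = None
    s = grid_spacing
    gx, gy = gx[::s, ::s], gy[::s, ::s]
    norm = np.hypot(gx, gy)
    out = np.full(gx.shape + (2,), np.nan)
    ok = norm > 0
    if mask is not None:
        ok &= mask[::s, ::s]
    out[ok, 0] = gx[ok] / norm[ok]
    out[ok, 1] = gy[ok] / norm[ok]
    return out
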