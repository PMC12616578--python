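"""Physiological delay estimation corrected for indicator kinetics.

Voltage indicators low-pass filter membrane potential with indicator- and
cell-type-specific kinetics, so the apparent cross-correlation delay
between two simultaneously imaged cell types mixes the physiological
delay Delta with the difference of two indicator-induced lags.  A
7-experiment design (one dual-GEVI experiment plus six calibration
experiments) identifies Delta and the six indicator/cell-type lags via a
weighted least-squares fit with a norm penalty on the lag vector and a
non-negativity constraint on the lags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal

from .spectral import band_envelope, cross_correlation

__all__ = [
    "DelayDesign",
    "DelayFit",
    "canonical_design",
    "apparent_delay",
    "fit_delay_model",
    "physio_delay_distribution",
]

N_INDICATOR_SLOTS = 6  # 3 indicators x 2 cell types


@dataclass
class DelayDesign:
    """Linear design mapping (Delta, d1..d6) to each experiment's mean
    apparent delay:  pred_e = Delta * includes_e + d_A(e) - d_B(e).

    ``slot_a``/``slot_b`` give the indicator/cell-type slot index (0-5)
    used on each side of experiment e, or -1 for a kinetics-free timing
    reference (no lag term on that side).
    """

    slot_a: np.ndarray
    slot_b: np.ndarray
    includes_true_delay: np.ndarray
    samples_per_experiment: int = 100

    def __post_init__(self) -> None:
        self.slot_a = np.asarray(self.slot_a, dtype=int)
        self.slot_b = np.asarray(self.slot_b, dtype=int)
        self.includes_true_delay = np.asarray(self.includes_true_delay,
                                              dtype=bool)
        n = len(self.slot_a)
        if not (len(self.slot_b) == len(self.includes_true_delay) == n):
            raise ValueError("design columns must share length")
        if n != 7:
            raise ValueError(f"design must have exactly 7 rows, got {n}")
        used = set(self.slot_a[self.slot_a >= 0]) | \
            set(self.slot_b[self.slot_b >= 0])
        if used != set(range(N_INDICATOR_SLOTS)):
            raise ValueError(
                "all 6 indicator/cell-type slots must appear in the design"
            )
        m = self.matrix()
        rank = np.linalg.matrix_rank(m)
        if rank < N_INDICATOR_SLOTS:
            raise ValueError(f"design matrix rank {rank} < 6")
        # Delta must not lie in the span of the lag columns (trivial
        # null space for the physiological delay)
        if rank < np.linalg.matrix_rank(m[:, 1:]) + 1:
            raise ValueError(
                "physiological delay is not identifiable: the Delta column "
                "is spanned by the indicator-lag columns"
            )

    def matrix(self) -> np.ndarray:
        """7 x 7 design matrix; column 0 is Delta, columns 1-6 the lags."""
        n = len(self.slot_a)
        m = np.zeros((n, 1 + N_INDICATOR_SLOTS))
        m[:, 0] = self.includes_true_delay.astype(float)
        for e in range(n):
            if self.slot_a[e] >= 0:
                m[e, 1 + self.slot_a[e]] += 1.0
            if self.slot_b[e] >= 0:
                m[e, 1 + self.slot_b[e]] -= 1.0
        return m

    def predict(self, delta_s: float, d_s: np.ndarray) -> np.ndarray:
        return self.matrix() @ np.concatenate([[delta_s], d_s])

    def swapped(self) -> "DelayDesign":
        """Exchange the indicator assignments between the two cell types.

        Slot k of cell type A (k in 0..2) maps to slot k of cell type B
        (k+3) and vice versa; the roles of the two sides of each
        experiment flip accordingly, so the physiological delay keeps its
        sign while the lag difference negates.
        """
        remap = np.array([3, 4, 5, 0, 1, 2])
        new_a = np.empty_like(self.slot_a)
        new_b = np.empty_like(self.slot_b)
        for e in range(len(self.slot_a)):
            sa, sb = self.slot_a[e], self.slot_b[e]
            if sa >= 0 and sb >= 0:
                # the measured sides keep their cell-type roles; the
                # indicators trade places
                new_a[e], new_b[e] = remap[sb], remap[sa]
            else:
                new_a[e] = remap[sa] if sa >= 0 else -1
                new_b[e] = remap[sb] if sb >= 0 else -1
        return DelayDesign(slot_a=new_a, slot_b=new_b,
                           includes_true_delay=self.includes_true_delay,
                           samples_per_experiment=self.samples_per_experiment)


def canonical_design(samples_per_experiment: int = 100) -> DelayDesign:
    """The shipped 7-experiment design.

    Row 0 is the dual-GEVI experiment (indicator slot 0 on cell type A
    vs slot 4 on cell type B; includes the physiological delay).  Rows
    1-6 calibrate each of the six indicator/cell-type lags against a
    kinetics-free timing reference (slot -1), which makes every lag --
    and hence the physiological delay -- identifiable.
    """
    slot_a = np.array([0, 0, 1, 2, 3, 4, 5])
    slot_b = np.array([4, -1, -1, -1, -1, -1, -1])
    includes = np.array([True, False, False, False, False, False, False])
    return DelayDesign(slot_a=slot_a, slot_b=slot_b,
                       includes_true_delay=includes,
                       samples_per_experiment=samples_per_experiment)


@dataclass
class DelayFit:
    """Fitted physiological delay and indicator lags with resampling
    dispersion."""

    physio_delay_s: float
    physio_delay_sd_s: float
    indicator_delays_s: np.ndarray
    indicator_delays_sd_s: np.ndarray
    lambda_reg: float
    n_resamplings: int
    penalty: str = "l2_norm"
    per_resampling: np.ndarray | None = field(default=None, repr=False)


def apparent_delay(x, y, rate_hz: float,
                   band_hz: tuple[float, float] = (3.0, 7.0),
                   bout_threshold_sd: float = 1.0,
                   min_cycles: float = 2.0,
                   max_lag_s: float | None = None):
    """Per-bout apparent delay between two channels.

    Both channels are band-passed; bouts are intervals where the carrier
    amplitude envelope of x exceeds ``bout_threshold_sd`` standard
    deviations above its mean for at least ``min_cycles`` carrier
    periods.  Each bout's delay is the sub-sample cross-correlation peak
    lag (positive = x leads y).  Returns (delays_s, n_skipped).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    f_mid = 0.5 * (band_hz[0] + band_hz[1])
    if max_lag_s is None:
        max_lag_s = 0.5 / f_mid
    sos = signal.butter(4, band_hz, btype="bandpass", fs=rate_hz,
                        output="sos")
    xf = signal.sosfiltfilt(sos, x)
    yf = signal.sosfiltfilt(sos, y)
    _, amp = band_envelope(x, rate_hz, band_hz)
    thr = amp.mean() + bout_threshold_sd * amp.std()
    above = amp > thr
    idx = np.flatnonzero(above)
    if idx.size == 0:
        return np.empty(0), 0
    splits = np.flatnonzero(np.diff(idx) > 1)
    runs = np.split(idx, splits + 1)
    min_len = int(round(min_cycles / f_mid * rate_hz))
    delays, skipped = [], 0
    for r in runs:
        if len(r) < min_len:
            skipped += 1
            continue
        seg_x = xf[r[0]:r[-1] + 1]
        seg_y = yf[r[0]:r[-1] + 1]
        try:
            _, _, lag = cross_correlation(seg_x, seg_y, rate_hz, max_lag_s,
                                          per_lag_norm=True)
        except ValueError:
            skipped += 1
            continue
        delays.append(lag)  # positive: y lags x, i.e. x leads y
    return np.asarray(delays), skipped


def _objective(theta, obs, weights, m, lam, penalty):
    resid = obs - m @ theta
    d = theta[1:]
    if penalty == "l2_norm":
        pen = np.sqrt(np.dot(d, d) + 1e-18)
    elif penalty == "l1":
        pen = np.sum(np.abs(d))
    else:
        raise ValueError(f"unknown penalty {penalty!r}")
    return float(np.dot(weights * resid, resid) + lam * pen)


def fit_delay_model(means_s, sds_s, design: DelayDesign,
                    lambda_reg: float = 0.01,
                    n_resamplings: int = 100,
                    n_samples_per: int | None = None,
                    penalty: str = "l2_norm",
                    seed: int = 0) -> DelayFit:
    """Weighted, norm-penalized fit of the delay model.

    Per resampling, each experiment's observed delay is drawn from
    Normal(mean, sd / sqrt(n_samples_per)) and the loss

        sum_e (obs_e - pred_e)^2 / sd_e^2 + lambda * ||d||

    is minimized subject to d >= 0 (Delta unconstrained).  Means and
    dispersions over resamplings are reported.
    """
    means = np.asarray(means_s, dtype=float)
    sds = np.asarray(sds_s, dtype=float)
    if means.shape != sds.shape or len(means) != 7:
        raise ValueError("means and sds must be length-7")
    if np.any(sds <= 0):
        raise ValueError("sds must be positive")
    if n_samples_per is None:
        n_samples_per = design.samples_per_experiment
    rng = np.random.default_rng(seed)
    m = design.matrix()
    weights = 1.0 / sds ** 2
    sem = sds / np.sqrt(n_samples_per)
    bounds = [(None, None)] + [(0.0, None)] * N_INDICATOR_SLOTS

    draws = np.empty((n_resamplings, 1 + N_INDICATOR_SLOTS))
    for i in range(n_resamplings):
        obs = means + sem * rng.standard_normal(7)
        # warm starts: weighted LSQ solution clipped to the feasible set,
        # and zero lags
        theta_ls, *_ = np.linalg.lstsq(m * np.sqrt(weights)[:, None],
                                       obs * np.sqrt(weights), rcond=None)
        starts = [np.concatenate([[theta_ls[0]],
                                  np.clip(theta_ls[1:], 0, None)]),
                  np.concatenate([[obs[0]], np.zeros(N_INDICATOR_SLOTS)])]
        best = None
        for x0 in starts:
            res = optimize.minimize(
                _objective, x0, args=(obs, weights, m, lambda_reg, penalty),
                method="L-BFGS-B", bounds=bounds)
            if best is None or res.fun < best.fun:
                best = res
        draws[i] = best.x
    return DelayFit(
        physio_delay_s=float(draws[:, 0].mean()),
        physio_delay_sd_s=float(draws[:, 0].std(ddof=1))
        if n_resamplings > 1 else 0.0,
        indicator_delays_s=draws[:, 1:].mean(axis=0),
        indicator_delays_sd_s=draws[:, 1:].std(axis=0, ddof=1)
        if n_resamplings > 1 else np.zeros(N_INDICATOR_SLOTS),
        lambda_reg=lambda_reg, n_resamplings=n_resamplings,
        penalty=penalty, per_resampling=draws)


def physio_delay_distribution(recording_bout_delays_s,
                              calibration_means_s,
                              calibration_sds_s,
                              design: DelayDesign,
                              lambda_reg: float = 0.01,
                              n_resamplings: int = 100,
                              penalty: str = "l2_norm",
                              seed: int = 0) -> list[DelayFit]:
    """Fit the delay model once per recording.

    Each recording's bout delays replace experiment 1's summary; the six
    calibration summaries are shared.  Returns one DelayFit per
    recording.
    """
    recordings = list(recording_bout_delays_s)
    if not recordings:
        raise ValueError("need at least one recording")
    cal_means = np.asarray(calibration_means_s, dtype=float)
    cal_sds = np.asarray(calibration_sds_s, dtype=float)
    if len(cal_means) != 6 or len(cal_sds) != 6:
        raise ValueError("need 6 calibration summaries")
    fits = []
    for bouts in recordings:
        bouts = np.asarray(bouts, dtype=float)
        if bouts.size < 2:
            raise ValueError("each recording needs >= 2 bout delays")
        means = np.concatenate([[bouts.mean()], cal_means])
        sds = np.concatenate([[bouts.std(ddof=1)], cal_sds])
        fits.append(fit_delay_model(
            means, sds, design, lambda_reg=lambda_reg,
            n_resamplings=n_resamplings, n_samples_per=len(bouts),
            penalty=penalty, seed=seed))
    return fits
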