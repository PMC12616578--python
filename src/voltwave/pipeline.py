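"""End-to-end processing pipelines with provenance logging.

Canonical stage orders:
  traces: notch -> detrend -> decrosstalk -> unmix
  movies: bin -> decrosstalk -> detrend -> unmix -> svd_denoise -> waves
Registration / motion-correction slots exist as no-op hooks (external
tools go there); stages may be omitted but not reordered unless the
config opts out of template validation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import preprocess, unmix as unmix_mod, waves as waves_mod
from .types import TwoChannelMovie, TwoChannelTrace

__all__ = ["PipelineConfig", "run_trace_pipeline", "run_movie_pipeline"]

TRACE_TEMPLATE = ["notch", "detrend", "decrosstalk", "unmix"]
MOVIE_TEMPLATE = ["bin", "register", "motion_correct", "decrosstalk",
                  "detrend", "unmix", "svd_denoise", "waves"]
_NOOP_STAGES = {"register", "motion_correct"}


@dataclass
class PipelineConfig:
    """Ordered stage list with per-stage parameter dicts."""

    stages: list[tuple[str, dict]] = field(default_factory=list)
    seed: int = 0
    validate_order: bool = True
    sidecar_path: str | None = None

    @classmethod
    def from_dict(cls, cfg: dict) -> "PipelineConfig":
        stages = [(s["name"], {k: v for k, v in s.items() if k != "name"})
                  for s in cfg.get("stages", [])]
        return cls(stages=stages, seed=cfg.get("seed", 0),
                   validate_order=cfg.get("validate_order", True),
                   sidecar_path=cfg.get("sidecar_path"))

    def check_order(self, template: list[str]) -> None:
        names = [n for n, _ in self.stages]
        idx = []
        for n in names:
            if n not in template:
                raise ValueError(f"unknown stage {n!r}")
            idx.append(template.index(n))
        if idx != sorted(idx):
            raise ValueError(
                f"stage order {names} violates the template {template}"
            )


def _write_sidecar(path: str | None, record: dict) -> None:
    if path is None:
        return
    Path(path).write_text(json.dumps(record, indent=1, default=str))


def run_trace_pipeline(trace: TwoChannelTrace, config: PipelineConfig):
    """Apply the configured trace stages in order.

    Returns (UnmixResult or conditioned trace, provenance dict).
    """
    if config.validate_order:
        config.check_order(TRACE_TEMPLATE)
    provenance = {"kind": "trace", "seed": config.seed, "stages": []}
    current = trace
    result = None
    for name, params in config.stages:
        try:
            if name == "notch":
                current = current.with_channels(
                    gevi=preprocess.notch(current.gevi, current.rate_hz,
                                          **params),
                    reference=preprocess.notch(current.reference,
                                               current.rate_hz, **params))
            elif name == "detrend":
                mode = params.get("mode", "lowpass")
                if mode == "lowpass":
                    kw = {k: v for k, v in params.items() if k != "mode"}
                    g, _ = preprocess.detrend_lowpass(current.gevi,
                                                      current.rate_hz, **kw)
                    r, _ = preprocess.detrend_lowpass(current.reference,
                                                      current.rate_hz, **kw)
                else:
                    kw = {k: v for k, v in params.items() if k != "mode"}
                    g, _ = preprocess.detrend_exponential(
                        current.gevi, current.rate_hz, **kw)
                    r, _ = preprocess.detrend_exponential(
                        current.reference, current.rate_hz, **kw)
                current = current.with_channels(gevi=g, reference=r)
            elif name == "decrosstalk":
                corrected, beta = preprocess.decrosstalk(
                    current.gevi, current.reference, current.rate_hz,
                    **params)
                current = current.with_channels(gevi=corrected)
                params = {**params, "beta": beta}
            elif name == "unmix":
                result = unmix_mod.unmix_trace(current, **params)
            else:
                raise ValueError(f"unknown trace stage {name!r}")
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        provenance["stages"].append({"name": name, "params": params})
    _write_sidecar(config.sidecar_path, provenance)
    return (result if result is not None else current), provenance


def run_movie_pipeline(movie: TwoChannelMovie, config: PipelineConfig):
    """Apply the configured movie stages in order.

    Returns (voltage movie array, list of WaveEvent, provenance dict).
    """
    if config.validate_order:
        config.check_order(MOVIE_TEMPLATE)
    provenance = {"kind": "movie", "seed": config.seed, "stages": []}
    current = movie
    voltage = None
    events: list = []
    for name, params in config.stages:
        try:
            if name in _NOOP_STAGES:
                pass  # external registration/motion tools slot in here
            elif name == "bin":
                current = preprocess.bin_movie(current, **params)
            elif name == "decrosstalk":
                nt = current.n_frames
                g2 = current.gevi.reshape(nt, -1)
                gm = g2.mean(axis=1)
                rm = current.reference.reshape(nt, -1).mean(axis=1)
                _, beta = preprocess.decrosstalk(
                    rm, gm, current.rate_hz, **params)
                current = TwoChannelMovie(
                    gevi=current.gevi,
                    reference=current.reference - beta * current.gevi,
                    rate_hz=current.rate_hz,
                    pixel_pitch_mm=current.pixel_pitch_mm)
                params = {**params, "beta": beta}
            elif name == "detrend":
                cutoff = params.get("cutoff_hz", 1.5)
                current = TwoChannelMovie(
                    gevi=preprocess.highpass(current.gevi, current.rate_hz,
                                             cutoff),
                    reference=preprocess.highpass(current.reference,
                                                  current.rate_hz, cutoff),
                    rate_hz=current.rate_hz,
                    pixel_pitch_mm=current.pixel_pitch_mm)
            elif name == "unmix":
                res = unmix_mod.unmix_movie(current, **params)
                voltage = res.voltage
            elif name == "svd_denoise":
                src = voltage if voltage is not None else current.gevi
                voltage = preprocess.svd_denoise(src, **params)
            elif name == "waves":
                src = voltage if voltage is not None else current.gevi
                events = _wave_stage(src, current, params)
            else:
                raise ValueError(f"unknown movie stage {name!r}")
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        provenance["stages"].append({"name": name, "params": params})
    if voltage is None:
        voltage = current.gevi
    _write_sidecar(config.sidecar_path, provenance)
    return voltage, events, provenance


def _wave_stage(voltage: np.ndarray, movie: TwoChannelMovie, params: dict):
    threshold_sd = params.get("threshold_sd", 3.0)
    p_thresh = params.get("p_thresh", 0.01)
    windows = waves_mod.detect_wave_events(voltage, movie.rate_hz,
                                           threshold_sd=threshold_sd)
    px, _ = waves_mod.spacetime_project(voltage, "x", movie.pixel_pitch_mm)
    py, _ = waves_mod.spacetime_project(voltage, "y", movie.pixel_pitch_mm)
    events = []
    for w0, w1 in windows:
        events.append(waves_mod.fit_wavenumbers(
            px, py, movie.rate_hz, movie.pixel_pitch_mm, (w0, w1),
            p_thresh=p_thresh, any_axis=params.get("any_axis", False)))
    return events
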