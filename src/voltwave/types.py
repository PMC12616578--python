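"""Core domain containers for two-channel voltage-imaging data.

All times are in seconds and all frequencies in Hz.  Movies are time-major
``T x Y x X`` arrays; Y increases anterior-to-posterior, X left-to-right.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "TwoChannelTrace",
    "TwoChannelMovie",
    "ElectricalTrace",
    "EventTable",
]


def _as_float_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass
class TwoChannelTrace:
    """Paired GEVI / reference fluorescence time series.

    The GEVI channel carries voltage signal plus shared artifacts; the
    voltage-insensitive reference channel carries artifacts only.
    """

    gevi: np.ndarray
    reference: np.ndarray
    rate_hz: float
    t0_s: float = 0.0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gevi = _as_float_1d(self.gevi, "gevi")
        self.reference = _as_float_1d(self.reference, "reference")
        if len(self.gevi) != len(self.reference):
            raise ValueError(
                f"channel length mismatch: gevi {len(self.gevi)} vs "
                f"reference {len(self.reference)}"
            )
        if len(self.gevi) < 2:
            raise ValueError("trace must contain at least 2 samples")
        if not self.rate_hz > 0:
            raise ValueError(f"rate_hz must be positive, got {self.rate_hz}")
        for name, arr in (("gevi", self.gevi), ("reference", self.reference)):
            bad = np.flatnonzero(~np.isfinite(arr))
            if bad.size:
                raise ValueError(
                    f"non-finite sample in {name} at index {bad[0]}"
                )

    def __len__(self) -> int:
        return len(self.gevi)

    @property
    def duration_s(self) -> float:
        return len(self.gevi) / self.rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return self.t0_s + np.arange(len(self.gevi)) / self.rate_hz

    def with_channels(self, gevi=None, reference=None) -> "TwoChannelTrace":
        """Copy with one or both channels replaced."""
        return TwoChannelTrace(
            gevi=self.gevi if gevi is None else gevi,
            reference=self.reference if reference is None else reference,
            rate_hz=self.rate_hz,
            t0_s=self.t0_s,
            meta=dict(self.meta),
        )


@dataclass
class TwoChannelMovie:
    """Paired GEVI / reference fluorescence movies (T x Y x X)."""

    gevi: np.ndarray
    reference: np.ndarray
    rate_hz: float
    pixel_pitch_mm: float
    axes_note: str = "axis0=time, axis1=Y (anterior->posterior), axis2=X (left->right)"
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gevi = np.asarray(self.gevi, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        if self.gevi.ndim != 3 or self.reference.ndim != 3:
            raise ValueError("movie channels must be 3-D (T, Y, X)")
        if self.gevi.shape != self.reference.shape:
            raise ValueError(
                f"channel shape mismatch: {self.gevi.shape} vs {self.reference.shape}"
            )
        if not self.rate_hz > 0:
            raise ValueError(f"rate_hz must be positive, got {self.rate_hz}")
        if not self.pixel_pitch_mm > 0:
            raise ValueError(
                f"pixel_pitch_mm must be positive, got {self.pixel_pitch_mm}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.gevi.shape

    @property
    def n_frames(self) -> int:
        return self.gevi.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.rate_hz


@dataclass
class ElectricalTrace:
    """Single-channel LFP trace; samples in microvolts."""

    samples: np.ndarray
    rate_hz: float

    def __post_init__(self) -> None:
        self.samples = _as_float_1d(self.samples, "samples")
        if len(self.samples) < 2:
            raise ValueError("trace must contain at least 2 samples")
        if not self.rate_hz > 0:
            raise ValueError(f"rate_hz must be positive, got {self.rate_hz}")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.rate_hz


@dataclass
class EventTable:
    """Table of discrete events (times plus optional labels/extras)."""

    times_s: np.ndarray
    labels: list[str] | None = None
    extras: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float).ravel()
        if np.any(np.diff(self.times_s) < 0):
            raise ValueError("times_s must be sorted non-decreasing")
        if self.labels is not None and len(self.labels) != len(self.times_s):
            raise ValueError("labels length must match times_s")
        clean = {}
        for key, col in self.extras.items():
            col = np.asarray(col, dtype=float).ravel()
            if len(col) != len(self.times_s):
                raise ValueError(f"extras[{key!r}] length must match times_s")
            clean[key] = col
        self.extras = clean

    def __len__(self) -> int:
        return len(self.times_s)
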