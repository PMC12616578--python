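"""Readers and writers for traces, movies and event tables.

Formats: CSV (RFC 4180 via pandas), HDF5 (h5py), multi-page TIFF
(tifffile), JSON.  HDF5 round trips are bit exact; CSV round trips are
exact to 17 significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .types import ElectricalTrace, EventTable, TwoChannelMovie, TwoChannelTrace

__all__ = [
    "read_trace",
    "write_trace",
    "read_movie",
    "write_movie",
    "read_events",
    "write_events",
    "read_electrical",
    "write_electrical",
]

_TIME_TOL_S = 1e-6


class FormatError(ValueError):
    """Input file does not match the expected layout."""


class SamplingError(ValueError):
    """Time base of a CSV trace is not uniform."""


def _infer_format(path: Path, fmt: str | None, kinds: dict[str, str]) -> str:
    if fmt is not None:
        if fmt not in kinds.values():
            raise ValueError(f"unsupported format {fmt!r}")
        return fmt
    suffix = path.suffix.lower()
    if suffix in kinds:
        return kinds[suffix]
    raise ValueError(f"cannot infer format from suffix {suffix!r}")


def read_trace(path, format: str | None = None) -> TwoChannelTrace:
    """Load a two-channel trace from CSV or HDF5.

    CSV needs columns ``time,gevi,reference`` (rate inferred from the time
    column, which must be uniform to 1e-6 s) or ``gevi,reference`` plus a
    ``# rate_hz=<value>`` header comment.  HDF5 needs datasets ``/gevi``
    and ``/reference`` and a root attribute ``rate_hz``.
    """
    path = Path(path)
    fmt = _infer_format(path, format, {".csv": "csv", ".h5": "hdf5", ".hdf5": "hdf5"})
    if fmt == "hdf5":
        with h5py.File(path, "r") as f:
            for key in ("gevi", "reference"):
                if key not in f:
                    raise FormatError(f"{path}: missing dataset /{key}")
            if "rate_hz" not in f.attrs:
                raise FormatError(f"{path}: missing attribute rate_hz")
            return TwoChannelTrace(
                gevi=f["gevi"][()],
                reference=f["reference"][()],
                rate_hz=float(f.attrs["rate_hz"]),
                t0_s=float(f.attrs.get("t0_s", 0.0)),
            )
    # CSV
    rate_hz = None
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for token in first.lstrip("#").split(","):
            token = token.strip()
            if token.startswith("rate_hz="):
                rate_hz = float(token.split("=", 1)[1])
    df = pd.read_csv(path, comment="#")
    for col in ("gevi", "reference"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    t0_s = 0.0
    if "time" in df.columns:
        t = df["time"].to_numpy(float)
        dt = np.diff(t)
        if len(dt) == 0:
            raise FormatError(f"{path}: need at least 2 rows")
        rate_hz = 1.0 / float(np.median(dt))
        if np.max(np.abs(dt - 1.0 / rate_hz)) >= _TIME_TOL_S:
            raise SamplingError(f"{path}: non-uniform time base")
        t0_s = float(t[0])
    elif rate_hz is None:
        raise FormatError(f"{path}: no time column and no '# rate_hz=' header")
    gevi = df["gevi"].to_numpy(float)
    reference = df["reference"].to_numpy(float)
    for name, arr in (("gevi", gevi), ("reference", reference)):
        bad = np.flatnonzero(~np.isfinite(arr))
        if bad.size:
            raise FormatError(
                f"{path}: non-finite {name} sample at row {int(bad[0])}"
            )
    return TwoChannelTrace(gevi=gevi, reference=reference, rate_hz=rate_hz, t0_s=t0_s)


def write_trace(trace: TwoChannelTrace, path, format: str | None = None) -> None:
    path = Path(path)
    fmt = _infer_format(path, format, {".csv": "csv", ".h5": "hdf5", ".hdf5": "hdf5"})
    if fmt == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("gevi", data=trace.gevi)
            f.create_dataset("reference", data=trace.reference)
            f.attrs["rate_hz"] = trace.rate_hz
            f.attrs["t0_s"] = trace.t0_s
        return
    df = pd.DataFrame(
        {"time": trace.times_s, "gevi": trace.gevi, "reference": trace.reference}
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_movie(path, format: str | None = None, *, rate_hz: float | None = None,
               pixel_pitch_mm: float | None = None) -> TwoChannelMovie:
    """Load a two-channel movie.

    HDF5: one file with ``/gevi``, ``/reference`` and attrs ``rate_hz``,
    ``pixel_pitch_mm``.  TIFF: a stack pair named ``<stem>_gevi.tif`` /
    ``<stem>_reference.tif`` (pass either one, or the stem); rate and
    pitch must then be supplied by the caller.
    """
    path = Path(path)
    fmt = _infer_format(
        path, format, {".h5": "hdf5", ".hdf5": "hdf5", ".tif": "tiff", ".tiff": "tiff"}
    )
    if fmt == "hdf5":
        with h5py.File(path, "r") as f:
            for key in ("gevi", "reference"):
                if key not in f:
                    raise FormatError(f"{path}: missing dataset /{key}")
            return TwoChannelMovie(
                gevi=np.asarray(f["gevi"][()], dtype=float),
                reference=np.asarray(f["reference"][()], dtype=float),
                rate_hz=float(f.attrs["rate_hz"]),
                pixel_pitch_mm=float(f.attrs["pixel_pitch_mm"]),
            )
    # TIFF pair
    stem = str(path)
    for suffix in ("_gevi.tif", "_gevi.tiff", "_reference.tif", "_reference.tiff",
                   ".tif", ".tiff"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    candidates = [(f"{stem}_gevi{ext}", f"{stem}_reference{ext}")
                  for ext in (".tif", ".tiff")]
    for gpath, rpath in candidates:
        if Path(gpath).exists() and Path(rpath).exists():
            break
    else:
        raise FormatError(f"{path}: TIFF pair {stem}_gevi/_reference not found")
    gevi = np.asarray(tifffile.imread(gpath), dtype=float)
    reference = np.asarray(tifffile.imread(rpath), dtype=float)
    if gevi.shape != reference.shape:
        raise FormatError(
            f"TIFF channel shape mismatch: {gevi.shape} vs {reference.shape}"
        )
    if rate_hz is None or pixel_pitch_mm is None:
        raise ValueError("rate_hz and pixel_pitch_mm are required for TIFF input")
    return TwoChannelMovie(gevi=gevi, reference=reference, rate_hz=rate_hz,
                           pixel_pitch_mm=pixel_pitch_mm)


def write_movie(movie: TwoChannelMovie, path, format: str | None = None) -> None:
    path = Path(path)
    fmt = _infer_format(
        path, format, {".h5": "hdf5", ".hdf5": "hdf5", ".tif": "tiff", ".tiff": "tiff"}
    )
    if fmt == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("gevi", data=movie.gevi)
            f.create_dataset("reference", data=movie.reference)
            f.attrs["rate_hz"] = movie.rate_hz
            f.attrs["pixel_pitch_mm"] = movie.pixel_pitch_mm
        return
    stem = str(path)
    for suffix in (".tif", ".tiff"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
    tifffile.imwrite(f"{stem}_gevi.tif", movie.gevi.astype(np.float32),
                     photometric="minisblack")
    tifffile.imwrite(f"{stem}_reference.tif",
                     movie.reference.astype(np.float32),
                     photometric="minisblack")


def write_events(events: EventTable, path, format: str | None = None) -> None:
    path = Path(path)
    fmt = _infer_format(path, format, {".csv": "csv", ".json": "json"})
    if fmt == "json":
        payload = {
            "times_s": events.times_s.tolist(),
            "labels": events.labels,
            "extras": {k: v.tolist() for k, v in events.extras.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
        return
    data = {"times_s": events.times_s}
    if events.labels is not None:
        data["label"] = events.labels
    for key, col in events.extras.items():
        data[key] = col
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


def read_events(path, format: str | None = None) -> EventTable:
    path = Path(path)
    fmt = _infer_format(path, format, {".csv": "csv", ".json": "json"})
    if fmt == "json":
        with open(path) as fh:
            payload = json.load(fh)
        return EventTable(
            times_s=np.asarray(payload["times_s"], dtype=float),
            labels=payload.get("labels"),
            extras={k: np.asarray(v, dtype=float)
                    for k, v in payload.get("extras", {}).items()},
        )
    df = pd.read_csv(path)
    if "times_s" not in df.columns:
        raise FormatError(f"{path}: missing column 'times_s'")
    labels = df["label"].astype(str).tolist() if "label" in df.columns else None
    extras = {c: df[c].to_numpy(float) for c in df.columns
              if c not in ("times_s", "label")}
    return EventTable(times_s=df["times_s"].to_numpy(float), labels=labels,
                      extras=extras)


def write_electrical(trace: ElectricalTrace, path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("samples", data=trace.samples)
            f.attrs["rate_hz"] = trace.rate_hz
    else:
        pd.DataFrame({"samples": trace.samples}).to_csv(
            path, index=False, float_format="%.17g"
        )


def read_electrical(path, rate_hz: float | None = None) -> ElectricalTrace:
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            return ElectricalTrace(samples=f["samples"][()],
                                   rate_hz=float(f.attrs["rate_hz"]))
    if rate_hz is None:
        raise ValueError("rate_hz is required for CSV electrical traces")
    df = pd.read_csv(path)
    return ElectricalTrace(samples=df["samples"].to_numpy(float), rate_hz=rate_hz)
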