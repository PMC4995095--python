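"""Container file formats: HDF5 for signals, CSV for event/interval tables.

Layout of a session file::

    /signals/<name>   float64 dataset, attrs: rate_hz, t0_s, units, label
    /events/spikes    float64 seconds (optional)
    /events/stim      float64 seconds (optional)
    root attrs: duration_s, config_hash

CSV dialect: header required, times in seconds with 6 decimal digits,
intervals half-open; a leading ``# config_hash=...`` comment embeds
provenance and is skipped on read.
"""
from __future__ import annotations

import io as _io
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import ContinuousSignal, EventSeries, IntervalSeries, Recording
from .errors import FormatError, ValidationError

__all__ = [
    "write_recording",
    "read_recording",
    "write_events",
    "read_events",
    "write_intervals",
    "read_intervals",
]

_SIGNAL_ATTRS = ("rate_hz", "t0_s", "units", "label")


def write_recording(recording: Recording, path: str | Path, config_hash: str = "") -> None:
    with h5py.File(path, "w") as f:
        f.attrs["duration_s"] = recording.duration_s
        f.attrs["config_hash"] = config_hash or recording.meta.get("config_hash", "")
        sig = f.create_group("signals")
        for name, s in recording.signals.items():
            d = sig.create_dataset(name, data=s.samples)
            d.attrs["rate_hz"] = s.rate_hz
            d.attrs["t0_s"] = s.t0_s
            d.attrs["units"] = s.units
            d.attrs["label"] = s.label or name
        ev = f.create_group("events")
        if recording.spikes is not None:
            ev.create_dataset("spikes", data=recording.spikes.times_s)
        if recording.stim is not None:
            ev.create_dataset("stim", data=recording.stim.times_s)


def read_recording(path: str | Path) -> Recording:
    with h5py.File(path, "r") as f:
        signals: dict[str, ContinuousSignal] = {}
        for name, d in f.get("signals", {}).items():
            for attr in ("rate_hz", "t0_s"):
                if attr not in d.attrs:
                    raise FormatError(f"dataset 'signals/{name}' lacks required attribute {attr!r}")
            signals[name] = ContinuousSignal(
                samples=d[...],
                rate_hz=float(d.attrs["rate_hz"]),
                t0_s=float(d.attrs["t0_s"]),
                units=str(d.attrs.get("units", "")),
                label=str(d.attrs.get("label", name)),
            )
        ev = f.get("events", {})
        spikes = EventSeries(ev["spikes"][...], "spikes") if "spikes" in ev else None
        stim = EventSeries(ev["stim"][...], "stimulation") if "stim" in ev else None
        meta = {"config_hash": str(f.attrs.get("config_hash", ""))}
        return Recording(
            signals=signals,
            spikes=spikes,
            stim=stim,
            duration_s=float(f.attrs.get("duration_s", 0.0)),
            meta=meta,
        )


def _write_csv(df: pd.DataFrame, path: str | Path, config_hash: str) -> None:
    buf = _io.StringIO()
    if config_hash:
        buf.write(f"# config_hash={config_hash}\n")
    df.to_csv(buf, index=False, float_format="%.6f")
    Path(path).write_text(buf.getvalue())


def write_events(series: EventSeries, path: str | Path, config_hash: str = "") -> None:
    df = pd.DataFrame({"time_s": series.times_s, "label": [series.label] * series.n})
    _write_csv(df, path, config_hash)


def read_events(path: str | Path, label: str = "") -> EventSeries:
    df = pd.read_csv(path, comment="#")
    if "time_s" not in df.columns:
        raise FormatError(f"{path}: missing required column 'time_s'")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size and np.any(np.diff(t) < 0):
        raise ValidationError(f"{path}: times are not sorted")
    lab = label or (str(df["label"].iloc[0]) if "label" in df.columns and len(df) else "")
    return EventSeries(t, lab)


def write_intervals(series: IntervalSeries, path: str | Path, config_hash: str = "") -> None:
    df = pd.DataFrame(
        {"onset_s": series.onsets_s, "offset_s": series.offsets_s, "label": list(series.labels)}
    )
    _write_csv(df, path, config_hash)


def read_intervals(path: str | Path, name: str = "") -> IntervalSeries:
    df = pd.read_csv(path, comment="#")
    for col in ("onset_s", "offset_s"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    on = df["onset_s"].to_numpy(dtype=float)
    off = df["offset_s"].to_numpy(dtype=float)
    if on.size and np.any(np.diff(on) < 0):
        raise ValidationError(f"{path}: intervals are not sorted")
    labels = df["label"].astype(str).to_numpy() if "label" in df.columns else None
    return IntervalSeries(on, off, labels, name=name)
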