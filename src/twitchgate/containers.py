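"""Core in-memory containers: continuous signals, point events, labeled intervals.

Conventions used throughout the package:

* times are seconds, float64, zero-based at recording start;
* intervals are half-open ``[onset, offset)``;
* event times within a series are sorted (non-decreasing).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

from .errors import ConsistencyError

WAKE = "wake"
ACTIVE_SLEEP = "active_sleep"


@dataclass
class ContinuousSignal:
    """A uniformly sampled real-valued channel (EMG envelope, LFP, MUA band)."""

    samples: np.ndarray
    rate_hz: float
    t0_s: float = 0.0
    label: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.rate_hz <= 0:
            raise ConsistencyError(f"rate_hz must be positive, got {self.rate_hz}")
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ConsistencyError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ConsistencyError(f"signal {self.label!r} contains non-finite samples")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n / self.rate_hz

    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n) / self.rate_hz

    def slice(self, t_start: float, t_stop: float) -> "ContinuousSignal":
        """Return the samples in ``[t_start, t_stop)`` as a new signal."""
        i0 = int(np.ceil((t_start - self.t0_s) * self.rate_hz - 1e-9))
        i1 = int(np.ceil((t_stop - self.t0_s) * self.rate_hz - 1e-9))
        i0, i1 = max(i0, 0), min(i1, self.n)
        return replace(self, samples=self.samples[i0:i1].copy(), t0_s=self.t0_s + i0 / self.rate_hz)


@dataclass
class EventSeries:
    """Sorted point events (spikes, twitches, stimulations)."""

    times_s: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=np.float64).ravel()
        if self.times_s.size and np.any(np.diff(self.times_s) < 0):
            raise ConsistencyError(f"event series {self.label!r} is not sorted")

    @property
    def n(self) -> int:
        return self.times_s.size

    def __len__(self) -> int:
        return self.n

    def between(self, t_start: float, t_stop: float) -> "EventSeries":
        lo, hi = np.searchsorted(self.times_s, [t_start, t_stop], side="left")
        return EventSeries(self.times_s[lo:hi].copy(), self.label)

    def shifted(self, dt: float) -> "EventSeries":
        return EventSeries(self.times_s + dt, self.label)


# Spike trains are plain event series; the alias documents intent at call sites.
SpikeTrain = EventSeries


@dataclass
class IntervalSeries:
    """Sorted, non-overlapping half-open labeled intervals."""

    onsets_s: np.ndarray
    offsets_s: np.ndarray
    labels: np.ndarray | None = None
    name: str = ""

    def __post_init__(self) -> None:
        self.onsets_s = np.asarray(self.onsets_s, dtype=np.float64).ravel()
        self.offsets_s = np.asarray(self.offsets_s, dtype=np.float64).ravel()
        if self.onsets_s.shape != self.offsets_s.shape:
            raise ConsistencyError("onsets and offsets must have equal length")
        if self.labels is None:
            self.labels = np.array([""] * self.onsets_s.size, dtype=object)
        else:
            self.labels = np.asarray(self.labels, dtype=object).ravel()
            if self.labels.shape != self.onsets_s.shape:
                raise ConsistencyError("labels must match interval count")
        if np.any(self.offsets_s <= self.onsets_s):
            raise ConsistencyError(f"interval series {self.name!r}: offset <= onset")
        if self.onsets_s.size > 1:
            if np.any(np.diff(self.onsets_s) < 0):
                raise ConsistencyError(f"interval series {self.name!r} is not sorted")
            if np.any(self.onsets_s[1:] < self.offsets_s[:-1]):
                raise ConsistencyError(f"interval series {self.name!r} has overlaps")

    @property
    def n(self) -> int:
        return self.onsets_s.size

    def __len__(self) -> int:
        return self.n

    def __iter__(self) -> Iterator[tuple[float, float, str]]:
        yield from zip(self.onsets_s, self.offsets_s, self.labels)

    @property
    def durations_s(self) -> np.ndarray:
        return self.offsets_s - self.onsets_s

    def contains(self, times: Sequence[float]) -> np.ndarray:
        """Boolean mask: does each time fall inside some interval?"""
        t = np.asarray(times, dtype=np.float64)
        idx = np.searchsorted(self.onsets_s, t, side="right") - 1
        ok = idx >= 0
        out = np.zeros(t.shape, dtype=bool)
        out[ok] = t[ok] < self.offsets_s[idx[ok]]
        return out

    def between(self, t_start: float, t_stop: float, clip: bool = True) -> "IntervalSeries":
        """Intervals overlapping ``[t_start, t_stop)``, optionally clipped to it."""
        keep = (self.offsets_s > t_start) & (self.onsets_s < t_stop)
        on, off = self.onsets_s[keep].copy(), self.offsets_s[keep].copy()
        if clip:
            on, off = np.clip(on, t_start, None), np.clip(off, None, t_stop)
        return IntervalSeries(on, off, self.labels[keep].copy(), self.name)


@dataclass
class BoutSegmentation:
    """Exhaustive alternating wake / active-sleep partition of a recording.

    Derived from the nuchal EMG envelope: high tone marks wake, atonia marks
    active sleep.  The intervals cover ``[t0, t0 + duration)`` with no gaps.
    """

    intervals: IntervalSeries

    def __post_init__(self) -> None:
        iv = self.intervals
        bad = set(iv.labels) - {WAKE, ACTIVE_SLEEP}
        if bad:
            raise ConsistencyError(f"bout labels must be wake/active_sleep, got {bad}")
        if iv.n > 1 and not np.allclose(iv.onsets_s[1:], iv.offsets_s[:-1]):
            raise ConsistencyError("bouts must partition the recording without gaps")

    @property
    def t0_s(self) -> float:
        return float(self.intervals.onsets_s[0])

    @property
    def t_end_s(self) -> float:
        return float(self.intervals.offsets_s[-1])

    def for_state(self, state: str) -> IntervalSeries:
        keep = self.intervals.labels == state
        return IntervalSeries(
            self.intervals.onsets_s[keep],
            self.intervals.offsets_s[keep],
            self.intervals.labels[keep],
            name=state,
        )

    def state_at(self, times: Sequence[float]) -> np.ndarray:
        """State label for each time (times outside the record get '')."""
        t = np.asarray(times, dtype=np.float64)
        idx = np.searchsorted(self.intervals.onsets_s, t, side="right") - 1
        out = np.array([""] * t.size, dtype=object)
        ok = (idx >= 0) & (t < self.t_end_s)
        out[ok] = self.intervals.labels[idx[ok]]
        return out

    def time_in_state(self, state: str) -> float:
        return float(self.for_state(state).durations_s.sum())

    def between(self, t_start: float, t_stop: float) -> "BoutSegmentation":
        return BoutSegmentation(self.intervals.between(t_start, t_stop, clip=True))


@dataclass
class Recording:
    """A synthetic or imported session: named signals plus event channels."""

    signals: dict[str, ContinuousSignal] = field(default_factory=dict)
    spikes: SpikeTrain | None = None
    stim: EventSeries | None = None
    duration_s: float = 0.0
    meta: dict = field(default_factory=dict)

    def slice(self, t_start: float, t_stop: float) -> "Recording":
        """View of ``[t_start, t_stop)``; events are re-based are left absolute."""
        return Recording(
            signals={k: s.slice(t_start, t_stop) for k, s in self.signals.items()},
            spikes=None if self.spikes is None else self.spikes.between(t_start, t_stop),
            stim=None if self.stim is None else self.stim.between(t_start, t_stop),
            duration_s=t_stop - t_start,
            meta=dict(self.meta),
        )
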