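"""Spindle-burst detection in the LFP by RMS thresholding.

A spindle burst is an oscillatory LFP event with at least three
oscillations, a dominant frequency of 10-15 Hz, and a duration of at least
100 ms.  Detection band-passes the LFP (1-40 Hz), computes the RMS envelope
(tau = 10 ms), thresholds it at the midpoint between the envelope baseline
and the mean peak of reference bursts, and then applies the acceptance
criteria to each candidate excursion.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import periodogram

from .containers import ContinuousSignal, IntervalSeries
from .errors import DetectionInfeasibleError, UndefinedFrequencyError
from .preprocess import bandpass, rms_envelope

__all__ = [
    "SpindleCriteria",
    "SpindleBurst",
    "spindle_threshold",
    "detect_spindles",
    "dominant_frequency",
    "bursts_to_intervals",
]


@dataclass
class SpindleCriteria:
    min_oscillations: int = 3
    freq_band_hz: tuple[float, float] = (10.0, 15.0)
    min_dur_s: float = 0.1
    lfp_band_hz: tuple[float, float] = (1.0, 40.0)
    rms_tau_s: float = 0.01
    n_reference_bursts: int = 5
    candidate_k: float = 2.0      # candidate = RMS excursion above k x baseline
    merge_gap_s: float = 0.05     # adjacent candidates closer than this merge

    def __post_init__(self) -> None:
        if self.min_dur_s <= 0:
            raise ValueError("min_dur_s must be > 0")
        if self.freq_band_hz[0] >= self.freq_band_hz[1] or self.lfp_band_hz[0] >= self.lfp_band_hz[1]:
            raise ValueError("band low must be below band high")


@dataclass
class SpindleBurst:
    onset_s: float
    offset_s: float
    dominant_freq_hz: float
    n_oscillations: int
    peak_rms: float

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


def _rms_of(lfp: ContinuousSignal, criteria: SpindleCriteria) -> tuple[ContinuousSignal, ContinuousSignal]:
    filt = bandpass(lfp, *criteria.lfp_band_hz)
    return filt, rms_envelope(filt, criteria.rms_tau_s)


def _candidate_runs(env: np.ndarray, thr: float, fs: float, merge_gap_s: float) -> list[tuple[int, int]]:
    above = env > thr
    change = np.flatnonzero(np.diff(above.astype(np.int8))) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [env.size]))
    runs = [(s, e) for s, e in zip(starts, ends) if above[s]]
    merged: list[list[int]] = []
    gap = int(round(merge_gap_s * fs))
    for s, e in runs:
        if merged and s - merged[-1][1] < gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def spindle_threshold(rms_env: ContinuousSignal, criteria: SpindleCriteria | None = None) -> float:
    """Detection threshold: midpoint of the RMS baseline and reference-burst peaks.

    The baseline is the median RMS outside candidate excursions; reference
    bursts are the ``n_reference_bursts`` candidates with the largest peaks.
    Raises ``DetectionInfeasibleError`` with fewer candidates than that.
    """
    criteria = criteria or SpindleCriteria()
    env = rms_env.samples
    baseline = float(np.median(env))
    runs = _candidate_runs(env, criteria.candidate_k * baseline, rms_env.rate_hz, criteria.merge_gap_s)
    outside = np.ones(env.size, dtype=bool)
    for s, e in runs:
        outside[s:e] = False
    if outside.any():
        baseline = float(np.median(env[outside]))
    if len(runs) < criteria.n_reference_bursts:
        raise DetectionInfeasibleError(
            f"only {len(runs)} candidate bursts (< {criteria.n_reference_bursts})"
        )
    peaks = np.sort([env[s:e].max() for s, e in runs])[::-1]
    ref_mean = float(np.mean(peaks[: criteria.n_reference_bursts]))
    return 0.5 * (baseline + ref_mean)


def dominant_frequency(
    segment: ContinuousSignal, band_hz: tuple[float, float] = (1.0, 40.0)
) -> float:
    """Frequency of the spectral peak of a segment within ``band_hz``.

    Uses a Hann-windowed periodogram zero-padded to at least 1 Hz
    resolution.  For segments shorter than one period of the band's low
    edge, the searchable band is floored at ``1/duration`` (lower
    frequencies are unresolvable); a segment with fewer than two cycles of
    the band's high edge has no defined dominant frequency.
    """
    n = segment.n
    fs = segment.rate_hz
    dur = n / fs
    if dur * band_hz[1] < 2:
        raise UndefinedFrequencyError(
            f"segment of {dur:.3f} s too short for a spectral peak in {band_hz} Hz"
        )
    nfft = max(int(2 ** np.ceil(np.log2(fs / 1.0))), n)
    f, p = periodogram(segment.samples, fs=fs, window="hann", nfft=nfft)
    lo = max(band_hz[0], 1.0 / dur)
    sel = (f >= lo) & (f <= band_hz[1])
    if not sel.any():
        raise UndefinedFrequencyError(f"no spectral bins inside {band_hz} Hz")
    return float(f[sel][np.argmax(p[sel])])


def _oscillation_count(filt_segment: np.ndarray) -> int:
    """Oscillations = zero-crossing pairs of the band-filtered segment.

    A pure tone of n cycles has 2n-1 to 2n+1 sign changes depending on
    phase; ``(crossings + 1) // 2`` recovers n and counts a trailing
    partial cycle clipped by the envelope threshold.
    """
    x = filt_segment
    crossings = np.count_nonzero(np.signbit(x[1:]) != np.signbit(x[:-1]))
    return (crossings + 1) // 2


def detect_spindles(
    lfp: ContinuousSignal, criteria: SpindleCriteria | None = None
) -> list[SpindleBurst]:
    """Detect spindle bursts in a (raw or band-filtered) LFP channel.

    Candidates are RMS-envelope excursions above the midpoint threshold
    (adjacent candidates < 50 ms apart merged); a candidate is accepted iff
    its duration is >= ``min_dur_s``, its dominant frequency lies within
    ``freq_band_hz``, and it contains >= ``min_oscillations`` oscillations.
    An empty list is a valid result.
    """
    criteria = criteria or SpindleCriteria()
    filt, env = _rms_of(lfp, criteria)
    try:
        thr = spindle_threshold(env, criteria)
    except DetectionInfeasibleError:
        return []
    fs = lfp.rate_hz
    out: list[SpindleBurst] = []
    for s, e in _candidate_runs(env.samples, thr, fs, criteria.merge_gap_s):
        dur = (e - s) / fs
        if dur < criteria.min_dur_s:
            continue
        seg = ContinuousSignal(filt.samples[s:e], fs, t0_s=lfp.t0_s + s / fs)
        try:
            freq = dominant_frequency(seg, criteria.lfp_band_hz)
        except UndefinedFrequencyError:
            continue
        if not (criteria.freq_band_hz[0] <= freq <= criteria.freq_band_hz[1]):
            continue
        n_osc = _oscillation_count(filt.samples[s:e])
        if n_osc < criteria.min_oscillations:
            continue
        out.append(
            SpindleBurst(
                onset_s=lfp.t0_s + s / fs,
                offset_s=lfp.t0_s + e / fs,
                dominant_freq_hz=freq,
                n_oscillations=n_osc,
                peak_rms=float(env.samples[s:e].max()),
            )
        )
    return out


def bursts_to_intervals(bursts: list[SpindleBurst]) -> IntervalSeries:
    if not bursts:
        return IntervalSeries(np.empty(0), np.empty(0), name="spindles")
    return IntervalSeries(
        [b.onset_s for b in bursts], [b.offset_s for b in bursts], name="spindles"
    )
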