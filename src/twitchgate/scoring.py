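"""EMG-based behavioral-state scoring and motor-event extraction.

The nuchal EMG envelope is dichotomized into high tone (wake) and atonia
(active sleep).  Twitches are suprathreshold limb-EMG excursions exceeding
3x the atonia baseline during active sleep; wake movements are limb-EMG
bursts lasting at least 300 ms during high tone, detected with a threshold
at the midpoint between the atonia baseline and the mean peak amplitude of
reference movements.  All thresholds are relative, so detection is invariant
to rescaling the envelope.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    ACTIVE_SLEEP,
    WAKE,
    BoutSegmentation,
    ContinuousSignal,
    EventSeries,
    IntervalSeries,
)
from .errors import ParameterError

__all__ = [
    "ScoringConfig",
    "score_tone",
    "detect_twitches",
    "detect_wake_movements",
    "state_rates",
    "paired_state_test",
]


@dataclass
class ScoringConfig:
    twitch_k: float = 3.0                # twitch threshold multiplier over atonia baseline
    wake_move_min_dur_s: float = 0.3     # minimum suprathreshold duration of a movement
    min_bout_s: float = 5.0              # shorter tone runs are merged into neighbors
    tone_threshold_method: str = "midpoint"  # "midpoint" (2-means) or "quantile"
    n_reference_movements: int = 5
    twitch_refractory_s: float = 0.1
    edge_exclude_tau_mult: float = 5.0   # envelope transient excluded from baselines
    envelope_tau_s: float = 0.01

    def __post_init__(self) -> None:
        if self.twitch_k <= 1:
            raise ParameterError(f"twitch_k must be > 1, got {self.twitch_k}")
        if self.wake_move_min_dur_s <= 0:
            raise ParameterError("wake_move_min_dur_s must be > 0")
        if self.tone_threshold_method not in ("midpoint", "quantile"):
            raise ParameterError(f"unknown tone_threshold_method {self.tone_threshold_method!r}")


def _two_means_threshold(x: np.ndarray, n_iter: int = 50) -> tuple[float, float, float]:
    """1-D two-means split; returns (threshold, low_center, high_center)."""
    c1, c2 = np.percentile(x, [10.0, 90.0])
    for _ in range(n_iter):
        mid = 0.5 * (c1 + c2)
        lo, hi = x[x <= mid], x[x > mid]
        if lo.size == 0 or hi.size == 0:
            break
        n1, n2 = lo.mean(), hi.mean()
        if n1 == c1 and n2 == c2:
            break
        c1, c2 = n1, n2
    return 0.5 * (c1 + c2), c1, c2


def score_tone(nuchal_env: ContinuousSignal, cfg: ScoringConfig | None = None) -> BoutSegmentation:
    """Dichotomize the nuchal envelope into wake (high tone) / active-sleep bouts.

    Runs shorter than ``min_bout_s`` are absorbed into their neighbors
    (shortest first), so brief threshold chatter does not fragment bouts.
    A flat (unimodal) envelope yields a single wake bout with a warning.
    """
    cfg = cfg or ScoringConfig()
    x = nuchal_env.samples
    fs = nuchal_env.rate_hz
    if cfg.tone_threshold_method == "quantile":
        q10, q90 = np.percentile(x, [10.0, 90.0])
        thr, c1, c2 = 0.5 * (q10 + q90), q10, q90
    else:
        thr, c1, c2 = _two_means_threshold(x)
    t0, t_end = nuchal_env.t0_s, nuchal_env.t0_s + nuchal_env.duration_s
    if c2 - c1 < 0.2 * max(c2, 1e-12):
        warnings.warn("nuchal envelope is unimodal; returning a single wake bout")
        iv = IntervalSeries([t0], [t_end], [WAKE], name="bouts")
        return BoutSegmentation(iv)

    high = x > thr
    change = np.flatnonzero(np.diff(high.astype(np.int8))) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [x.size]))
    runs = [[WAKE if high[s] else ACTIVE_SLEEP, s / fs + t0, e / fs + t0] for s, e in zip(starts, ends)]

    # Merge short runs, shortest first; interior removals fuse the two
    # (same-state) neighbors, edge removals relabel into the single neighbor.
    while len(runs) > 1:
        durs = [r[2] - r[1] for r in runs]
        i = int(np.argmin(durs))
        if durs[i] >= cfg.min_bout_s:
            break
        if 0 < i < len(runs) - 1:
            runs[i - 1][2] = runs[i + 1][2]
            del runs[i: i + 2]
        elif i == 0:
            runs[1][1] = runs[0][1]
            del runs[0]
        else:
            runs[-2][2] = runs[-1][2]
            del runs[-1]
    labels = [r[0] for r in runs]
    iv = IntervalSeries([r[1] for r in runs], [r[2] for r in runs], labels, name="bouts")
    return BoutSegmentation(iv)


def _edge_mask(n: int, fs: float, cfg: ScoringConfig) -> np.ndarray:
    m = np.ones(n, dtype=bool)
    k = int(cfg.edge_exclude_tau_mult * cfg.envelope_tau_s * fs)
    if 0 < k < n:
        m[:k] = False
    return m


def atonia_baseline(limb_env: ContinuousSignal, bouts: BoutSegmentation, cfg: ScoringConfig) -> float:
    """Median envelope over active-sleep samples (robust to twitch excursions)."""
    t = limb_env.times()
    mask = bouts.for_state(ACTIVE_SLEEP).contains(t) & _edge_mask(limb_env.n, limb_env.rate_hz, cfg)
    if not mask.any():
        return float(np.median(limb_env.samples))
    return float(np.median(limb_env.samples[mask]))


def _excursions(x: np.ndarray, thr: float) -> list[tuple[int, int]]:
    """Maximal runs with x > thr (strict), as (start, stop) index pairs."""
    above = x > thr
    change = np.flatnonzero(np.diff(above.astype(np.int8))) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [x.size]))
    return [(s, e) for s, e in zip(starts, ends) if above[s]]


def detect_twitches(
    limb_env: ContinuousSignal, bouts: BoutSegmentation, cfg: ScoringConfig | None = None
) -> EventSeries:
    """Myoclonic twitches: envelope excursions > ``twitch_k`` x atonia baseline.

    Only excursions whose peak falls inside an active-sleep bout count
    (twitches are defined against atonia); the event time is the excursion
    peak, and a 100 ms refractory suppresses secondary crossings.  The
    threshold comparison is strict, so an excursion at exactly 3x baseline is
    not a twitch.
    """
    cfg = cfg or ScoringConfig()
    sleep = bouts.for_state(ACTIVE_SLEEP)
    if sleep.n == 0:
        return EventSeries(np.empty(0), label="twitches")
    base = atonia_baseline(limb_env, bouts, cfg)
    thr = cfg.twitch_k * base
    x, fs, t0 = limb_env.samples, limb_env.rate_hz, limb_env.t0_s
    peaks = []
    for s, e in _excursions(x, thr):
        p = s + int(np.argmax(x[s:e]))
        peaks.append(t0 + p / fs)
    peaks = np.array([p for p in peaks if sleep.contains([p])[0]])
    if peaks.size:
        keep = [0]
        for i in range(1, peaks.size):
            if peaks[i] - peaks[keep[-1]] >= cfg.twitch_refractory_s:
                keep.append(i)
        peaks = peaks[keep]
    return EventSeries(peaks, label="twitches")


def detect_wake_movements(
    limb_env: ContinuousSignal,
    bouts: BoutSegmentation,
    cfg: ScoringConfig | None = None,
    rng: np.random.Generator | None = None,
) -> IntervalSeries:
    """Wake movements: long high-amplitude limb-EMG bursts during high tone.

    Candidate bursts (>= ``wake_move_min_dur_s`` above a provisional high
    threshold, onset during wake) supply reference peak amplitudes: by
    default the ``n_reference_movements`` largest peaks; with ``rng`` given,
    a seeded random draw from the top decile.  The final threshold is the
    midpoint between the atonia baseline and the mean reference peak; kept
    intervals are those with suprathreshold duration >= the minimum, onset
    in a wake bout.  With too few candidates the twitch threshold is used as
    a fallback (with a warning).
    """
    cfg = cfg or ScoringConfig()
    wake = bouts.for_state(WAKE)
    x, fs, t0 = limb_env.samples, limb_env.rate_hz, limb_env.t0_s
    base = atonia_baseline(limb_env, bouts, cfg)
    if wake.n == 0:
        return IntervalSeries(np.empty(0), np.empty(0), name="wake_movements")

    wake_mask = wake.contains(limb_env.times())
    tone_level = float(np.median(x[wake_mask])) if wake_mask.any() else base
    provisional = 0.5 * (tone_level + float(x[wake_mask].max())) if wake_mask.any() else base
    min_len = int(round(cfg.wake_move_min_dur_s * fs))
    cand_peaks = []
    for s, e in _excursions(x, provisional):
        if e - s >= min_len and wake.contains([t0 + s / fs])[0]:
            cand_peaks.append(float(x[s:e].max()))
    if len(cand_peaks) < cfg.n_reference_movements:
        warnings.warn(
            f"only {len(cand_peaks)} candidate movements (< {cfg.n_reference_movements}); "
            "falling back to the twitch threshold"
        )
        thr = cfg.twitch_k * base
    else:
        peaks = np.sort(cand_peaks)[::-1]
        if rng is not None:
            top = peaks[: max(len(peaks) // 10, cfg.n_reference_movements)]
            ref = rng.choice(top, size=cfg.n_reference_movements, replace=False)
        else:
            ref = peaks[: cfg.n_reference_movements]
        thr = 0.5 * (base + float(np.mean(ref)))

    onsets, offsets = [], []
    for s, e in _excursions(x, thr):
        if e - s >= min_len and wake.contains([t0 + s / fs])[0]:
            onsets.append(t0 + s / fs)
            offsets.append(t0 + e / fs)
    if not onsets:
        return IntervalSeries(np.empty(0), np.empty(0), name="wake_movements")
    return IntervalSeries(onsets, offsets, name="wake_movements")


def state_rates(
    events: EventSeries, bouts: BoutSegmentation, min_pairs: int = 20
) -> tuple[pd.DataFrame, dict]:
    """Per-bout event rates plus a within-subject state-dependence summary.

    Returns a table with one row per bout (events, rate in Hz and per
    minute) and a summary containing per-state mean bout rates, pooled
    rates, and — when at least ``min_pairs`` successive wake/sleep bout
    pairs exist — the Wilcoxon matched-pairs signed-ranks test on paired
    bout rates.  With fewer pairs the test fields are flagged unavailable.
    """
    times = events.times_s
    rows = []
    for on, off, lab in bouts.intervals:
        n = int(np.searchsorted(times, off, "left") - np.searchsorted(times, on, "left"))
        dur = off - on
        rows.append(
            {"state": lab, "onset_s": on, "offset_s": off, "duration_s": dur,
             "n_events": n, "rate_hz": n / dur, "rate_per_min": 60.0 * n / dur}
        )
    table = pd.DataFrame(rows)
    summary: dict = {}
    for state in (WAKE, ACTIVE_SLEEP):
        sub = table[table.state == state]
        tot_t = sub.duration_s.sum()
        summary[state] = {
            "n_bouts": int(len(sub)),
            "mean_bout_rate_hz": float(sub.rate_hz.mean()) if len(sub) else np.nan,
            "pooled_rate_hz": float(sub.n_events.sum() / tot_t) if tot_t > 0 else np.nan,
        }
    # successive disjoint bout pairs, one of each state (bouts alternate)
    pairs = []
    for i in range(0, len(table) - 1, 2):
        a, b = table.iloc[i], table.iloc[i + 1]
        if {a.state, b.state} == {WAKE, ACTIVE_SLEEP}:
            w, s = (a, b) if a.state == WAKE else (b, a)
            pairs.append((w.rate_hz, s.rate_hz))
    summary["n_pairs"] = len(pairs)
    if len(pairs) >= min_pairs:
        w_rates, s_rates = map(np.array, zip(*pairs))
        d = s_rates - w_rates
        if np.allclose(d, 0):
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.wilcoxon(s_rates, w_rates)
        summary["wilcoxon"] = {"statistic": float(stat), "p": float(p)}
        summary["test_available"] = True
    else:
        summary["wilcoxon"] = None
        summary["test_available"] = False
    return table, summary


def paired_state_test(sleep_means: np.ndarray, wake_means: np.ndarray) -> dict:
    """Across-subject paired t test on per-subject mean rates (sleep vs wake)."""
    sleep_means = np.asarray(sleep_means, float)
    wake_means = np.asarray(wake_means, float)
    if sleep_means.size != wake_means.size or sleep_means.size < 2:
        raise ParameterError("need >= 2 paired subject means")
    t, p = stats.ttest_rel(sleep_means, wake_means)
    return {"t": float(t), "p": float(p), "df": int(sleep_means.size - 1), "n": int(sleep_means.size)}
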