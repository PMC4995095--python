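"""Pre/post infusion delta-firing-rate analysis.

A session is split into pre- and post-infusion epochs (30 min each by
default).  For each epoch and behavioral state, a perievent correlation
(3 s window, 50 ms bins) is built around motor events, the mean rate over
the quiescence window (1-1.5 s before the trigger) is subtracted, and the
pre correlation is subtracted from the post correlation.  The resulting
delta curves are averaged within experimental groups (drug vs saline), the
peak change around the expected reafference latency is extracted, and
groups are compared.  Motor metrics (movements/min, twitches/min, tonic
firing rate) serve as controls that the manipulation acts on gating, not on
motor output.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import EventSeries, Recording, SpikeTrain
from .errors import DesignError, ParameterError
from .perievent import INFUSION, CorrelationSpec, EventCorrelation, event_correlation

__all__ = [
    "InfusionDesign",
    "DeltaResult",
    "epoch_split",
    "split_events",
    "baseline_subtracted_correlation",
    "delta_correlation",
    "group_delta",
    "peak_change",
    "expected_latency_window",
    "compare_conditions",
    "motor_metrics",
]


@dataclass
class InfusionDesign:
    pre_s: float = 1800.0
    post_s: float = 1800.0
    group: str = "drug"
    quiescence_window_s: tuple[float, float] = (-1.5, -1.0)
    spec: CorrelationSpec = INFUSION

    def __post_init__(self) -> None:
        if self.pre_s <= 0 or self.post_s <= 0:
            raise DesignError("pre_s and post_s must be positive")
        q0, q1 = self.quiescence_window_s
        if not (q0 < q1 <= 0):
            raise DesignError(f"quiescence window {self.quiescence_window_s} must precede the trigger")
        if q0 < -self.spec.half_s:
            raise DesignError("quiescence window falls outside the correlation window")


def epoch_split(recording: Recording, design: InfusionDesign) -> tuple[Recording, Recording]:
    """Pre ``[0, pre_s)`` and post ``[pre_s, pre_s + post_s)`` views.

    Half-open convention: an event exactly at the boundary belongs to the
    post epoch.  Raises ``DesignError`` if the recording is too short.
    """
    if recording.duration_s < design.pre_s + design.post_s:
        raise DesignError(
            f"recording of {recording.duration_s} s cannot hold "
            f"{design.pre_s} + {design.post_s} s epochs"
        )
    pre = recording.slice(0.0, design.pre_s)
    post = recording.slice(design.pre_s, design.pre_s + design.post_s)
    return pre, post


def split_events(events: EventSeries, design: InfusionDesign) -> tuple[EventSeries, EventSeries]:
    """Partition an event series at the infusion boundary (boundary -> post)."""
    t = events.times_s
    b = design.pre_s
    return (
        EventSeries(t[t < b], events.label),
        EventSeries(t[(t >= b) & (t < b + design.post_s)], events.label),
    )


def _quiescence_bins(corr: EventCorrelation, window: tuple[float, float]) -> np.ndarray:
    centers = corr.bin_centers_s
    return (centers >= window[0]) & (centers < window[1])


def baseline_subtracted_correlation(
    spikes: SpikeTrain,
    triggers: EventSeries,
    design: InfusionDesign,
    t_span: tuple[float, float] | None = None,
) -> EventCorrelation:
    """Perievent correlation minus its mean rate over the quiescence window.

    After subtraction the mean over quiescence bins is exactly zero, so the
    delta analysis compares evoked activity, not baseline drift.
    """
    corr = event_correlation(spikes, triggers, design.spec, t_span)
    qmask = _quiescence_bins(corr, design.quiescence_window_s)
    if not qmask.any():
        raise ParameterError("quiescence window contains no bins")
    corr.rate_hz = corr.rate_hz - corr.rate_hz[qmask].mean()
    corr.meta["quiescence_window_s"] = design.quiescence_window_s
    return corr


@dataclass
class DeltaResult:
    bin_edges_s: np.ndarray
    delta_hz: np.ndarray
    sem_hz: np.ndarray | None = None
    n_subjects: int = 1
    peak_change_hz: float | None = None
    peak_latency_s: float | None = None
    meta: dict = field(default_factory=dict)

    @property
    def bin_centers_s(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_s[:-1] + self.bin_edges_s[1:])


def delta_correlation(post_corr: EventCorrelation, pre_corr: EventCorrelation) -> DeltaResult:
    """Per-bin post-minus-pre change in (baseline-subtracted) firing rate."""
    if post_corr.rate_hz.size != pre_corr.rate_hz.size or not np.allclose(
        post_corr.bin_edges_s, pre_corr.bin_edges_s
    ):
        raise ParameterError("pre and post correlations use different specs")
    return DeltaResult(
        bin_edges_s=post_corr.bin_edges_s.copy(),
        delta_hz=post_corr.rate_hz - pre_corr.rate_hz,
    )


def group_delta(deltas: list[DeltaResult]) -> DeltaResult:
    """Group mean +/- SEM per bin across subjects."""
    if not deltas:
        raise ParameterError("no subjects")
    a = np.vstack([d.delta_hz for d in deltas])
    n = a.shape[0]
    sem = a.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(a.shape[1])
    return DeltaResult(
        bin_edges_s=deltas[0].bin_edges_s.copy(),
        delta_hz=a.mean(axis=0),
        sem_hz=sem,
        n_subjects=n,
    )


def peak_change(delta: DeltaResult, window_s: tuple[float, float]) -> tuple[float, float]:
    """Signed change of maximum magnitude within the latency window.

    Ties break toward the earliest bin; returns (signed peak, latency).
    """
    centers = delta.bin_centers_s
    sel = (centers >= window_s[0]) & (centers <= window_s[1])
    if not sel.any():
        raise ParameterError(f"latency window {window_s} contains no bins")
    d = delta.delta_hz[sel]
    i = int(np.argmax(np.abs(d)))
    return float(d[i]), float(centers[sel][i])


def expected_latency_window(
    pooled_corr: EventCorrelation, fallback_s: tuple[float, float] = (0.0, 0.2)
) -> tuple[float, float]:
    """Latency window = contiguous post-trigger bins exceeding the upper band.

    Derived from the pooled raw correlation (with acceptance bands
    attached); when no bin exceeds the band the fallback window is used.
    """
    if pooled_corr.upper_band_hz is None:
        return fallback_s
    centers = pooled_corr.bin_centers_s
    above = (pooled_corr.rate_hz > pooled_corr.upper_band_hz) & (centers >= 0)
    if not above.any():
        return fallback_s
    idx = np.flatnonzero(above)
    # contiguous run containing the first suprathreshold bin
    run = [idx[0]]
    for j in idx[1:]:
        if j == run[-1] + 1:
            run.append(j)
        else:
            break
    half_bin = 0.5 * pooled_corr.bin_s
    return float(centers[run[0]] - half_bin), float(centers[run[-1]] + half_bin)


def compare_conditions(
    drug_pre: np.ndarray,
    drug_post: np.ndarray,
    saline_pre: np.ndarray,
    saline_post: np.ndarray,
    alpha: float = 0.05,
) -> dict:
    """Within-group pre/post paired t and between-group independent t.

    The between-group test runs on percent differences 100*(post-pre)/pre
    when all pre values are nonzero, otherwise on raw differences (flagged
    in the result).  Requires >= 2 subjects per group; otherwise the
    statistics are flagged unavailable.
    """
    out: dict = {"alpha": alpha}
    groups = {"drug": (np.asarray(drug_pre, float), np.asarray(drug_post, float)),
              "saline": (np.asarray(saline_pre, float), np.asarray(saline_post, float))}
    for name, (pre, post) in groups.items():
        if pre.size != post.size:
            raise ParameterError(f"{name}: pre/post subject counts differ")
        if pre.size < 2:
            out[name] = {"available": False, "n": int(pre.size)}
            continue
        if np.allclose(pre, post):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(post, pre)
        out[name] = {"available": True, "n": int(pre.size), "paired_t": float(t),
                     "paired_p": float(p), "mean_change": float(np.mean(post - pre))}
    dp, dq = groups["drug"]
    sp, sq = groups["saline"]
    if dp.size < 2 or sp.size < 2:
        out["between"] = {"available": False}
        return out
    use_percent = bool(np.all(dp != 0) and np.all(sp != 0))
    if use_percent:
        a = 100.0 * (dq - dp) / dp
        b = 100.0 * (sq - sp) / sp
    else:
        a, b = dq - dp, sq - sp
    if np.allclose(a.mean(), b.mean()) and np.allclose(np.concatenate([a, b]).std(), 0):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(a, b)
    out["between"] = {
        "available": True, "on": "percent_difference" if use_percent else "raw_difference",
        "t": float(t), "p": float(p),
        "drug_mean": float(a.mean()), "saline_mean": float(b.mean()),
        "significant": bool(p < alpha),
    }
    return out


def motor_metrics(
    twitches: EventSeries,
    movements_onsets: EventSeries,
    spikes: SpikeTrain,
    design: InfusionDesign,
) -> pd.DataFrame:
    """Pre/post motor and tonic-activity metrics with percent differences.

    Rows: wake movements/min, twitches/min, unit activity (Hz).  The
    percent difference uses the pre value as the reference and is NaN
    (flagged undefined) when the pre value is zero.
    """
    rows = []
    for name, series, per_min in (
        ("wake_movements_per_min", movements_onsets, True),
        ("twitches_per_min", twitches, True),
        ("unit_activity_hz", spikes, False),
    ):
        pre, post = split_events(series, design)
        scale = 60.0 if per_min else 1.0
        v_pre = scale * pre.n / design.pre_s
        v_post = scale * post.n / design.post_s
        if v_pre == 0:
            pct, defined = np.nan, False
        else:
            pct, defined = 100.0 * (v_post - v_pre) / v_pre, True
        rows.append({"metric": name, "pre": v_pre, "post": v_post,
                     "percent_difference": pct, "percent_defined": defined})
    return pd.DataFrame(rows)
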