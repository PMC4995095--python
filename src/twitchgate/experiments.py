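"""Study-level simulation experiments run on the synthetic generator.

Each function here assembles one complete in-silico experiment — null
calibration of the acceptance bands, the gating dissociation, pharmacological
unmasking, statistical-test calibration, detector fidelity, and the
motor-control null — by generating sessions, running the analysis pipeline,
and measuring the result.  The analysis drivers, the test suite, and the
acceptance script all call these functions, so a number reported anywhere is
always recomputed from scratch.
"""
from __future__ import annotations

import numpy as np

from .containers import ACTIVE_SLEEP, WAKE, BoutSegmentation, EventSeries, IntervalSeries, SpikeTrain
from .infusion import (
    InfusionDesign,
    baseline_subtracted_correlation,
    compare_conditions,
    delta_correlation,
    expected_latency_window,
    group_delta,
    motor_metrics,
    peak_change,
    split_events,
)
from .perievent import (
    ECN_SPONT,
    STIMULATION,
    CorrelationSpec,
    EventSeries as _ES,
    JitterSpec,
    band_exceedances,
    event_correlation,
    jitter_acceptance,
    peak_rate,
    stimulation_state_comparison,
)
from .scoring import ScoringConfig, detect_twitches, detect_wake_movements, paired_state_test, score_tone, state_rates
from .spindles import SpindleCriteria, bursts_to_intervals, detect_spindles
from .synth import SessionConfig, generate_emg, generate_infusion_session, generate_session, generate_spikes, sample_bouts

__all__ = [
    "band_fwer_experiment",
    "gating_dissociation_experiment",
    "unmasking_experiment",
    "state_dependency_type1",
    "stimulation_type1",
    "detector_fidelity_experiment",
    "motor_null_experiment",
]


def band_fwer_experiment(
    n_sessions: int = 500,
    seed: int = 0,
    rate_hz: float = 5.0,
    duration_s: float = 600.0,
    n_triggers: int = 100,
    spec: CorrelationSpec = ECN_SPONT,
    jspec: JitterSpec | None = None,
) -> dict:
    """Family-wise false-positive rate of the jitter acceptance bands.

    Each session draws a homogeneous Poisson spike train and triggers
    placed independently of spiking, builds the perievent correlation with
    1000 interval-jitter surrogates and simultaneous bands at the default
    level, and records whether any bin falls outside the bands.  Under the
    null this should happen in at most ``alpha`` of sessions.
    """
    jspec = jspec or JitterSpec()
    exceed = 0
    for i in range(n_sessions):
        rng = np.random.default_rng([seed, 7001, i])
        n_sp = rng.poisson(rate_hz * duration_s)
        spikes = SpikeTrain(np.sort(rng.uniform(0.0, duration_s, n_sp)))
        trig = EventSeries(
            np.sort(rng.uniform(spec.half_s, duration_s - spec.half_s, n_triggers))
        )
        corr = jitter_acceptance(spikes, trig, spec, jspec, rng, t_span=(0.0, duration_s))
        if band_exceedances(corr)["any"]:
            exceed += 1
    return {
        "fraction": exceed / n_sessions,
        "n_sessions": n_sessions,
        "n_exceed": exceed,
        "alpha": jspec.alpha,
    }


def _concatenate(sessions: list[tuple[np.ndarray, np.ndarray, float]]) -> tuple[SpikeTrain, EventSeries, float]:
    """Concatenate (spikes, triggers, duration) across subjects end to end."""
    offset, sp, tr = 0.0, [], []
    for spikes, trig, dur in sessions:
        sp.append(np.asarray(spikes) + offset)
        tr.append(np.asarray(trig) + offset)
        offset += dur
    return SpikeTrain(np.concatenate(sp)), EventSeries(np.concatenate(tr)), offset


def gating_dissociation_experiment(
    seed: int = 0,
    n_subjects: int = 3,
    duration_s: float = 1200.0,
    jspec: JitterSpec | None = None,
) -> dict:
    """Full-pipeline reproduction of the twitch/wake-movement dissociation.

    Sessions are generated with the wake gate engaged, scored from the EMG
    envelopes (tone, twitches, movements all re-detected, not read from
    ground truth), concatenated across subjects, and correlated against the
    spike train with acceptance bands.  The twitch-triggered correlation
    should exceed its upper band at the injected latency while the
    wake-movement-triggered correlation stays inside its bands.
    """
    jspec = jspec or JitterSpec()
    scfg = ScoringConfig()
    per_twitch, per_move = [], []
    for i in range(n_subjects):
        cfg = SessionConfig(duration_s=duration_s, gate_wake=True, infusion_post=False,
                            seed=int(np.random.default_rng([seed, 7100, i]).integers(2**31)))
        rec, truth = generate_session(cfg)
        bouts = score_tone(rec.signals["emg_nuchal"], scfg)
        tw = detect_twitches(rec.signals["emg_forelimb"], bouts, scfg)
        mv = detect_wake_movements(rec.signals["emg_forelimb"], bouts, scfg)
        per_twitch.append((rec.spikes.times_s, tw.times_s, duration_s))
        per_move.append((rec.spikes.times_s, mv.onsets_s, duration_s))
    spikes_t, twitches, total = _concatenate(per_twitch)
    spikes_m, moves, _ = _concatenate(per_move)
    rng = np.random.default_rng([seed, 7101])
    tw_corr = jitter_acceptance(spikes_t, twitches, ECN_SPONT, jspec, rng, t_span=(0.0, total))
    mv_corr = jitter_acceptance(spikes_m, moves, ECN_SPONT, jspec, rng, t_span=(0.0, total))
    tw_ex = band_exceedances(tw_corr)
    mv_ex = band_exceedances(mv_corr)
    centers = tw_corr.bin_centers_s
    peak_hz, lat = peak_rate(tw_corr, (0.0, ECN_SPONT.half_s))
    above_lat = [float(centers[j]) for j in tw_ex["above"]]
    return {
        "n_twitches": tw_corr.n_triggers,
        "n_movements": mv_corr.n_triggers,
        "twitch_exceeds": bool(len(tw_ex["above"]) > 0),
        "twitch_exceed_latencies_s": above_lat,
        "twitch_exceeds_at_latency": bool(any(0.01 < t <= 0.05 for t in above_lat)),
        "twitch_peak_hz": peak_hz,
        "twitch_peak_latency_s": lat,
        "movement_exceeds": bool(len(mv_ex["above"]) > 0),
    }


def unmasking_experiment(
    seed: int = 0,
    n_per_group: int = 20,
    jspec: JitterSpec | None = None,
    kernel_width_s: float = 0.05,
) -> dict:
    """Pre/post infusion delta analysis: drug releases the wake gate.

    Drug subjects carry the wake-movement kernel only post-infusion; saline
    subjects stay gated throughout.  Per subject and state the
    baseline-subtracted infusion correlations are differenced (post - pre),
    averaged within group, and the peak change extracted in the expected
    latency window derived from the pooled post-infusion raw correlation.
    The injected kernel peak rate is returned for comparison.
    """
    jspec = jspec or JitterSpec()
    design = InfusionDesign()

    def subjects(drug: bool, tag: int):
        out = []
        for i in range(n_per_group):
            cfg = SessionConfig(
                duration_s=3600.0,
                evoked_kernel_width_s=kernel_width_s,
                gate_wake=True,
                seed=int(np.random.default_rng([seed, tag, i]).integers(2**31)),
            )
            rec, truth = generate_infusion_session(cfg, drug=drug)
            out.append((rec, truth, cfg))
        return out

    drug_subj = subjects(True, 7200)
    sal_subj = subjects(False, 7201)

    def deltas(subj_list, trigger: str):
        dl, pre_pk, post_pk = [], [], []
        for rec, truth, cfg in subj_list:
            times = truth.twitch_times_s if trigger == "twitch" else truth.wake_move_intervals.onsets_s
            ev = EventSeries(times)
            pre_ev, post_ev = split_events(ev, design)
            span_pre = (0.0, design.pre_s)
            span_post = (design.pre_s, design.pre_s + design.post_s)
            c_pre = baseline_subtracted_correlation(rec.spikes, pre_ev, design, span_pre)
            c_post = baseline_subtracted_correlation(rec.spikes, post_ev, design, span_post)
            dl.append(delta_correlation(c_post, c_pre))
            pre_pk.append(c_pre)
            post_pk.append(c_post)
        return dl, pre_pk, post_pk

    result: dict = {"injected_peak_hz": float(SessionConfig().evoked_rate_hz)}
    # expected-latency window from the pooled post-infusion raw wake correlation (drug group)
    pooled = _concatenate(
        [
            (
                rec.spikes.between(design.pre_s, design.pre_s + design.post_s).times_s - design.pre_s,
                t.wake_move_intervals.onsets_s[t.wake_move_intervals.onsets_s >= design.pre_s] - design.pre_s,
                design.post_s,
            )
            for rec, t, _ in drug_subj
        ]
    )
    rng = np.random.default_rng([seed, 7202])
    pooled_corr = jitter_acceptance(pooled[0], pooled[1], design.spec, jspec, rng, t_span=(0.0, pooled[2]))
    window = expected_latency_window(pooled_corr)
    result["latency_window_s"] = window

    for state, trigger in (("wake", "wake_move"), ("sleep", "twitch")):
        drug_dl, _, _ = deltas(drug_subj, trigger)
        sal_dl, _, _ = deltas(sal_subj, trigger)
        g_drug = group_delta(drug_dl)
        g_sal = group_delta(sal_dl)
        pk_drug, lat_drug = peak_change(g_drug, window)
        pk_sal, _ = peak_change(g_sal, window)
        subj_pk_drug = np.array([peak_change(d, window)[0] for d in drug_dl])
        subj_pk_sal = np.array([peak_change(d, window)[0] for d in sal_dl])
        sem_at_peak = float(
            g_drug.sem_hz[np.argmin(np.abs(g_drug.bin_centers_s - lat_drug))]
        )
        result[state] = {
            "drug_peak_change_hz": pk_drug,
            "drug_peak_latency_s": lat_drug,
            "drug_group_sem_at_peak": sem_at_peak,
            "saline_peak_change_hz": pk_sal,
            "drug_subject_peaks": subj_pk_drug.tolist(),
            "saline_subject_peaks": subj_pk_sal.tolist(),
            "comparison": compare_conditions(
                np.zeros(n_per_group), subj_pk_drug, np.zeros(n_per_group), subj_pk_sal
            )["between"],
        }
    return result


def state_dependency_type1(
    n_sims: int = 200,
    n_subjects: int = 8,
    seed: int = 0,
    duration_s: float = 400.0,
    rate_hz: float = 5.0,
    alpha: float = 0.05,
) -> dict:
    """Type-I error of the across-subject paired t state-dependency test.

    Spiking is homogeneous Poisson, independent of state, so the sleep and
    wake per-subject mean rates differ only by sampling noise; the paired t
    test should reject at its nominal level.
    """
    cfg = SessionConfig(duration_s=duration_s)
    rejections = 0
    for s in range(n_sims):
        sleep_means, wake_means = [], []
        for j in range(n_subjects):
            rng = np.random.default_rng([seed, 7300, s, j])
            bouts = sample_bouts(cfg, rng)
            n_sp = rng.poisson(rate_hz * duration_s)
            spikes = EventSeries(np.sort(rng.uniform(0.0, duration_s, n_sp)))
            _, summary = state_rates(spikes, bouts, min_pairs=10**9)
            sleep_means.append(summary[ACTIVE_SLEEP]["pooled_rate_hz"])
            wake_means.append(summary[WAKE]["pooled_rate_hz"])
        res = paired_state_test(np.array(sleep_means), np.array(wake_means))
        if res["p"] < alpha:
            rejections += 1
    return {"rejection_rate": rejections / n_sims, "n_sims": n_sims, "alpha": alpha}


def stimulation_type1(
    n_sims: int = 200,
    n_subjects: int = 6,
    seed: int = 0,
    duration_s: float = 600.0,
    stim_rate_hz: float = 0.15,
    alpha: float = 0.05,
    sleep_gain: float = 1.0,
) -> dict:
    """Calibration (or power, with ``sleep_gain`` != 1) of the stimulation
    state comparison.

    Each subject receives stimulations in both states with a
    state-independent evoked kernel; ``sleep_gain`` scales the kernel for
    sleep-state stimulations to simulate a true state effect.
    """
    rejections, used = 0, 0
    for s in range(n_sims):
        sessions = []
        for j in range(n_subjects):
            rng = np.random.default_rng([seed, 7400, s, j])
            cfg = SessionConfig(duration_s=duration_s, seed=0)
            bouts = sample_bouts(cfg, rng)
            n_stim = rng.poisson(stim_rate_hz * duration_s)
            stim = np.sort(rng.uniform(0.3, duration_s - 0.3, n_stim))
            states = bouts.state_at(stim)
            stim_sleep = stim[states == ACTIVE_SLEEP]
            stim_wake = stim[states == WAKE]
            amps = {"stim_sleep": cfg.evoked_rate_hz * sleep_gain, "stim_wake": cfg.evoked_rate_hz}
            spikes = generate_spikes(
                {"stim_sleep": stim_sleep, "stim_wake": stim_wake}, cfg, rng, amplitudes=amps
            )
            sessions.append((spikes, EventSeries(stim), bouts))
        res = stimulation_state_comparison(sessions, STIMULATION)
        if res["paired_t"] is None:
            continue
        used += 1
        if res["paired_t"]["p"] < alpha:
            rejections += 1
    return {"rejection_rate": rejections / max(used, 1), "n_sims": used, "alpha": alpha}


def _interval_recall_precision(truth: IntervalSeries, detected: IntervalSeries) -> tuple[float, float]:
    def overlaps(a_on, a_off, b: IntervalSeries) -> bool:
        return bool(np.any((b.onsets_s < a_off) & (b.offsets_s > a_on)))

    if truth.n == 0:
        return float("nan"), float("nan")
    hit = sum(overlaps(on, off, detected) for on, off, _ in truth)
    recall = hit / truth.n
    if detected.n == 0:
        return recall, float("nan")
    ok = sum(overlaps(on, off, truth) for on, off, _ in detected)
    precision = ok / detected.n
    return recall, precision


def detector_fidelity_experiment(seed: int = 0) -> dict:
    """Round-trip fidelity of the twitch, wake-movement, and spindle detectors."""
    scfg = ScoringConfig()
    out: dict = {}

    # spindles at SNR 10 with >= 20 injected bursts
    cfg = SessionConfig(duration_s=900.0, spindle_rate_hz=0.1, spindle_amp=10.0, noise_sd=1.0, seed=seed)
    rec, truth = generate_session(cfg)
    bursts = detect_spindles(rec.signals["lfp"], SpindleCriteria())
    det = bursts_to_intervals(bursts)
    recall, precision = _interval_recall_precision(truth.spindle_intervals, det)
    out["spindle"] = {
        "n_injected": int(truth.spindle_intervals.n),
        "n_detected": int(det.n),
        "recall": recall,
        "precision": precision,
    }

    # twitches: recall at amplitude gain 3.5, zero detections at gain 2
    for gain, key in ((3.5, "twitch_gain_3.5"), (2.0, "twitch_gain_2.0")):
        cfg = SessionConfig(duration_s=600.0, twitch_amp_gain=gain, seed=seed + 1)
        rec, truth = generate_session(cfg)
        bouts = score_tone(rec.signals["emg_nuchal"], scfg)
        det_tw = detect_twitches(rec.signals["emg_forelimb"], bouts, scfg)
        if truth.twitch_times_s.size and det_tw.n:
            d = np.abs(truth.twitch_times_s[:, None] - det_tw.times_s[None, :])
            matched = int(np.sum(d.min(axis=1) <= 0.025))
        else:
            matched = 0
        out[key] = {
            "n_injected": int(truth.twitch_times_s.size),
            "n_detected": int(det_tw.n),
            "recall_25ms": matched / truth.twitch_times_s.size if truth.twitch_times_s.size else float("nan"),
        }

    # wake movements: the 300 ms rule excludes injected sub-300 ms bursts
    cfg = SessionConfig(duration_s=300.0, seed=seed + 2, wake_move_rate_hz=0.0, emg_noise_sd=0.02)
    rng = np.random.default_rng([seed, 7500])
    bouts_iv = IntervalSeries([0.0, 100.0, 200.0], [100.0, 200.0, 300.0],
                              [WAKE, ACTIVE_SLEEP, WAKE], name="bouts")
    bouts = BoutSegmentation(bouts_iv)
    short_on = np.arange(5.0, 50.0, 9.0)
    long_on = np.arange(55.0, 95.0, 8.0) + 150.0  # in the second wake bout
    movements = IntervalSeries(
        np.concatenate([short_on, long_on]),
        np.concatenate([short_on + 0.2, long_on + 0.45]),
    )
    env = generate_emg(bouts, np.empty(0), movements, cfg, rng, label="emg_forelimb")
    det_mv = detect_wake_movements(env, bouts, scfg)
    short_hit = sum(
        bool(np.any((det_mv.onsets_s < on + 0.2) & (det_mv.offsets_s > on))) for on in short_on
    )
    long_hit = sum(
        bool(np.any((det_mv.onsets_s < on + 0.45) & (det_mv.offsets_s > on))) for on in long_on
    )
    out["wake_movement"] = {
        "n_short_injected": int(short_on.size),
        "n_short_detected": int(short_hit),
        "n_long_injected": int(long_on.size),
        "n_long_detected": int(long_hit),
        "min_detected_duration_s": float(det_mv.durations_s.min()) if det_mv.n else float("nan"),
    }
    return out


def motor_null_experiment(seed: int = 0, n_per_group: int = 8) -> dict:
    """Motor-metric control: gating-only infusions leave motor output unchanged.

    Generates drug and saline infusion sessions in which only the
    wake-movement kernel amplitude changes post-infusion, computes the
    motor metrics pre and post, and summarizes the percent differences,
    which should be statistically indistinguishable from zero.
    """
    design = InfusionDesign(pre_s=900.0, post_s=900.0)
    metrics = ("wake_movements_per_min", "twitches_per_min", "unit_activity_hz")
    pct: dict[str, dict[str, list[float]]] = {g: {m: [] for m in metrics} for g in ("drug", "saline")}
    pre_post: dict[str, dict[str, list[tuple[float, float]]]] = {
        g: {m: [] for m in metrics} for g in ("drug", "saline")
    }
    for group, drug, tag in (("drug", True, 7600), ("saline", False, 7601)):
        for i in range(n_per_group):
            cfg = SessionConfig(
                duration_s=1800.0,
                seed=int(np.random.default_rng([seed, tag, i]).integers(2**31)),
            )
            rec, truth = generate_infusion_session(cfg, drug=drug, pre_s=900.0, post_s=900.0)
            table = motor_metrics(
                EventSeries(truth.twitch_times_s),
                EventSeries(truth.wake_move_intervals.onsets_s),
                rec.spikes,
                design,
            )
            for _, row in table.iterrows():
                pct[group][row.metric].append(row.percent_difference)
                pre_post[group][row.metric].append((row.pre, row.post))
    out: dict = {}
    for m in metrics:
        entry: dict = {}
        for g in ("drug", "saline"):
            a = np.array(pct[g][m], float)
            a = a[np.isfinite(a)]
            entry[g] = {
                "mean_pct": float(a.mean()),
                "sem_pct": float(a.std(ddof=1) / np.sqrt(a.size)),
                "n": int(a.size),
            }
        dpre, dpost = map(np.array, zip(*pre_post["drug"][m]))
        spre, spost = map(np.array, zip(*pre_post["saline"][m]))
        entry["comparison"] = compare_conditions(dpre, dpost, spre, spost)
        out[m] = entry
    return out
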