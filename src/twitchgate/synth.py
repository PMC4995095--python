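"""Synthetic recording sessions with known ground truth.

The generator emulates the statistical structure of a head-fixed neonatal rat
recording: alternating wake (high nuchal tone) and active-sleep (atonia)
bouts; myoclonic twitches as point events confined to atonia; wake movements
as long (>= 300 ms) high-amplitude EMG bursts confined to high tone; cortical
spindle bursts (10-15 Hz oscillations) confined to active sleep; and a spike
train realized as an inhomogeneous Poisson process — homogeneous background
plus a Gaussian-in-time evoked-rate kernel after each trigger event.

Sensory gating is modeled as a single switch: when ``gate_wake`` is set and
``infusion_post`` is not, the wake-movement kernel amplitude is zero (the
reafference from self-generated wake movements is blocked), while twitch and
stimulation kernels are unaffected.  Setting ``infusion_post`` releases the
gate, emulating disinhibition of the recorded nucleus.

EMG channels are synthesized directly as rectified envelopes (baseline units
are arbitrary); the analysis path treats them exactly like envelopes computed
from real rectified EMG.  All randomness flows from ``SessionConfig.seed``
through fixed per-channel substreams, so sessions are bit-identical across
runs and channels can be regenerated independently.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .containers import (
    ACTIVE_SLEEP,
    WAKE,
    BoutSegmentation,
    ContinuousSignal,
    EventSeries,
    IntervalSeries,
    Recording,
    SpikeTrain,
)
from .errors import ConfigError, ConsistencyError

__all__ = [
    "SessionConfig",
    "SessionGroundTruth",
    "generate_session",
    "generate_infusion_session",
    "sample_bouts",
    "generate_emg",
    "generate_spikes",
    "generate_lfp",
]

# Fixed substream offsets (master seed + offset -> independent Generator).
_STREAMS = {
    "bouts": 1,
    "twitch": 2,
    "move": 3,
    "spindle": 4,
    "emg_nuchal": 5,
    "emg_forelimb": 6,
    "emg_hindlimb": 7,
    "lfp": 8,
    "spikes": 9,
}

TRIGGER_CLASSES = ("twitch", "wake_move", "stimulation")


@dataclass
class SessionConfig:
    """Generative parameters of one synthetic session.

    Rates are per second of time spent in the relevant state; EMG amplitudes
    are in arbitrary envelope units relative to ``emg_baseline``.
    """

    duration_s: float = 600.0
    emg_rate_hz: float = 1000.0
    neural_rate_hz: float = 2500.0  # desk-scale LFP rate
    bout_mean_wake_s: float = 40.0
    bout_mean_sleep_s: float = 40.0
    min_bout_s: float = 10.0
    twitch_rate_hz: float = 0.5
    wake_move_rate_hz: float = 0.05
    wake_move_dur_s: float = 0.5  # mean; durations are >= 0.35 s
    emg_baseline: float = 1.0
    emg_tone_gain: float = 5.0
    twitch_amp_gain: float = 5.0
    wake_move_amp_gain: float = 12.0
    emg_noise_sd: float = 0.05  # fraction of baseline
    spike_background_hz: float = 5.0
    evoked_latency_s: float = 0.02
    evoked_kernel_width_s: float = 0.01
    evoked_rate_hz: float = 50.0
    gate_wake: bool = True
    infusion_post: bool = False
    stim_times_s: list[float] | None = None
    spindle_rate_hz: float = 0.1
    spindle_freq_hz: float = 12.0
    spindle_dur_s: float = 0.5  # mean; drawn uniform within +-20%
    spindle_amp: float = 10.0
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.duration_s <= 0:
            raise ConfigError(f"duration_s must be > 0, got {self.duration_s}")
        for name in (
            "emg_rate_hz",
            "neural_rate_hz",
            "bout_mean_wake_s",
            "bout_mean_sleep_s",
            "min_bout_s",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in (
            "twitch_rate_hz",
            "wake_move_rate_hz",
            "spike_background_hz",
            "evoked_rate_hz",
            "spindle_rate_hz",
            "noise_sd",
            "emg_noise_sd",
            "spindle_amp",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.bout_mean_wake_s <= self.min_bout_s or self.bout_mean_sleep_s <= self.min_bout_s:
            raise ConfigError("bout_mean_wake_s/bout_mean_sleep_s must exceed min_bout_s")
        if self.emg_baseline <= 0:
            raise ConfigError(f"emg_baseline must be > 0, got {self.emg_baseline}")
        if self.emg_tone_gain <= 1:
            raise ConfigError(f"emg_tone_gain must be > 1, got {self.emg_tone_gain}")
        if self.twitch_amp_gain <= 0:
            raise ConfigError(f"twitch_amp_gain must be > 0, got {self.twitch_amp_gain}")
        if self.wake_move_dur_s < 0.3:
            raise ConfigError(f"wake_move_dur_s must be >= 0.3, got {self.wake_move_dur_s}")
        if self.evoked_kernel_width_s <= 0:
            raise ConfigError(f"evoked_kernel_width_s must be > 0, got {self.evoked_kernel_width_s}")
        if not (0 < self.spindle_freq_hz < self.neural_rate_hz / 2):
            raise ConfigError(
                f"spindle_freq_hz must lie in (0, neural_rate_hz/2), got {self.spindle_freq_hz}"
            )
        if self.spindle_dur_s < 0.1:
            raise ConfigError(f"spindle_dur_s must be >= 0.1, got {self.spindle_dur_s}")
        if self.stim_times_s is not None:
            st = np.asarray(self.stim_times_s, dtype=float)
            if st.size and (np.any(np.diff(st) < 0) or st.min() < 0 or st.max() > self.duration_s):
                raise ConfigError("stim_times_s must be sorted and within [0, duration_s]")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STREAMS[stream]])

    def evoked_amplitudes(self) -> dict[str, float]:
        gated = self.gate_wake and not self.infusion_post
        return {
            "twitch": self.evoked_rate_hz,
            "wake_move": 0.0 if gated else self.evoked_rate_hz,
            "stimulation": self.evoked_rate_hz,
        }


@dataclass
class SessionGroundTruth:
    """Generator-side record of everything injected; the oracle in tests."""

    bouts: BoutSegmentation
    twitch_times_s: np.ndarray
    wake_move_intervals: IntervalSeries
    spindle_intervals: IntervalSeries
    stim_times_s: np.ndarray
    evoked: dict[str, dict] = field(default_factory=dict)

    def check(self) -> None:
        sleep = self.bouts.for_state(ACTIVE_SLEEP)
        wake = self.bouts.for_state(WAKE)
        if self.twitch_times_s.size and not sleep.contains(self.twitch_times_s).all():
            raise ConsistencyError("a twitch lies outside active-sleep bouts")
        for on, off, _ in self.wake_move_intervals:
            if not (wake.contains([on]).all() and wake.contains([off - 1e-9]).all()):
                raise ConsistencyError("a wake movement lies outside wake bouts")
        for on, off, _ in self.spindle_intervals:
            if not (sleep.contains([on]).all() and sleep.contains([off - 1e-9]).all()):
                raise ConsistencyError("a spindle burst lies outside active-sleep bouts")


def sample_bouts(config: SessionConfig, rng: np.random.Generator) -> BoutSegmentation:
    """Alternating wake/sleep bouts; durations are ``min_bout + Exp(mean - min_bout)``.

    The truncated-exponential draw keeps the configured mean while enforcing
    the minimum bout length; the final bout is clipped at the session end.
    """
    means = {WAKE: config.bout_mean_wake_s, ACTIVE_SLEEP: config.bout_mean_sleep_s}
    state = WAKE if rng.random() < 0.5 else ACTIVE_SLEEP
    t, onsets, offsets, labels = 0.0, [], [], []
    while t < config.duration_s:
        dur = config.min_bout_s + rng.exponential(means[state] - config.min_bout_s)
        end = min(t + dur, config.duration_s)
        onsets.append(t)
        offsets.append(end)
        labels.append(state)
        t = end
        state = ACTIVE_SLEEP if state == WAKE else WAKE
    return BoutSegmentation(IntervalSeries(onsets, offsets, labels, name="bouts"))


def _poisson_times_in_intervals(
    intervals: IntervalSeries,
    rate_hz: float,
    rng: np.random.Generator,
    margin_s: float = 0.1,
    min_gap_s: float = 0.0,
) -> np.ndarray:
    """Homogeneous Poisson point events inside each interval, kept off the edges."""
    out: list[float] = []
    for on, off, _ in intervals:
        lo, hi = on + margin_s, off - margin_s
        if hi <= lo:
            continue
        n = rng.poisson(rate_hz * (hi - lo))
        out.extend(np.sort(rng.uniform(lo, hi, n)))
    times = np.array(sorted(out))
    if min_gap_s > 0 and times.size:
        keep = [0]
        for i in range(1, times.size):
            if times[i] - times[keep[-1]] >= min_gap_s:
                keep.append(i)
        times = times[keep]
    return times


def _sample_interval_events(
    host: IntervalSeries,
    rate_hz: float,
    dur_sampler,
    rng: np.random.Generator,
    margin_s: float = 0.05,
    min_gap_s: float = 0.2,
) -> IntervalSeries:
    """Non-overlapping sub-intervals (movements, spindles) inside host intervals."""
    onsets: list[float] = []
    offsets: list[float] = []
    for on, off, _ in host:
        lo, hi = on + margin_s, off - margin_s
        if hi <= lo:
            continue
        n = rng.poisson(rate_hz * (hi - lo))
        starts = np.sort(rng.uniform(lo, hi, n))
        durs = np.array([dur_sampler(rng) for _ in range(n)])
        last_end = -np.inf
        for s, d in zip(starts, durs):
            e = s + d
            if s - last_end < min_gap_s or e > hi:
                continue
            onsets.append(s)
            offsets.append(e)
            last_end = e
    if not onsets:
        return IntervalSeries(np.empty(0), np.empty(0))
    return IntervalSeries(onsets, offsets)


def generate_emg(
    bouts: BoutSegmentation,
    twitches: np.ndarray,
    movements: IntervalSeries,
    config: SessionConfig,
    rng: np.random.Generator,
    label: str = "emg",
) -> ContinuousSignal:
    """Rectified-envelope EMG: tone steps + twitch bumps + movement plateaus.

    Twitches are 50 ms raised-cosine bumps peaking at ``twitch_amp_gain x
    baseline``; movements are plateaus at ``wake_move_amp_gain x baseline``
    with 20 ms ramps inside the interval.  Raises ``ConsistencyError`` if an
    event is scheduled in the wrong state.
    """
    twitches = np.asarray(twitches, dtype=float)
    if twitches.size:
        states = bouts.state_at(twitches)
        if np.any(states != ACTIVE_SLEEP):
            raise ConsistencyError("twitch scheduled inside a wake bout")
    if movements.n:
        wake_iv = bouts.for_state(WAKE)
        if not wake_iv.contains(movements.onsets_s).all():
            raise ConsistencyError("wake movement scheduled inside a sleep bout")

    fs = config.emg_rate_hz
    n = int(round(config.duration_s * fs))
    t = np.arange(n) / fs
    base = config.emg_baseline
    env = np.full(n, base)
    for on, off, lab in bouts.intervals:
        if lab == WAKE:
            i0, i1 = int(np.ceil(on * fs)), int(np.ceil(off * fs))
            env[i0:i1] = base * config.emg_tone_gain

    half = 0.025  # 50 ms raised-cosine bump
    for tc in twitches:
        i0, i1 = int(np.ceil((tc - half) * fs)), int(np.floor((tc + half) * fs)) + 1
        i0, i1 = max(i0, 0), min(i1, n)
        bump = 0.5 * (1 + np.cos(np.pi * (t[i0:i1] - tc) / half))
        env[i0:i1] += (config.twitch_amp_gain - 1.0) * base * bump

    ramp = 0.02
    amp = config.wake_move_amp_gain * base
    for on, off, _ in movements:
        i0, i1 = int(np.ceil(on * fs)), int(np.floor(off * fs)) + 1
        i0, i1 = max(i0, 0), min(i1, n)
        seg_t = t[i0:i1]
        shape = np.minimum(
            np.clip((seg_t - on) / ramp, 0, 1), np.clip((off - seg_t) / ramp, 0, 1)
        )
        env[i0:i1] = np.maximum(env[i0:i1], base + (amp - base) * shape)

    if config.emg_noise_sd > 0:
        env = env + rng.normal(0.0, config.emg_noise_sd * base, n)
        env = np.maximum(env, 0.0)
    return ContinuousSignal(env, fs, label=label, units="a.u.")


def generate_spikes(
    triggers_by_class: dict[str, np.ndarray],
    config: SessionConfig,
    rng: np.random.Generator,
    amplitudes: dict[str, float] | None = None,
) -> SpikeTrain:
    """Inhomogeneous-Poisson spike train: background + evoked Gaussian kernels.

    The rate is ``background + sum_k A_k * exp(-(t - t_k - latency)^2 / 2w^2)``
    over triggers ``t_k``; it is simulated exactly by superposition (each
    kernel contributes ``Poisson(A_k * w * sqrt(2*pi))`` spikes at
    ``Normal(t_k + latency, w)``).  Default amplitudes implement the gating
    rule: the wake-movement kernel is zero while the gate is engaged, the
    stimulation kernel is state-independent.
    """
    if amplitudes is None:
        bad = set(triggers_by_class) - set(TRIGGER_CLASSES)
        if bad:
            raise ConfigError(f"unknown trigger classes {sorted(bad)}")
        amplitudes = config.evoked_amplitudes()
    for cls, a in amplitudes.items():
        if a < 0:
            raise ConfigError(f"evoked amplitude for {cls!r} is negative ({a}): rate would be negative")

    T = config.duration_s
    n_bg = rng.poisson(config.spike_background_hz * T)
    times = [rng.uniform(0.0, T, n_bg)]
    w = config.evoked_kernel_width_s
    lam_per_trigger = np.sqrt(2 * np.pi) * w  # integral of a unit-amplitude kernel
    for cls in sorted(triggers_by_class):
        trig = np.asarray(triggers_by_class[cls], dtype=float)
        a = amplitudes.get(cls, 0.0)
        if a == 0.0 or trig.size == 0:
            continue
        counts = rng.poisson(a * lam_per_trigger, trig.size)
        centers = np.repeat(trig + config.evoked_latency_s, counts)
        ev = rng.normal(centers, w)
        times.append(ev[(ev >= 0) & (ev < T)])
    allt = np.sort(np.concatenate(times))
    return SpikeTrain(allt, label="spikes")


def generate_lfp(
    spindle_intervals: IntervalSeries,
    config: SessionConfig,
    rng: np.random.Generator,
) -> ContinuousSignal:
    """LFP = 1/f-shaped noise + amplitude-modulated sinusoids in each interval.

    Bursts use a Tukey taper whose cosine lobes span ~100 ms, so the burst
    sits at full amplitude over most of its interval (keeping the detectable
    duration close to the injected one).
    """
    if not (0 < config.spindle_freq_hz < config.neural_rate_hz / 2):
        raise ConfigError(
            f"spindle_freq_hz {config.spindle_freq_hz} outside (0, {config.neural_rate_hz / 2})"
        )
    fs = config.neural_rate_hz
    n = int(round(config.duration_s * fs))
    t = np.arange(n) / fs
    if config.noise_sd > 0:
        white = rng.standard_normal(n)
        spec = np.fft.rfft(white)
        freqs = np.fft.rfftfreq(n, d=1.0 / fs)
        spec /= np.sqrt(np.maximum(freqs, 1.0))  # 1/f power shaping above 1 Hz
        x = np.fft.irfft(spec, n)
        x *= config.noise_sd / x.std()
    else:
        x = np.zeros(n)

    from scipy.signal.windows import tukey

    for on, off, _ in spindle_intervals:
        i0, i1 = int(np.ceil(on * fs)), int(np.floor(off * fs)) + 1
        i0, i1 = max(i0, 0), min(i1, n)
        m = i1 - i0
        if m < 2:
            continue
        dur = m / fs
        alpha = min(1.0, 0.1 / dur)
        phase = rng.uniform(0, 2 * np.pi)
        burst = config.spindle_amp * tukey(m, alpha) * np.sin(
            2 * np.pi * config.spindle_freq_hz * (t[i0:i1] - on) + phase
        )
        x[i0:i1] += burst
    return ContinuousSignal(x, fs, label="lfp", units="a.u.")


def generate_session(config: SessionConfig) -> tuple[Recording, SessionGroundTruth]:
    """Generate a complete session (EMG channels, LFP, spikes) plus ground truth.

    Deterministic given ``config.seed``; all ground-truth invariants are
    asserted before returning.
    """
    config.validate()
    bouts = sample_bouts(config, config.rng("bouts"))
    sleep = bouts.for_state(ACTIVE_SLEEP)
    wake = bouts.for_state(WAKE)
    twitches = _poisson_times_in_intervals(
        sleep, config.twitch_rate_hz, config.rng("twitch"), margin_s=0.1, min_gap_s=0.2
    )

    def move_dur(r: np.random.Generator) -> float:
        return 0.35 + r.exponential(max(config.wake_move_dur_s - 0.35, 1e-3))

    movements = _sample_interval_events(
        wake, config.wake_move_rate_hz, move_dur, config.rng("move"), min_gap_s=0.3
    )

    def spindle_dur(r: np.random.Generator) -> float:
        return config.spindle_dur_s * r.uniform(0.8, 1.2)

    spindles = _sample_interval_events(
        sleep, config.spindle_rate_hz, spindle_dur, config.rng("spindle"), min_gap_s=0.2
    )

    nuchal = generate_emg(
        bouts, np.empty(0), IntervalSeries(np.empty(0), np.empty(0)), config,
        config.rng("emg_nuchal"), label="emg_nuchal",
    )
    forelimb = generate_emg(
        bouts, twitches, movements, config, config.rng("emg_forelimb"), label="emg_forelimb"
    )
    hindlimb = generate_emg(
        bouts, np.empty(0), IntervalSeries(np.empty(0), np.empty(0)), config,
        config.rng("emg_hindlimb"), label="emg_hindlimb",
    )
    lfp = generate_lfp(spindles, config, config.rng("lfp"))

    stim = np.asarray(config.stim_times_s if config.stim_times_s is not None else [], dtype=float)
    triggers = {"twitch": twitches, "wake_move": movements.onsets_s, "stimulation": stim}
    spikes = generate_spikes(triggers, config, config.rng("spikes"))

    amps = config.evoked_amplitudes()
    truth = SessionGroundTruth(
        bouts=bouts,
        twitch_times_s=twitches,
        wake_move_intervals=movements,
        spindle_intervals=spindles,
        stim_times_s=stim,
        evoked={
            cls: {
                "latency_s": config.evoked_latency_s,
                "width_s": config.evoked_kernel_width_s,
                "peak_rate_hz": amps[cls],
            }
            for cls in TRIGGER_CLASSES
        },
    )
    truth.check()
    rec = Recording(
        signals={"emg_nuchal": nuchal, "emg_forelimb": forelimb, "emg_hindlimb": hindlimb, "lfp": lfp},
        spikes=spikes,
        stim=EventSeries(stim, label="stimulation") if stim.size else None,
        duration_s=config.duration_s,
        meta={"config": asdict(config)},
    )
    return rec, truth


def generate_infusion_session(
    config: SessionConfig, drug: bool, pre_s: float = 1800.0, post_s: float = 1800.0
) -> tuple[Recording, SessionGroundTruth]:
    """A pre/post infusion session in one recording.

    The pre epoch is ``[0, pre_s)``, the post epoch ``[pre_s, pre_s+post_s)``.
    Motor statistics are identical across epochs by construction; the only
    epoch difference is the wake-movement kernel amplitude, which switches
    from gated (0) to released for the drug group.  Saline sessions are
    statistically identical pre and post.
    """
    config.validate()
    if config.duration_s < pre_s + post_s:
        raise ConfigError(
            f"duration_s={config.duration_s} shorter than pre+post={pre_s + post_s}"
        )
    base_gate = config.gate_wake
    a = config.evoked_rate_hz
    pre_amp = 0.0 if base_gate else a
    post_amp = a if drug else pre_amp

    bouts = sample_bouts(config, config.rng("bouts"))
    sleep, wake = bouts.for_state(ACTIVE_SLEEP), bouts.for_state(WAKE)
    twitches = _poisson_times_in_intervals(
        sleep, config.twitch_rate_hz, config.rng("twitch"), margin_s=0.1, min_gap_s=0.2
    )

    def move_dur(r: np.random.Generator) -> float:
        return 0.35 + r.exponential(max(config.wake_move_dur_s - 0.35, 1e-3))

    movements = _sample_interval_events(
        wake, config.wake_move_rate_hz, move_dur, config.rng("move"), min_gap_s=0.3
    )
    onsets = movements.onsets_s
    spikes = generate_spikes(
        {
            "twitch": twitches,
            "wake_move_pre": onsets[onsets < pre_s],
            "wake_move_post": onsets[onsets >= pre_s],
        },
        config,
        config.rng("spikes"),
        amplitudes={"twitch": a, "wake_move_pre": pre_amp, "wake_move_post": post_amp},
    )
    spindles = IntervalSeries(np.empty(0), np.empty(0))
    truth = SessionGroundTruth(
        bouts=bouts,
        twitch_times_s=twitches,
        wake_move_intervals=movements,
        spindle_intervals=spindles,
        stim_times_s=np.empty(0),
        evoked={
            "twitch": {"latency_s": config.evoked_latency_s, "width_s": config.evoked_kernel_width_s, "peak_rate_hz": a},
            "wake_move_pre": {"latency_s": config.evoked_latency_s, "width_s": config.evoked_kernel_width_s, "peak_rate_hz": pre_amp},
            "wake_move_post": {"latency_s": config.evoked_latency_s, "width_s": config.evoked_kernel_width_s, "peak_rate_hz": post_amp},
        },
    )
    truth.check()
    rec = Recording(
        signals={},
        spikes=spikes,
        stim=None,
        duration_s=config.duration_s,
        meta={"config": asdict(config), "group": "drug" if drug else "saline", "pre_s": pre_s, "post_s": post_s},
    )
    return rec, truth
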