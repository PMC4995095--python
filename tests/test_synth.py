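"""Synthetic-session generator: determinism, ground-truth invariants, and
agreement of the spike process with its injected rate function."""
import numpy as np
import pytest
from scipy.stats import norm

from twitchgate.containers import ACTIVE_SLEEP, WAKE, BoutSegmentation, IntervalSeries
from twitchgate.errors import ConfigError, ConsistencyError
from twitchgate.synth import (
    SessionConfig,
    generate_emg,
    generate_infusion_session,
    generate_session,
    generate_spikes,
    generate_lfp,
    sample_bouts,
)


def _expected_window_count(cfg, t_lo, t_hi):
    """Independent oracle: integral of the injected rate over a post-trigger window.

    background*width + A*w*sqrt(2*pi)*(Phi((t_hi-lat)/w) - Phi((t_lo-lat)/w)).
    """
    a = cfg.evoked_rate_hz
    w = cfg.evoked_kernel_width_s
    lat = cfg.evoked_latency_s
    bg = cfg.spike_background_hz * (t_hi - t_lo)
    ev = a * w * np.sqrt(2 * np.pi) * (norm.cdf((t_hi - lat) / w) - norm.cdf((t_lo - lat) / w))
    return bg + ev


class TestConfig:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("duration_s", -1.0),
            ("twitch_rate_hz", -0.1),
            ("emg_tone_gain", 0.5),
            ("wake_move_dur_s", 0.2),
            ("spindle_freq_hz", 2000.0),
            ("spindle_dur_s", 0.05),
        ],
    )
    def test_invalid_config_names_field(self, field, value):
        cfg = SessionConfig(**{field: value})
        with pytest.raises(ConfigError, match=field):
            cfg.validate()


class TestDeterminismAndInvariants:
    def test_same_seed_bit_identical(self):
        a_rec, a_truth = generate_session(SessionConfig(duration_s=120.0, seed=5))
        b_rec, b_truth = generate_session(SessionConfig(duration_s=120.0, seed=5))
        for k in a_rec.signals:
            assert np.array_equal(a_rec.signals[k].samples, b_rec.signals[k].samples)
        assert np.array_equal(a_rec.spikes.times_s, b_rec.spikes.times_s)
        assert np.array_equal(a_truth.twitch_times_s, b_truth.twitch_times_s)

    def test_different_seed_differs(self):
        a, _ = generate_session(SessionConfig(duration_s=120.0, seed=5))
        b, _ = generate_session(SessionConfig(duration_s=120.0, seed=6))
        assert not np.array_equal(a.spikes.times_s, b.spikes.times_s)

    def test_ground_truth_state_consistency(self, small_session):
        _, _, truth = small_session
        truth.check()  # raises on violation
        sleep = truth.bouts.for_state(ACTIVE_SLEEP)
        assert sleep.contains(truth.twitch_times_s).all()

    def test_bouts_partition_and_respect_minimum(self):
        cfg = SessionConfig(duration_s=500.0, seed=2)
        bouts = sample_bouts(cfg, cfg.rng("bouts"))
        iv = bouts.intervals
        assert iv.onsets_s[0] == 0.0 and iv.offsets_s[-1] == 500.0
        assert np.allclose(iv.onsets_s[1:], iv.offsets_s[:-1])
        assert (iv.durations_s[:-1] >= cfg.min_bout_s).all()  # last one may be clipped
        assert all(a != b for a, b in zip(iv.labels[:-1], iv.labels[1:]))


class TestNullSession:
    def test_event_free_session_is_baseline_plus_poisson(self):
        cfg = SessionConfig(
            duration_s=400.0, twitch_rate_hz=0.0, wake_move_rate_hz=0.0,
            spindle_rate_hz=0.0, emg_noise_sd=0.0, seed=9,
        )
        rec, truth = generate_session(cfg)
        env = rec.signals["emg_forelimb"]
        sleep_mask = truth.bouts.for_state(ACTIVE_SLEEP).contains(env.times())
        assert np.allclose(env.samples[sleep_mask], cfg.emg_baseline)
        # homogeneous Poisson: empirical rate within 3 SE of nominal
        lam = cfg.spike_background_hz * cfg.duration_s
        assert abs(rec.spikes.n - lam) < 3 * np.sqrt(lam)

    def test_noise_free_lfp_without_bursts_is_zero(self):
        cfg = SessionConfig(duration_s=60.0, noise_sd=0.0, seed=1)
        lfp = generate_lfp(IntervalSeries(np.empty(0), np.empty(0)), cfg, cfg.rng("lfp"))
        assert np.all(lfp.samples == 0)


class TestEmg:
    def _simple_bouts(self):
        return BoutSegmentation(
            IntervalSeries([0.0, 30.0], [30.0, 60.0], [ACTIVE_SLEEP, WAKE])
        )

    def test_noise_free_envelope_piecewise_two_valued(self):
        cfg = SessionConfig(duration_s=60.0, emg_noise_sd=0.0)
        env = generate_emg(
            self._simple_bouts(), np.empty(0), IntervalSeries(np.empty(0), np.empty(0)),
            cfg, np.random.default_rng(0),
        )
        vals = np.unique(env.samples)
        assert np.allclose(sorted(vals), [cfg.emg_baseline, cfg.emg_baseline * cfg.emg_tone_gain])

    def test_twitch_peak_reaches_gain_times_baseline(self):
        cfg = SessionConfig(duration_s=60.0, emg_noise_sd=0.0, twitch_amp_gain=3.5)
        env = generate_emg(
            self._simple_bouts(), np.array([15.0]), IntervalSeries(np.empty(0), np.empty(0)),
            cfg, np.random.default_rng(0),
        )
        sleep_part = env.samples[: int(30.0 * env.rate_hz)]
        assert sleep_part.max() == pytest.approx(3.5 * cfg.emg_baseline, rel=1e-3)

    def test_event_in_wrong_state_raises(self):
        cfg = SessionConfig(duration_s=60.0)
        with pytest.raises(ConsistencyError):
            generate_emg(
                self._simple_bouts(), np.array([45.0]),  # twitch inside the wake bout
                IntervalSeries(np.empty(0), np.empty(0)), cfg, np.random.default_rng(0),
            )


class TestSpikes:
    def test_background_only_count_within_3se(self):
        cfg = SessionConfig(duration_s=100.0, spike_background_hz=5.0)
        train = generate_spikes({}, cfg, np.random.default_rng(3))
        assert abs(train.n - 500) < 3 * np.sqrt(500)

    def test_unknown_trigger_class_rejected(self):
        cfg = SessionConfig()
        with pytest.raises(ConfigError):
            generate_spikes({"licking": np.array([1.0])}, cfg, np.random.default_rng(0))

    def test_negative_amplitude_rejected(self):
        cfg = SessionConfig()
        with pytest.raises(ConfigError):
            generate_spikes(
                {"twitch": np.array([1.0])}, cfg, np.random.default_rng(0),
                amplitudes={"twitch": -1.0},
            )

    def test_gated_wake_kernel_flat_and_released_by_infusion_flag(self):
        trig = np.arange(5.0, 595.0, 3.0)
        for post, expect_peak in ((False, False), (True, True)):
            cfg = SessionConfig(
                duration_s=600.0, gate_wake=True, infusion_post=post,
                spike_background_hz=2.0, seed=4,
            )
            train = generate_spikes({"wake_move": trig}, cfg, np.random.default_rng(4))
            # count spikes in the evoked window after each trigger
            n_win = sum(
                np.searchsorted(train.times_s, t + 0.05) - np.searchsorted(train.times_s, t + 0.0)
                for t in trig
            )
            expected_null = cfg.spike_background_hz * 0.05 * trig.size
            if expect_peak:
                assert n_win > expected_null + 5 * np.sqrt(expected_null)
            else:
                assert abs(n_win - expected_null) < 4 * np.sqrt(expected_null)

    def test_twitch_window_counts_match_kernel_integral_oracle(self):
        """Mean spike count in (0.01, 0.05] after twitches matches the
        independent integration of the injected rate; wake-movement windows
        stay at background when gated."""
        cfg = SessionConfig(duration_s=600.0, gate_wake=True, infusion_post=False, seed=7)
        rec, truth = generate_session(cfg)
        spikes = rec.spikes.times_s

        def mean_count(events):
            return np.mean(
                [
                    np.searchsorted(spikes, t + 0.05) - np.searchsorted(spikes, t + 0.01)
                    for t in events
                ]
            )

        tw = mean_count(truth.twitch_times_s)
        exp_tw = _expected_window_count(cfg, 0.01, 0.05)
        n = truth.twitch_times_s.size
        se = np.sqrt(exp_tw / n)
        assert abs(tw - exp_tw) < 4 * se
        if truth.wake_move_intervals.n >= 5:
            mv = mean_count(truth.wake_move_intervals.onsets_s)
            exp_mv = cfg.spike_background_hz * 0.04  # gated: background only
            se_mv = np.sqrt(exp_mv / truth.wake_move_intervals.n)
            assert mv < exp_tw / 2
            assert abs(mv - exp_mv) < 4 * se_mv
        assert tw > mean_count(truth.wake_move_intervals.onsets_s)


class TestLfp:
    def test_single_burst_dominant_frequency(self):
        from twitchgate.containers import ContinuousSignal
        from twitchgate.spindles import dominant_frequency

        cfg = SessionConfig(duration_s=10.0, noise_sd=0.0)
        iv = IntervalSeries([2.0], [2.3])
        lfp = generate_lfp(iv, cfg, np.random.default_rng(0))
        seg = lfp.slice(2.0, 2.3)
        assert dominant_frequency(seg, (1.0, 40.0)) == pytest.approx(12.0, abs=1.0)

    def test_bad_spindle_frequency_rejected(self):
        cfg = SessionConfig(neural_rate_hz=100.0, spindle_freq_hz=60.0)
        with pytest.raises(ConfigError):
            generate_lfp(IntervalSeries(np.empty(0), np.empty(0)), cfg, np.random.default_rng(0))


class TestInfusionSession:
    def test_motor_events_span_both_epochs_and_gate_is_epoch_specific(self):
        cfg = SessionConfig(duration_s=3600.0, seed=21, evoked_kernel_width_s=0.05)
        rec, truth = generate_infusion_session(cfg, drug=True)
        on = truth.wake_move_intervals.onsets_s
        assert (on < 1800).any() and (on >= 1800).any()
        assert truth.evoked["wake_move_pre"]["peak_rate_hz"] == 0.0
        assert truth.evoked["wake_move_post"]["peak_rate_hz"] == cfg.evoked_rate_hz

    def test_saline_session_never_releases_gate(self):
        cfg = SessionConfig(duration_s=3600.0, seed=22)
        _, truth = generate_infusion_session(cfg, drug=False)
        assert truth.evoked["wake_move_post"]["peak_rate_hz"] == 0.0

    def test_too_short_recording_rejected(self):
        with pytest.raises(ConfigError):
            generate_infusion_session(SessionConfig(duration_s=600.0), drug=True)
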