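"""Perievent correlations, jitter surrogates, and acceptance bands."""
import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import kstest

from twitchgate.containers import (
    ACTIVE_SLEEP,
    WAKE,
    BoutSegmentation,
    EventSeries,
    IntervalSeries,
    SpikeTrain,
)
from twitchgate.errors import EmptyCorrelationError, ParameterError
from twitchgate.perievent import (
    ECN_SPONT,
    SMC_SPONT,
    STIMULATION,
    CorrelationSpec,
    EventCorrelation,
    JitterSpec,
    acceptance_bands,
    band_exceedances,
    event_correlation,
    jitter_acceptance,
    jitter_surrogates,
    peak_rate,
    stimulation_state_comparison,
    waveform_average,
)


def brute_force_counts(spikes, triggers, spec):
    """Independent oracle: nested loop over (trigger, spike) pairs."""
    edges = spec.edges()
    counts = np.zeros(spec.n_bins, dtype=int)
    for tr in triggers:
        for sp in spikes:
            dt = sp - tr
            if dt < edges[0] or dt > edges[-1]:
                continue
            for b in range(spec.n_bins):
                if (edges[b] <= dt < edges[b + 1]) or (b == spec.n_bins - 1 and dt == edges[-1]):
                    counts[b] += 1
                    break
    return counts


class TestEventCorrelation:
    def test_known_two_trigger_example(self):
        """Two triggers with one spike 5 ms after each: only the (0.005,
        0.006] bin carries rate 2 / (2 * 0.001) = 1000 Hz."""
        spikes = SpikeTrain([10.0050001, 20.0050001])
        trig = EventSeries([10.0, 20.0])
        corr = event_correlation(spikes, trig, ECN_SPONT)
        idx = np.flatnonzero(corr.rate_hz)
        assert list(idx) == [155]  # bin [0.005, 0.006)
        assert corr.rate_hz[155] == pytest.approx(1000.0)

    def test_ecn_preset_bin_count(self):
        corr = event_correlation(SpikeTrain([1.0]), EventSeries([1.0]), ECN_SPONT)
        assert corr.rate_hz.size == 300  # 300 ms window, 1 ms bins

    def test_no_spikes_all_zero(self):
        corr = event_correlation(SpikeTrain([]), EventSeries([5.0]), ECN_SPONT)
        assert np.all(corr.rate_hz == 0)

    def test_zero_usable_triggers_raises(self):
        with pytest.raises(EmptyCorrelationError):
            event_correlation(SpikeTrain([1.0]), EventSeries([0.05]), ECN_SPONT, t_span=(0.0, 10.0))

    def test_edge_triggers_dropped(self):
        spikes = SpikeTrain(np.linspace(0, 10, 51))
        trig = EventSeries([0.05, 5.0, 9.99])
        corr = event_correlation(spikes, trig, ECN_SPONT, t_span=(0.0, 10.0))
        assert corr.n_triggers == 1

    @given(st.integers(0, 2**31 - 1), st.integers(1, 60), st.integers(0, 80))
    def test_matches_brute_force_oracle(self, seed, n_trig, n_spikes):
        r = np.random.default_rng(seed)
        spec = CorrelationSpec(0.4, 0.02)
        spikes = np.sort(r.uniform(0, 20, n_spikes))
        trig = np.sort(r.uniform(0.2, 19.8, n_trig))
        corr = event_correlation(SpikeTrain(spikes), EventSeries(trig), spec)
        assert np.array_equal(corr.counts, brute_force_counts(spikes, trig, spec))

    @given(st.integers(0, 2**31 - 1))
    def test_total_counts_equal_pairs_within_window(self, seed):
        r = np.random.default_rng(seed)
        spec = CorrelationSpec(0.5, 0.01)
        spikes = np.sort(r.uniform(0, 30, 200))
        trig = np.sort(r.uniform(0.25, 29.75, 40))
        corr = event_correlation(SpikeTrain(spikes), EventSeries(trig), spec)
        pairs = sum(
            int(np.sum(np.abs(spikes - t) <= spec.half_s)) for t in trig
        )
        assert corr.counts.sum() == pairs

    def test_invalid_spec_rejected(self):
        with pytest.raises(ParameterError):
            CorrelationSpec(0.3, 0.007)  # not divisible into whole bins


class TestWaveformAverage:
    def test_identical_segments_mean_exact_sem_zero(self):
        from twitchgate.containers import ContinuousSignal

        fs = 100.0
        t = np.arange(int(20 * fs)) / fs
        x = np.sin(2 * np.pi * 1.0 * t)  # 1 Hz; triggers 1 s apart see identical segments
        sig = ContinuousSignal(x, fs)
        trig = EventSeries(np.arange(5.0, 15.0, 1.0))
        wa = waveform_average(sig, trig, CorrelationSpec(1.0, 0.01))
        assert np.allclose(wa.sem, 0.0, atol=1e-12)
        assert wa.n_triggers == 10

    def test_two_segment_arithmetic(self):
        from twitchgate.containers import ContinuousSignal

        fs = 10.0
        x = np.concatenate([np.full(50, 1.0), np.full(50, 3.0)])
        sig = ContinuousSignal(x, fs)
        trig = EventSeries([2.0, 7.0])
        wa = waveform_average(sig, trig, CorrelationSpec(1.0, 0.1))
        assert np.allclose(wa.mean, 2.0)
        assert np.allclose(wa.sem, 1.0)  # sd of {1,3} / sqrt(2) = sqrt(2)/sqrt(2)


class TestJitterSurrogates:
    def test_counts_and_cells_preserved(self, rng):
        trig = np.sort(rng.uniform(0, 100, 50))
        js = JitterSpec(n_surrogates=200, jitter_window_s=0.5)
        surr = jitter_surrogates(trig, js, rng)
        assert surr.shape == (200, 50)
        cells = np.floor(trig / 0.5)
        for row in surr:
            assert np.array_equal(np.sort(np.floor(row / 0.5)), np.sort(cells))

    def test_tiny_window_is_identity_limit(self, rng):
        trig = np.sort(rng.uniform(0, 10, 20))
        js = JitterSpec(n_surrogates=5, jitter_window_s=1e-9)
        surr = jitter_surrogates(trig, js, rng)
        assert np.allclose(surr, trig, atol=1e-8)

    def test_uniform_within_cell(self, rng):
        """Jittered copies of one trigger are uniform over its 500 ms cell."""
        trig = np.array([3.2])
        js = JitterSpec(n_surrogates=1000, jitter_window_s=0.5)
        surr = jitter_surrogates(trig, js, rng)[:, 0]
        assert surr.min() >= 3.0 and surr.max() < 3.5
        stat = kstest(surr, "uniform", args=(3.0, 0.5))
        assert stat.pvalue > 0.01


class TestAcceptanceBands:
    def test_degenerate_constant_surrogates_collapse_bands(self):
        spec = CorrelationSpec(0.1, 0.01)
        corr = event_correlation(SpikeTrain([1.0]), EventSeries([1.0]), spec)
        surr = np.full((500, spec.n_bins), 7.0)
        out = acceptance_bands(corr, surr, JitterSpec(n_surrogates=500))
        assert np.allclose(out.upper_band_hz, 7.0)
        assert np.allclose(out.lower_band_hz, 7.0)

    def test_too_few_surrogates_raises(self):
        spec = CorrelationSpec(0.1, 0.01)
        corr = event_correlation(SpikeTrain([1.0]), EventSeries([1.0]), spec)
        with pytest.raises(ParameterError):
            acceptance_bands(corr, np.zeros((50, spec.n_bins)), JitterSpec(n_surrogates=50, alpha=0.01))

    def test_injected_response_detected_with_power(self, rng):
        """A 5x-background evoked response must cross the upper band at the
        injected latency in (nearly) every session."""
        from twitchgate.synth import SessionConfig, generate_spikes

        hits = 0
        for s in range(10):
            r = np.random.default_rng(600 + s)
            cfg = SessionConfig(duration_s=600.0, evoked_rate_hz=25.0, gate_wake=False)
            trig = np.sort(r.uniform(1.0, 599.0, 150))
            spikes = generate_spikes({"twitch": trig}, cfg, r)
            corr = jitter_acceptance(spikes, EventSeries(trig), ECN_SPONT, JitterSpec(), r,
                                     t_span=(0.0, 600.0))
            above = band_exceedances(corr)["above"]
            centers = corr.bin_centers_s
            if any(0.0 < centers[b] <= 0.05 for b in above):
                hits += 1
        assert hits >= 9


class TestPeakRate:
    def _corr(self, rates, bin_s=0.01):
        n = len(rates)
        edges = bin_s * np.arange(n + 1)
        return EventCorrelation(bin_edges_s=edges, rate_hz=np.array(rates, float), n_triggers=1)

    def test_max_and_latency(self):
        pk, lat = peak_rate(self._corr([0.0, 0.0, 5.0, 2.0]), (0.0, 0.04))
        assert pk == 5.0 and lat == pytest.approx(0.025)

    def test_tie_breaks_to_earliest(self):
        pk, lat = peak_rate(self._corr([0.0, 4.0, 4.0, 1.0]), (0.0, 0.04))
        assert pk == 4.0 and lat == pytest.approx(0.015)

    def test_empty_interval_raises(self):
        with pytest.raises(ParameterError):
            peak_rate(self._corr([1.0, 2.0]), (0.5, 0.6))

    def test_latency_recovered_from_generator(self):
        """ECN-preset peak latency lands in (10, 50] ms for a 20 ms kernel.

        Trigger counts mirror the pooled correlations the latency is read
        from (hundreds to thousands of twitches)."""
        from twitchgate.synth import SessionConfig, generate_spikes

        ok = 0
        for s in range(10):
            r = np.random.default_rng(900 + s)
            cfg = SessionConfig(duration_s=600.0, gate_wake=False)
            trig = np.sort(r.uniform(1.0, 599.0, 600))
            spikes = generate_spikes({"twitch": trig}, cfg, r)
            corr = event_correlation(spikes, EventSeries(trig), ECN_SPONT)
            _, lat = peak_rate(corr, (0.0, ECN_SPONT.half_s))
            if 0.01 < lat <= 0.05:
                ok += 1
        assert ok >= 0.95 * 10


class TestStimulationComparison:
    def _bouts(self, T=100.0):
        spans, t, lab = [], 0.0, WAKE
        while t < T:
            spans.append((t, min(t + 10.0, T), lab))
            lab = ACTIVE_SLEEP if lab == WAKE else WAKE
            t += 10.0
        on, off, labs = zip(*spans)
        return BoutSegmentation(IntervalSeries(on, off, labs))

    def test_identical_trains_give_zero_t(self):
        bouts = self._bouts()
        stim = EventSeries(np.arange(5.0, 95.0, 5.0))
        spikes = SpikeTrain(np.arange(0.0, 100.0, 0.11))
        sessions = [(spikes, stim, bouts) for _ in range(4)]
        res = stimulation_state_comparison(sessions, STIMULATION)
        # same deterministic train in each state of every subject -> identical peaks
        peaks = [(s["peak_sleep_hz"], s["peak_wake_hz"]) for s in res["per_subject"]]
        if all(a == b for a, b in peaks):
            assert res["paired_t"]["t"] == 0.0

    def test_subject_without_one_state_excluded(self):
        bouts = BoutSegmentation(IntervalSeries([0.0], [100.0], [WAKE]))
        stim = EventSeries([10.0, 20.0])
        spikes = SpikeTrain(np.arange(0.0, 100.0, 0.2))
        with pytest.warns(UserWarning, match="excluded"):
            res = stimulation_state_comparison([(spikes, stim, bouts)], STIMULATION)
        assert res["n_subjects"] == 0


class TestPairwiseAndSpikeJitter:
    def test_bonferroni_pairwise_limb_comparisons(self, rng):
        fore = rng.normal(30, 2, 8)
        nuch = rng.normal(20, 2, 8)
        hind = rng.normal(20, 2, 8)
        from twitchgate.perievent import pairwise_peak_comparisons

        res = pairwise_peak_comparisons({"forelimb": fore, "nuchal": nuch, "hindlimb": hind})
        assert res["alpha_per_comparison"] == pytest.approx(0.05 / 3)
        assert res["comparisons"]["forelimb_vs_nuchal"]["significant"]
        assert not res["comparisons"]["hindlimb_vs_nuchal"]["significant"]

    def test_spike_jitter_option_produces_bands(self, rng):
        spikes = SpikeTrain(np.sort(rng.uniform(0, 100, 600)))
        trig = EventSeries(np.sort(rng.uniform(1, 99, 40)))
        corr = jitter_acceptance(
            spikes, trig, CorrelationSpec(0.3, 0.01), JitterSpec(n_surrogates=200),
            rng, t_span=(0.0, 100.0), jitter_target="spikes",
        )
        assert corr.upper_band_hz is not None
        assert (corr.upper_band_hz >= corr.lower_band_hz).all()
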