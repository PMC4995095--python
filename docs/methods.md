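# Methods

This note documents the models, algorithms, and numerical choices behind
`twitchgate`, and what the synthetic validation does and does not show.

## The scientific setting

Neonatal rats cycle between wake (high nuchal muscle tone, long coordinated
limb movements) and active sleep (atonia punctuated by brief myoclonic
twitches). Sensory structures that relay proprioceptive reafference respond
strongly to twitches but not to wake movements: a corollary-discharge
mechanism gates the expected reafference of awake self-generated movement,
and that gate is disengaged during sleep. The pipeline quantifies this with
perievent spike statistics around detected motor events, and with a
pre/post pharmacological-disinhibition contrast in which the gate is
released and wake-movement reafference appears.

## Synthetic sessions

The generator produces the statistical structure the analyses assume, not
biophysics. All randomness derives from a single session seed through fixed
per-channel substreams, so any channel regenerates identically.

- **Bouts.** Wake and active sleep alternate; durations are
  `min_bout + Exponential(mean − min_bout)` with a 10 s minimum and 40 s
  default means, the final bout clipped at the session end. The literature
  gives no quantitative neonatal bout-duration model; the truncated
  exponential is the simplest alternating renewal process with a
  physiologically sensible floor, and both means are config fields rather
  than claims.
- **EMG.** Channels are synthesized directly as rectified envelopes
  (baseline 1 a.u. in atonia, ×5 during wake tone, ±5% Gaussian dither).
  Twitches are 50 ms raised-cosine bumps peaking at `twitch_amp_gain` ×
  baseline (default 5, comfortably above the 3× detection rule); wake
  movements are plateaus at 12× baseline with 20 ms ramps and durations
  0.35 s + Exponential (mean 0.5 s), so every injected movement satisfies
  the 300 ms detector rule with margin. The movement plateau must exceed
  twice the wake tone for the midpoint threshold (atonia baseline vs
  movement peaks) to sit above the tone; 12× achieves that with the
  default ×5 tone.
- **Twitch/movement placement.** Point events are Poisson within the
  permitted state's bouts (defaults: twitches 0.5 /s of sleep — matching
  the several-per-second-of-sleep pooled counts typical of this
  preparation — movements 0.05 /s of wake ≈ 3/min), kept 0.1 s off bout
  edges, with a 0.2–0.3 s minimum separation so that detector refractory
  periods cannot merge distinct ground-truth events.
- **LFP.** 1/f-shaped Gaussian noise (flat below 1 Hz) at 2500 Hz — a
  desk-scale rate that keeps the 1–40 Hz band and the 10–15 Hz spindle
  band fully resolvable — plus Tukey-tapered sinusoids at
  `spindle_freq_hz` (default 12 Hz) within sleep-confined intervals,
  default amplitude 10× the noise SD and default durations 0.4–0.6 s
  (several oscillation cycles, as real spindle bursts show).
- **Spikes.** An inhomogeneous Poisson process: homogeneous background
  (5 Hz) plus, after each trigger, a Gaussian rate kernel
  `A·exp(−(t − t_trig − λ)²/2w²)` with latency λ = 20 ms (relay-like; a
  cortex-like 110 ms is a config choice), width w = 10 ms and peak
  A = 50 Hz. Simulation is exact by superposition: each kernel contributes
  `Poisson(A·w·√(2π))` spikes at `Normal(t_trig + λ, w)`. Gating is the
  single switch the study manipulates: with `gate_wake` and no infusion the
  wake-movement kernel amplitude is 0; `infusion_post` (or the drug arm of
  an infusion session) restores it; twitch and stimulation kernels are
  state-independent throughout. For infusion analyses the kernel width is
  set to 50 ms, matching the 50 ms bins of the infusion correlation —
  reafference around long coordinated movements is temporally more
  dispersed than the sharp twitch response.

What the generator does **not** emulate: real EMG carrier waveforms and
motion artifacts, spike-waveform shape and sorting errors, non-Poisson
spiking (bursting, refractoriness), drifting state of arousal,
nonstationary firing, or correlated noise across channels. Passing tests
therefore validate the *analysis logic* — thresholds, windows, statistics,
calibration — not robustness to every pathology of real recordings.

## Scoring and detection rules

- **Tone dichotomization.** The nuchal envelope is split by a 1-D
  two-means threshold (initialized at the 10th/90th percentiles; a
  quantile-midpoint fallback is available). Runs shorter than 5 s are
  merged into their neighbors, shortest first. If the two means differ by
  less than 20% the envelope is treated as unimodal: one wake bout plus a
  warning. No tone threshold or hysteresis is published for this
  preparation; this rule is the package's own, chosen to be automatic,
  scale-invariant, and reproducible.
- **Baseline.** "Baseline" EMG is the median envelope over atonia samples
  (robust to twitch excursions), excluding the first 5τ of the record
  where the envelope filter is still settling.
- **Twitches.** Excursions strictly above 3× baseline whose peak lies in a
  sleep bout; event time is the peak (onset-vs-peak is unspecified in the
  field's descriptions; peak is config-exposed), with a 100 ms refractory.
  A value exactly at 3× is not a twitch.
- **Wake movements.** Candidates are ≥ 300 ms excursions above a
  provisional high threshold during wake; the final threshold is the
  midpoint between the atonia baseline and the mean peak of the 5 largest
  candidates (a seeded random draw from the top decile is available — a
  reproducible stand-in for manually picking five movements). Kept
  intervals have suprathreshold duration ≥ 300 ms and onset during wake.
  With fewer than 5 candidates the twitch threshold is used, with a
  warning.
- **Spindle bursts.** LFP band-passed 1–40 Hz (zero-phase 4th-order
  Butterworth — zero phase so perievent latencies, measured in
  milliseconds, are undistorted), RMS envelope with τ = 10 ms. The
  detection threshold is the midpoint between the envelope baseline
  (median outside candidate excursions, since "baseline" is otherwise
  undefined) and the mean peak of the 5 largest candidate excursions
  (candidates: > 2× median, < 50 ms gaps merged). Accepted bursts need
  duration ≥ 100 ms, dominant frequency 10–15 Hz (Hann periodogram,
  zero-padded to 1 Hz resolution; the searchable band is floored at
  1/duration), and ≥ 3 oscillations, counted as zero-crossing pairs with
  `(crossings+1)//2` so a clipped partial cycle counts.

## Perievent statistics

Bins are half-open `[left, right)` with the window's right edge inclusive;
a spike at the trigger time falls in the first post-trigger bin. Rates are
`count / (n_triggers · bin_s)`. Triggers whose window leaves the recording
are dropped, not padded. The histogram is validated bin-exactly against a
brute-force nested loop.

**Interval jitter.** The recording is partitioned into contiguous 500 ms
cells anchored at t = 0 (anchoring is unspecified in the source method;
fixed anchoring is reproducible); each of 1000 surrogates redraws every
trigger uniformly within its cell, preserving per-cell counts exactly.
Triggers, not spikes, are jittered.

**Simultaneous bands.** With per-bin surrogate mean `c(b)` and SD `s(b)`,
the bands are `c(b) ± δ·s(b)`, δ the ceiling (1−α) quantile of the
surrogate max-deviation statistic `M_i = max_b |R_i(b) − c(b)|/s(b)`
(zero-SD bins collapse onto the center). At most an α fraction of
surrogates escapes its own bands, so a null observation exchangeable with
the surrogates crosses anywhere with probability ≈ α. Calibrating one
scalar statistic in value space is essential: per-bin *quantile* bands
cannot exceed the surrogate support, and with hundreds of bins a new
draw's unique extreme bin would cross them with probability near B/(S+1)
regardless of α — a failure mode we verified by simulation before
adopting the max-deviation construction. The exact band algorithm of the
original correction is not restated in the source method; this
construction is a documented substitute validated by its measured
family-wise error (the acceptance experiment), not a claimed replica.

**Peaks.** `peak_rate` returns the maximum bin rate and its bin-center
latency in a search interval, earliest bin on ties.

## Infusion Δ analysis

Sessions split at 30 min (boundary events belong to post). Correlations
use the 3 s/50 ms preset; quiescence bins are those with centers in
[−1.5, −1.0) s, and their mean is subtracted, making the quiescence mean
exactly zero by construction. Δ = post − pre per subject, averaged within
group with per-bin SEM across subjects (not across triggers). The
expected-latency window is the contiguous run of post-trigger bins above
the upper acceptance band in the pooled raw correlation (pooled over both
groups by default; configurable), with a manual override; peak change is
the signed value of largest magnitude in that window. Group comparisons:
within-group paired t on pre vs post, between-group independent t on
percent differences (pre as denominator, undefined and flagged at
pre = 0; raw differences are used when any pre value is zero, as for
baseline-subtracted peaks). Motor metrics are movements/min, twitches/min
and tonic rate per epoch with the same percent-difference convention.

## Problem sizes and calibration experiments

The validation experiments run at desk scale, chosen to keep Monte-Carlo
error well inside the asserted tolerances: band calibration uses 500 null
sessions × 1000 surrogates (binomial SE ≈ 0.004 at α = 0.01); test
calibration uses 200 null experiments of 6–8 subjects; the unmasking
recovery uses 20 subjects per group × 60 min sessions; detector fidelity
uses sessions with ≥ 20 injected events per detector. Statistical-test
calibration experiments generate bouts and spikes directly (no EMG
synthesis), since the quantity under test is the inference step; the
dissociation experiment deliberately runs the full path from EMG scoring
onward.

## Known limitations

- The tone dichotomizer assumes a bimodal envelope; gradual tone drift or
  intermediate tone states would need hysteresis or an HMM, which the
  two-state model does not provide.
- Band calibration guarantees exchangeability-based control for jittered
  *triggers*; if real triggers carry sub-cell temporal structure (e.g.
  serial correlation faster than 500 ms), the surrogate null is partly
  destroyed by construction, as with all interval-jitter methods.
- The automated second pass (duration/frequency/oscillation criteria)
  replaces manual artifact review; residual artifacts must be excluded
  upstream by the user.
- `extract_spikes` is a single-threshold crossing detector meant as
  plumbing for synthetic MUA; it is not a spike sorter.
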