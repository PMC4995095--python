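"""Filtering, envelope extraction, and threshold spike extraction.

These are the shared front-end steps: zero-phase band-pass filtering (so
perievent latencies, which the downstream analyses measure in milliseconds,
are not distorted by filter delay), RMS and rectify-smooth envelopes with a
10 ms time constant, and a simple threshold-crossing spike extractor used as
plumbing when only a MUA-band trace is available.
"""
from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy import signal as sps
from scipy.stats import median_abs_deviation

from .containers import ContinuousSignal, SpikeTrain
from .errors import ParameterError

__all__ = ["bandpass", "rms_envelope", "rectify_smooth", "extract_spikes"]


def bandpass(signal: ContinuousSignal, low_hz: float, high_hz: float, order: int = 4) -> ContinuousSignal:
    """Zero-phase Butterworth band-pass (low-pass when ``low_hz == 0``).

    Forward-backward filtering (``sosfiltfilt``) doubles the effective order
    and removes group delay.
    """
    nyq = signal.rate_hz / 2.0
    if not (0 <= low_hz < high_hz):
        raise ParameterError(f"need 0 <= low < high, got ({low_hz}, {high_hz})")
    if high_hz >= nyq:
        raise ParameterError(
            f"band ({low_hz}, {high_hz}) Hz infeasible for rate {signal.rate_hz} Hz"
        )
    if low_hz == 0:
        sos = sps.butter(order, high_hz, btype="lowpass", fs=signal.rate_hz, output="sos")
    else:
        sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=signal.rate_hz, output="sos")
    out = sps.sosfiltfilt(sos, signal.samples)
    return replace(signal, samples=np.ascontiguousarray(out))


def _first_order_smooth(x: np.ndarray, tau_s: float, rate_hz: float) -> np.ndarray:
    # y[n] = (1-a) x[n] + a y[n-1],  a = exp(-dt/tau): exact exponential decay.
    a = float(np.exp(-1.0 / (rate_hz * tau_s)))
    zi = sps.lfiltic([1.0 - a], [1.0, -a], y=[x[0]], x=[x[0]])
    y, _ = sps.lfilter([1.0 - a], [1.0, -a], x, zi=zi)
    return y


def rms_envelope(signal: ContinuousSignal, tau_s: float = 0.01) -> ContinuousSignal:
    """Causal RMS envelope: exponentially weighted mean square, square-rooted.

    For a constant ``c`` the envelope settles at ``|c|``; for a sinusoid of
    period much shorter than ``tau_s`` it settles at amplitude / sqrt(2).
    """
    if tau_s <= 0:
        raise ParameterError(f"tau_s must be positive, got {tau_s}")
    ms = _first_order_smooth(signal.samples**2, tau_s, signal.rate_hz)
    return replace(signal, samples=np.sqrt(np.maximum(ms, 0.0)), units=signal.units)


def rectify_smooth(signal: ContinuousSignal, tau_s: float = 0.01) -> ContinuousSignal:
    """Full-wave rectification followed by first-order exponential smoothing."""
    if tau_s <= 0:
        raise ParameterError(f"tau_s must be positive, got {tau_s}")
    y = _first_order_smooth(np.abs(signal.samples), tau_s, signal.rate_hz)
    return replace(signal, samples=y)


def robust_sd(x: np.ndarray) -> float:
    """Noise SD estimate via the normal-consistent MAD (spikes inflate naive SD)."""
    return float(median_abs_deviation(x, scale="normal"))


def extract_spikes(mua_signal: ContinuousSignal, k_sd: float = 4.0, refractory_s: float = 0.001) -> SpikeTrain:
    """Threshold-crossing spike times from a MUA-band filtered trace.

    An event is an upward crossing of ``k_sd`` robust SDs by the absolute
    signal; crossings within ``refractory_s`` of an accepted event are
    discarded, so a biphasic waveform counts once.  A flat trace yields an
    empty train.
    """
    x = np.abs(mua_signal.samples)
    sd = robust_sd(mua_signal.samples)
    if sd == 0.0:
        return SpikeTrain(np.empty(0), label="spikes")
    thr = k_sd * sd
    above = x > thr
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above[0]:
        crossings = np.concatenate(([0], crossings))
    times = mua_signal.t0_s + crossings / mua_signal.rate_hz
    if times.size:
        keep = [0]
        for i in range(1, times.size):
            if times[i] - times[keep[-1]] >= refractory_s:
                keep.append(i)
        times = times[keep]
    return SpikeTrain(times, label="spikes")
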