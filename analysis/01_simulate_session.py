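#!/usr/bin/env python
"""Generate the reference spontaneous session used by the downstream drivers.

Writes the ground-truth event tables to results/session/ (text) and the
full signal container to scratch/ (binary, disposable).
"""
from pathlib import Path

from twitchgate.containers import EventSeries
from twitchgate.io import write_events, write_intervals, write_recording
from twitchgate.synth import SessionConfig, generate_session

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "session"
SCRATCH = ROOT / "scratch"


def main() -> None:
    cfg = SessionConfig(duration_s=600.0, seed=11)
    rec, truth = generate_session(cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
    write_recording(rec, SCRATCH / "session_seed11.h5")
    write_intervals(truth.bouts.intervals, OUT / "bouts_truth.csv")
    write_events(EventSeries(truth.twitch_times_s, "twitch"), OUT / "twitches_truth.csv")
    write_intervals(truth.wake_move_intervals, OUT / "wake_movements_truth.csv")
    write_intervals(truth.spindle_intervals, OUT / "spindles_truth.csv")
    write_events(rec.spikes, OUT / "spikes.csv")
    print(
        f"session: {cfg.duration_s:.0f} s, {truth.bouts.intervals.n} bouts, "
        f"{truth.twitch_times_s.size} twitches, {truth.wake_move_intervals.n} wake movements, "
        f"{truth.spindle_intervals.n} spindle bursts, {rec.spikes.n} spikes"
    )
    print(f"wrote tables to {OUT} and signals to {SCRATCH / 'session_seed11.h5'}")


if __name__ == "__main__":
    main()
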