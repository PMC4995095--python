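#!/usr/bin/env python
"""Score sleep/wake state and motor events from the EMG envelopes and
compare against the generator's ground truth.

The nuchal envelope is dichotomized into high tone (wake) and atonia
(active sleep); twitches are >3x-baseline excursions during atonia, wake
movements are >=300 ms suprathreshold bursts during high tone.
"""
import json
from pathlib import Path

import numpy as np

from twitchgate.containers import ACTIVE_SLEEP, WAKE
from twitchgate.io import write_events, write_intervals
from twitchgate.scoring import detect_twitches, detect_wake_movements, score_tone, state_rates
from twitchgate.synth import SessionConfig, generate_session

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "session"


def main() -> None:
    cfg = SessionConfig(duration_s=600.0, seed=11)
    rec, truth = generate_session(cfg)
    OUT.mkdir(parents=True, exist_ok=True)

    bouts = score_tone(rec.signals["emg_nuchal"])
    twitches = detect_twitches(rec.signals["emg_forelimb"], bouts)
    movements = detect_wake_movements(rec.signals["emg_forelimb"], bouts)
    write_intervals(bouts.intervals, OUT / "bouts_scored.csv")
    write_events(twitches, OUT / "twitches_scored.csv")
    write_intervals(movements, OUT / "wake_movements_scored.csv")

    d = np.abs(truth.twitch_times_s[:, None] - twitches.times_s[None, :]).min(axis=1)
    twitch_recall = float(np.mean(d <= 0.025))
    table, summary = state_rates(rec.spikes, bouts, min_pairs=5)
    table.to_csv(OUT / "state_rates.csv", index=False)
    report = {
        "n_bouts_scored": int(bouts.intervals.n),
        "n_bouts_truth": int(truth.bouts.intervals.n),
        "twitch_recall_25ms": twitch_recall,
        "n_movements_scored": int(movements.n),
        "n_movements_truth": int(truth.wake_move_intervals.n),
        "spike_rate_sleep_hz": summary[ACTIVE_SLEEP]["pooled_rate_hz"],
        "spike_rate_wake_hz": summary[WAKE]["pooled_rate_hz"],
        "wilcoxon": summary["wilcoxon"],
    }
    (OUT / "scoring_report.json").write_text(json.dumps(report, indent=2))
    print(
        f"scored {bouts.intervals.n} bouts (truth {truth.bouts.intervals.n}); "
        f"twitch recall at 25 ms = {twitch_recall:.3f}; "
        f"movements {movements.n}/{truth.wake_move_intervals.n}"
    )
    print(
        f"spike rate: sleep {report['spike_rate_sleep_hz']:.2f} Hz vs "
        f"wake {report['spike_rate_wake_hz']:.2f} Hz (twitch-evoked activity is sleep-confined)"
    )


if __name__ == "__main__":
    main()
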