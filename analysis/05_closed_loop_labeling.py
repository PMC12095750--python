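#!/usr/bin/env python
"""Closed-loop photolabeling comparison: trials ON vs trials OFF.

For a movement-suppressed (down-modulated) population, delivers matched
total light-on time either during trials or outside them and counts
labeled units under each condition, over 100 seeded sessions.  Writes
per-run counts to results/labeling_comparison.tsv.
"""

from pathlib import Path

import pandas as pd

from ctmotor import photoconversion as pc
from ctmotor import synth
from ctmotor.io import write_table

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(parents=True, exist_ok=True)

rows = []
for seed in range(100):
    cfg = synth.SessionConfig(duration=120.0, n_trials=20, seed=seed)
    session = synth.generate_session(cfg)
    activity, _ = synth.generate_activity(
        session,
        synth.PopulationConfig(n_units=50, class_proportions=(1.0, 0.0, 0.0)),
        seed=seed + 10_000,
    )
    trials = session.trials.rename(columns={"onset_s": "start", "offset_s": "end"})
    c_on = pc.LightDeliveryConfig(pulse_width=0.5, mode="trials_on", total_duration=cfg.duration)
    c_off = pc.LightDeliveryConfig(pulse_width=0.5, mode="trials_off", total_duration=cfg.duration)
    s_on = pc.build_light_schedule(c_on, trials)
    s_off = pc.build_light_schedule(c_off, trials, seed=seed + 20_000, n_pulses=len(s_on.events))
    out = pc.compare_labeling(activity, s_on, s_off)
    rows.append(
        {
            "seed": seed,
            "n_labeled_trials_on": out["n_labeled_on"],
            "n_labeled_trials_off": out["n_labeled_off"],
            "matched_on_time_s": out["matched_on_time"],
        }
    )

df = pd.DataFrame(rows)
write_table(df, OUT / "labeling_comparison.tsv")
frac = (df.n_labeled_trials_off >= df.n_labeled_trials_on).mean()
print(f"trials-OFF labeled >= trials-ON labeled in {100 * frac:.0f}% of 100 runs")
print(f"mean labeled counts: trials ON {df.n_labeled_trials_on.mean():.1f}, "
      f"trials OFF {df.n_labeled_trials_off.mean():.1f} (of 50 units)")
print("movement-suppressed units convert preferentially outside movement periods")
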