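#!/usr/bin/env python
"""Trial detection and success metrics on the reference synthetic session.

Detects trials with the three-way closed-loop gate (beam + capacitance +
minimum velocity), scores them against the success velocity threshold,
detects pulls and bins them by peak velocity.  Writes trials.tsv and
pulls.tsv under results/behavior/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from ctmotor import behavior, synth
from ctmotor.io import write_table

OUT = Path(__file__).resolve().parents[1] / "results" / "behavior"
OUT.mkdir(parents=True, exist_ok=True)

cfg = synth.SessionConfig(duration=300.0, n_trials=60, seed=1)
session = synth.generate_session(cfg)

starts = behavior.detect_trials(
    session.velocity, session.beam, session.capacitance, cfg.trial_min_velocity
)
trials = pd.DataFrame({"start": starts, "end": np.minimum(starts + 1.0, cfg.duration)})
trials = behavior.score_trials(trials, session.velocity, cfg.success_velocity_threshold)

pulls = behavior.detect_pulls(session.velocity, min_peak=cfg.trial_min_velocity)
pulls = behavior.bin_pulls_by_velocity(pulls)

write_table(trials, OUT / "trials.tsv")
write_table(pulls, OUT / "pulls.tsv")

gt_trials = session.trials
print(f"detected {len(trials)} trials (ground truth {len(gt_trials)}); "
      f"percent success {100 * trials.success.mean():.1f}%")
print(f"mean max velocity {trials.peak_velocity.mean():.2f} cm/s, "
      f"mean pull distance {trials.pull_distance.mean():.3f} cm")
print("pulls per velocity bin:")
print(pulls.velocity_bin.value_counts().sort_index().to_string())
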