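#!/usr/bin/env python
"""Optogenetic schedules and light-stratified movement metrics.

Builds a closed-loop schedule (400 ms trains at 20 Hz on one third of
trials) on the reference synthetic session, computes the two percent-
success definitions and per-condition kinematics, and measures keypoint
limb displacement per trial.  An opsin-like effect is emulated by halving
wheel velocity during lighted trials to show the metrics resolve it.
Writes results/opto_metrics.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from ctmotor import behavior, opto, synth
from ctmotor.io import write_table

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(parents=True, exist_ok=True)

cfg = synth.SessionConfig(duration=300.0, n_trials=60, seed=1)
session = synth.generate_session(cfg)
starts = behavior.detect_trials(
    session.velocity, session.beam, session.capacitance, cfg.trial_min_velocity
)
trials = pd.DataFrame({"start": starts, "end": np.minimum(starts + 1.0, cfg.duration)})
trials = behavior.score_trials(trials, session.velocity, cfg.success_velocity_threshold)

sched = opto.schedule_closed_loop(
    trials, fraction=1 / 3, delay=0.0, train_duration=0.4, rate=20.0,
    pulse_width=0.01, seed=3, session_duration=cfg.duration,
)
print(f"closed-loop schedule: {sched.train_onsets.size} trains of "
      f"{sched.pulses_per_train} pulses on {sched.lighted_trials.size}/{len(trials)} trials")

# emulate the opsin effect: halve velocity during lighted trials, rescore
v = session.velocity.samples.copy()
fs = cfg.sample_rate_behavior
for i in sched.lighted_trials:
    i0 = int(trials.start.iloc[i] * fs)
    i1 = int(trials.end.iloc[i] * fs)
    v[i0:i1] *= 0.5
from ctmotor.core import VelocityTrace

perturbed = behavior.score_trials(
    trials[["start", "end"]], VelocityTrace(v, fs), cfg.success_velocity_threshold
)

# limb kinematics follow the perturbed wheel velocity
session.velocity.samples[:] = v
kp = synth.generate_keypoints(session, seed=4, jitter_sd=0.002)
limb = opto.limb_displacement(kp, trials[["start", "end"]].to_numpy(), mode="max")

metrics = opto.stratified_trial_metrics(perturbed, sched, limb_max=limb)
rows = [("percent_successful_with_light_on", metrics.percent_successful_with_light_on)]
for name, d in (
    ("percent_success", metrics.percent_success_by_condition),
    ("mean_max_velocity_cm_s", metrics.mean_max_velocity),
    ("mean_pull_distance_cm", metrics.mean_pull_distance),
    ("mean_max_limb_displacement", metrics.mean_max_limb_displacement),
):
    rows += [(f"{name}_{k}", v) for k, v in sorted(d.items())]
df = pd.DataFrame(rows, columns=["metric", "value"])
write_table(df, OUT / "opto_metrics.tsv")
print(df.to_string(index=False))
print("lighted trials show lower success, velocity, distance and limb displacement")

open_sched = opto.schedule_open_loop(cfg.duration, 0.1, train_duration=1.2, rate=20.0, seed=5)
print(f"open-loop: {open_sched.train_onsets.size} trains x {open_sched.pulses_per_train} pulses "
      f"covering {open_sched.train_onsets.size * 1.2:.0f} s of {cfg.duration:.0f} s")
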