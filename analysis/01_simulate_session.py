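#!/usr/bin/env python
"""Generate the reference synthetic session used by the downstream analyses.

Writes a session bundle (events.tsv, traces.h5, keypoints.tsv, manifest)
under results/session/ via the pipeline driver and prints a summary of
what was embedded.
"""

from pathlib import Path

from ctmotor import io as ctio

OUT = Path(__file__).resolve().parents[1] / "results" / "session"

manifest = ctio.SessionManifest(
    sample_rate_behavior=2000.0,
    sample_rate_imaging=16.0,
    wheel_diameter=60.0,
    duration=300.0,
    n_trials=60,
    seed=1,
)

out = ctio.run_pipeline(manifest, ["simulate"], OUT)
session = out["simulate"]["session"]
gt = out["simulate"]["ground_truth"]

print(f"wrote session bundle to {OUT}")
print(f"  pulls embedded:   {len(session.pulls)}")
print(f"  trials (gated):   {len(session.trials)}")
print(f"  rewards:          {int((session.events.event == 'reward').sum())}")
print(f"  units:            {len(gt)}  ({gt.label.value_counts().to_dict()})")
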