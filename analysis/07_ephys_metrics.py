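#!/usr/bin/env python
"""Synaptic-response metrics on synthetic voltage-clamp sweeps.

Generates EPSC (-70 mV) and IPSC (0 mV) sweep sets at the latency and
amplitude scales typical of trained animals (onsets ~6 and ~13 ms),
measures onset latency, signed peak, steady state, the I/E ratio, and a
steady-state-normalized grand average.  Writes results/ephys_responses.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from ctmotor import ephys, synth
from ctmotor.io import write_table

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(parents=True, exist_ok=True)

cells = []
rng = np.random.default_rng(7)
for cell in range(8):
    e_peak = -float(rng.uniform(80, 250))
    i_peak = float(rng.uniform(150, 500))
    epsc = synth.generate_ephys(
        20, onset_latency=round(float(rng.uniform(5, 8)), 1), peak=e_peak,
        steady_state=0.4 * e_peak, noise_sd=4.0, seed=cell, holding_potential=-70.0,
    )
    ipsc = synth.generate_ephys(
        20, onset_latency=round(float(rng.uniform(11, 15)), 1), peak=i_peak,
        steady_state=0.4 * i_peak, noise_sd=4.0, seed=cell + 100, holding_potential=0.0,
    )
    r_e = ephys.detect_response(epsc)
    r_i = ephys.detect_response(ipsc)
    cells.append(
        {
            "cell": cell,
            "epsc_onset_ms": r_e.onset_latency_ms,
            "epsc_peak_pA": r_e.peak_pA,
            "ipsc_onset_ms": r_i.onset_latency_ms,
            "ipsc_peak_pA": r_i.peak_pA,
            "ie_ratio": ephys.ie_ratio(r_i.peak_pA, r_e.peak_pA),
            "_resp": r_e,
        }
    )

df = pd.DataFrame([{k: v for k, v in c.items() if not k.startswith("_")} for c in cells])
write_table(df, OUT / "ephys_responses.tsv")
print(df.round(2).to_string(index=False))
print(f"mean EPSC onset {df.epsc_onset_ms.mean():.1f} ms, "
      f"IPSC onset {df.ipsc_onset_ms.mean():.1f} ms, "
      f"mean I/E ratio {df.ie_ratio.mean():.2f}")

ga = ephys.grand_average([c["_resp"] for c in cells], normalization="steady_state")
print(f"grand average over {ga['n_cells']} cells; "
      f"normalized peak {ga['mean'].min():.2f} x steady state")
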