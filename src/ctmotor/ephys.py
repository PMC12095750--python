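"""Synaptic-response metrics from voltage-clamp sweeps.

Evoked excitatory currents are recorded at -70 mV holding (inward,
negative) and inhibitory currents at 0 mV (outward, positive) during a
100 ms photostimulation.  From the trial-averaged, baseline-subtracted
trace this module measures onset latency, signed peak current,
steady-state current, the inhibition/excitation ratio, and population
grand averages with optional steady-state normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import SweepSet

__all__ = ["SynapticResponse", "detect_response", "ie_ratio", "grand_average"]


@dataclass
class SynapticResponse:
    onset_latency_ms: float
    peak_pA: float            # signed: negative inward at -70 mV
    steady_state_pA: float
    times: np.ndarray         # s, sweep clock
    trace: np.ndarray         # baseline-subtracted mean sweep
    stim_onset: float
    stim_duration: float
    holding_potential: float

    @property
    def normalized_trace(self) -> np.ndarray:
        """Mean trace normalized to the steady-state evoked current."""
        if self.steady_state_pA == 0:
            raise ValueError("steady-state current is zero; cannot normalize")
        return self.trace / abs(self.steady_state_pA)


def detect_response(
    sweeps: SweepSet,
    k_sd: float = 3.0,
    sustain_ms: float = 1.0,
    baseline_ms: float = 10.0,
) -> SynapticResponse | None:
    """Detect and measure the evoked response; None if absent.

    On the trial-averaged trace, baseline statistics come from the
    ``baseline_ms`` window immediately before stimulus onset.  Onset is
    the first post-stimulus time at which |current| exceeds
    ``k_sd x baseline SD`` sustained for at least ``sustain_ms``; the
    peak is the signed extremum within the stimulus window (inward
    minimum at hyperpolarized holding, outward maximum at 0 mV); steady
    state is the mean over the final 20% of the stimulus window.
    """
    fs = sweeps.sample_rate
    avg = sweeps.mean
    i_stim = int(round(sweeps.stim_onset * fs))
    n_base = int(round(baseline_ms / 1000.0 * fs))
    if i_stim < n_base:
        raise ValueError("need >= %g ms of pre-stimulus baseline" % baseline_ms)
    base = avg[i_stim - n_base : i_stim]
    trace = avg - base.mean()
    sd = base.std(ddof=1) if n_base > 1 else 0.0

    i_end = int(round((sweeps.stim_onset + sweeps.stim_duration) * fs))
    window = trace[i_stim:i_end]
    thresh = k_sd * sd if sd > 0 else 0.0
    above = np.abs(window) > thresh
    n_sustain = max(int(round(sustain_ms / 1000.0 * fs)), 1)
    onset_idx = None
    run = 0
    for i, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= n_sustain:
            onset_idx = i - n_sustain + 1
            break
    if onset_idx is None:
        return None

    outward = sweeps.holding_potential > -35.0
    peak = float(window.max()) if outward else float(window.min())
    n_ss = max(int(round(0.2 * (i_end - i_stim))), 1)
    steady = float(window[-n_ss:].mean())
    return SynapticResponse(
        onset_latency_ms=onset_idx / fs * 1000.0,
        peak_pA=peak,
        steady_state_pA=steady,
        times=sweeps.times,
        trace=trace,
        stim_onset=sweeps.stim_onset,
        stim_duration=sweeps.stim_duration,
        holding_potential=sweeps.holding_potential,
    )


def ie_ratio(inhibitory_peak: float, excitatory_peak: float) -> float:
    """Inhibition/excitation ratio |I| / |E| (sign-free)."""
    if excitatory_peak == 0:
        warnings.warn("zero excitatory peak: I/E ratio undefined")
        return float("nan")
    return abs(inhibitory_peak) / abs(excitatory_peak)


def grand_average(
    responses: list,
    normalization: str = "steady_state",
) -> dict:
    """Population grand average response across cells (mean +/- SEM).

    With ``normalization="steady_state"`` each cell's trace is divided by
    the magnitude of its steady-state evoked current before averaging
    (cells with near-zero steady state are excluded with a warning).
    Traces are linearly resampled onto the first cell's time base when
    clocks differ.
    """
    if normalization not in ("steady_state", "none"):
        raise ValueError("normalization must be 'steady_state' or 'none'")
    if len(responses) == 0:
        raise ValueError("need at least one response")
    t_ref = responses[0].times
    traces = []
    for r in responses:
        tr = r.trace
        if normalization == "steady_state":
            if abs(r.steady_state_pA) < 1e-12:
                warnings.warn("cell with ~zero steady state excluded from normalized average")
                continue
            tr = tr / abs(r.steady_state_pA)
        if r.times.size != t_ref.size or not np.allclose(r.times, t_ref):
            tr = np.interp(t_ref, r.times, tr)
        traces.append(tr)
    if not traces:
        raise ValueError("no cells left after exclusion")
    m = np.vstack(traces)
    n = m.shape[0]
    sem = m.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(t_ref.size)
    return {"times": t_ref, "mean": m.mean(axis=0), "sem": sem, "n_cells": n}
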