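"""Wheel kinematics and closed-loop trial logic.

Decodes linear wheel velocity from an absolute rotary encoder, detects
trials by the task's three-way gate (IR beam + rung capacitance + minimum
velocity), scores success against a velocity threshold inside the reward
window, finds individual pulls, and provides the velocity-bin bookkeeping
used to compare pull groups at matched speeds.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .core import VelocityTrace

__all__ = [
    "VELOCITY_BINS",
    "decode_velocity",
    "detect_trials",
    "score_trials",
    "detect_pulls",
    "bin_pulls_by_velocity",
    "match_velocity_distributions",
]

#: Peak-velocity bins (cm/s), half-open [low, high); pulls below 2 cm/s are
#: left unbinned, 14 cm/s falls in the open-ended top bin.
VELOCITY_BINS = (("2-6", 2.0, 6.0), ("6-10", 6.0, 10.0), ("10-14", 10.0, 14.0), ("14+", 14.0, np.inf))


def _moving_average(x: np.ndarray, n: int) -> np.ndarray:
    """Centered moving average with edge shrinkage."""
    if n <= 1:
        return x
    kernel = np.ones(n) / n
    num = np.convolve(x, kernel, mode="same")
    norm = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / norm


def decode_velocity(
    encoder_positions: np.ndarray,
    resolution: int,
    wheel_diameter: float,
    sample_rate: float,
    smoothing: float = 0.05,
) -> VelocityTrace:
    """Convert absolute-encoder counts to linear wheel velocity (cm/s).

    Parameters
    ----------
    encoder_positions
        Raw counts in [0, resolution).
    resolution
        Counts per revolution (>= 2).
    wheel_diameter
        mm.
    smoothing
        Width (s) of the centered moving average applied to the unwrapped
        angle before differentiation.

    The angle is unwrapped across the counter wrap-around so a 1023 -> 0
    transition produces no velocity spike.
    """
    pos = np.asarray(encoder_positions, dtype=float)
    if resolution < 2:
        raise ValueError("encoder resolution must be >= 2")
    if np.any(pos < 0) or np.any(pos >= resolution):
        raise ValueError("encoder positions outside [0, resolution)")
    theta = np.unwrap(pos / resolution * 2 * np.pi)
    n_sm = int(round(smoothing * sample_rate))
    theta = _moving_average(theta, max(n_sm, 1))
    r_cm = wheel_diameter / 10.0 / 2.0
    v = np.gradient(theta) * sample_rate * r_cm
    return VelocityTrace(v, sample_rate)


def detect_trials(
    velocity: VelocityTrace,
    beam: np.ndarray,
    capacitance: np.ndarray,
    min_velocity: float,
    refractory: float = 1.0,
) -> np.ndarray:
    """Trial start times: first sample where all three gates hold.

    A trial commences at the first sample where the IR beam is broken, the
    rungs register contact, and velocity is at or above ``min_velocity``
    (the jitter-exclusion gate).  Subsequent starts within ``refractory``
    seconds are suppressed to avoid double-triggering on one pull.
    """
    beam = np.asarray(beam, dtype=bool)
    capacitance = np.asarray(capacitance, dtype=bool)
    v = velocity.samples
    if beam.size != v.size or capacitance.size != v.size:
        raise ValueError("beam/capacitance channels must be co-sampled with velocity")
    gate = (v >= min_velocity) & beam & capacitance
    idx = np.flatnonzero(gate)
    if idx.size == 0:
        return np.empty(0)
    fs = velocity.sample_rate
    keep = [idx[0]]
    min_gap = refractory * fs
    for i in idx[1:]:
        if i - keep[-1] >= min_gap:
            keep.append(i)
    return velocity.t0 + np.asarray(keep) / fs


def score_trials(
    trials: pd.DataFrame,
    velocity: VelocityTrace,
    success_threshold: float,
    window: float = 0.2,
) -> pd.DataFrame:
    """Score trials for success and compute per-trial kinematic metrics.

    Success: velocity reaches ``success_threshold`` at any sample within
    ``[start, start + window)``.  ``peak_velocity`` is the maximum over the
    trial interval, ``pull_distance`` the integral of positive velocity
    over it (cm).

    ``trials`` needs ``start`` and ``end`` columns (s); a scored copy is
    returned.
    """
    if window <= 0:
        raise ValueError("success window must be positive")
    out = trials.copy()
    v, fs, t0 = velocity.samples, velocity.sample_rate, velocity.t0
    succ, peak, dist = [], [], []
    for _, tr in trials.iterrows():
        i0 = int(round((tr.start - t0) * fs))
        i1 = int(round((tr.end - t0) * fs))
        iw = int(round((tr.start + window - t0) * fs))
        i0, i1, iw = max(i0, 0), min(i1, v.size), min(iw, v.size)
        seg = v[i0:i1]
        succ.append(bool(np.any(v[i0:iw] >= success_threshold)))
        peak.append(float(seg.max()) if seg.size else 0.0)
        dist.append(float(np.clip(seg, 0.0, None).sum() / fs))
    out["success"] = succ
    out["peak_velocity"] = peak
    out["pull_distance"] = dist
    return out


def detect_pulls(
    velocity: VelocityTrace,
    min_peak: float,
    refractory: float = 0.3,
) -> pd.DataFrame:
    """Detect discrete wheel pulls as local velocity maxima >= min_peak.

    Peaks closer together than ``refractory`` are merged, keeping the
    higher one.  Onset/offset are the nearest samples around the peak at
    which velocity crosses below ``min_peak``.
    """
    if min_peak <= 0:
        raise ValueError("min_peak must be positive")
    v, fs, t0 = velocity.samples, velocity.sample_rate, velocity.t0
    distance = max(int(round(refractory * fs)), 1)
    peaks, _ = find_peaks(v, height=min_peak, distance=distance)
    below = v < min_peak
    rows = []
    for p in peaks:
        pre = np.flatnonzero(below[:p])
        post = np.flatnonzero(below[p:])
        onset = (pre[-1] + 1) if pre.size else 0
        offset = (p + post[0]) if post.size else v.size - 1
        rows.append(
            {
                "peak_time": t0 + p / fs,
                "peak_velocity": float(v[p]),
                "onset": t0 + onset / fs,
                "offset": t0 + offset / fs,
            }
        )
    return pd.DataFrame(rows, columns=["peak_time", "peak_velocity", "onset", "offset"])


def bin_pulls_by_velocity(pulls: pd.DataFrame) -> pd.DataFrame:
    """Label each pull with its peak-velocity bin (NaN below 2 cm/s)."""
    out = pulls.copy()
    edges = [b[1] for b in VELOCITY_BINS] + [np.inf]
    labels = [b[0] for b in VELOCITY_BINS]
    out["velocity_bin"] = pd.cut(
        out["peak_velocity"], bins=edges, labels=labels, right=False
    )
    return out


def match_velocity_distributions(
    pulls_a: pd.DataFrame, pulls_b: pd.DataFrame, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Subsample two pull groups to identical per-bin counts.

    Within each peak-velocity bin, min(count_a, count_b) pulls are kept
    from each group (sampling without replacement, seeded), yielding
    subsets with equal bin histograms — the device used to compare
    activity across training stages at matched movement speeds.  Bins
    empty in both groups are dropped with a warning.
    """
    if len(pulls_a) == 0 or len(pulls_b) == 0:
        raise ValueError("both pull groups must be non-empty")
    rng = np.random.default_rng(seed)
    a = bin_pulls_by_velocity(pulls_a)
    b = bin_pulls_by_velocity(pulls_b)
    keep_a, keep_b = [], []
    for name, _, _ in VELOCITY_BINS:
        ia = a.index[a.velocity_bin == name]
        ib = b.index[b.velocity_bin == name]
        if len(ia) == 0 and len(ib) == 0:
            warnings.warn(f"velocity bin {name} empty in both groups; dropped")
            continue
        n = min(len(ia), len(ib))
        if n > 0:
            keep_a.extend(rng.choice(ia, size=n, replace=False))
            keep_b.extend(rng.choice(ib, size=n, replace=False))
    return a.loc[sorted(keep_a)], b.loc[sorted(keep_b)]
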