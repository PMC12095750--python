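"""Optogenetic stimulation schedules and light-stratified movement metrics.

Builds the pulse-train schedules used to perturb activity during the
wheel task — closed-loop trains triggered at trial start (optionally
delayed to around peak velocity) on a fraction of trials, and open-loop
trains covering a fraction of the session — and computes the trial
metrics stratified by light condition, including keypoint-derived limb
displacement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import KeypointTrack

__all__ = [
    "StimSchedule",
    "StratifiedMetrics",
    "schedule_closed_loop",
    "schedule_open_loop",
    "assign_light_condition",
    "stratified_trial_metrics",
    "limb_displacement",
]


@dataclass
class StimSchedule:
    """Pulse-train stimulation schedule.

    ``train_onsets`` are the starts of each pulse train; each train holds
    ``round(train_duration * rate)`` pulses of ``pulse_width`` seconds at
    ``rate`` Hz.  For closed-loop modes ``lighted_trials`` indexes the
    trials that received a train.
    """

    train_onsets: np.ndarray
    train_duration: float
    rate: float
    pulse_width: float
    mode: str
    lighted_trials: np.ndarray | None = None
    lighted_fraction: float | None = None
    n_truncated: int = 0

    @property
    def pulses_per_train(self) -> int:
        return int(round(self.train_duration * self.rate))

    @property
    def pulse_onsets(self) -> np.ndarray:
        within = np.arange(self.pulses_per_train) / self.rate
        return (self.train_onsets[:, None] + within[None, :]).ravel()

    @property
    def train_intervals(self) -> np.ndarray:
        return np.column_stack([self.train_onsets, self.train_onsets + self.train_duration])


def schedule_closed_loop(
    trials: pd.DataFrame,
    fraction: float = 1.0 / 3.0,
    delay: float = 0.0,
    train_duration: float = 0.4,
    rate: float = 20.0,
    pulse_width: float = 0.01,
    seed: int = 0,
    session_duration: float | None = None,
) -> StimSchedule:
    """Closed-loop trains on a seeded random subset of trials.

    A fraction of trials (sampled without replacement, exact count =
    ``round(fraction * n_trials)``) receives a train starting at
    ``trial start + delay``; delay 0 targets trial start, 110 ms targets
    the time of maximum trial velocity.  Trains that would run past the
    session end are truncated with a warning (counted in
    ``n_truncated``).
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    if delay < 0:
        raise ValueError("delay must be non-negative")
    starts = trials["start"].to_numpy(float)
    n = starts.size
    n_light = int(round(fraction * n))
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(n, size=n_light, replace=False))
    onsets = starts[chosen] + delay
    n_trunc = 0
    if session_duration is not None:
        n_trunc = int((onsets + train_duration > session_duration).sum())
        if n_trunc:
            warnings.warn(f"{n_trunc} trains extend past session end; truncated")
    return StimSchedule(
        onsets, train_duration, rate, pulse_width,
        mode="closed_loop", lighted_trials=chosen,
        lighted_fraction=n_light / n if n else 0.0, n_truncated=n_trunc,
    )


def schedule_open_loop(
    session_duration: float,
    coverage_fraction: float = 0.1,
    train_duration: float = 1.2,
    rate: float = 20.0,
    pulse_width: float = 0.01,
    seed: int = 0,
) -> StimSchedule:
    """Open-loop trains at random onsets covering a fraction of the session.

    Non-overlapping trains are placed at seeded uniform-random onsets
    until the total train time matches ``coverage_fraction`` of the
    session to within one train.
    """
    if not (0 < coverage_fraction < 1):
        raise ValueError("coverage_fraction must be in (0, 1)")
    n_trains = int(round(coverage_fraction * session_duration / train_duration))
    if n_trains * train_duration > session_duration:
        raise ValueError("requested coverage unattainable without overlap")
    rng = np.random.default_rng(seed)
    slack = session_duration - n_trains * train_duration
    onsets = np.sort(rng.uniform(0.0, slack, size=n_trains)) + np.arange(n_trains) * train_duration
    return StimSchedule(onsets, train_duration, rate, pulse_width, mode="open_loop")


def assign_light_condition(trials: pd.DataFrame, schedule: StimSchedule) -> pd.DataFrame:
    """Flag each trial as light-on if any train overlaps its interval."""
    out = trials.copy()
    iv = schedule.train_intervals
    s = out["start"].to_numpy(float)
    e = out["end"].to_numpy(float)
    out["light_on"] = [
        bool(np.any((iv[:, 0] < ei) & (iv[:, 1] > si))) for si, ei in zip(s, e)
    ] if iv.size else False
    return out


@dataclass
class StratifiedMetrics:
    """Light-stratified trial metrics.

    percent_successful_with_light_on = 100 x (# successful light-on trials)
    / (# all successful trials); percent_success_by_condition = 100 x
    (# successful trials in condition) / (# trials in condition).
    """

    percent_successful_with_light_on: float
    percent_success_by_condition: dict
    mean_max_velocity: dict
    mean_pull_distance: dict
    mean_max_limb_displacement: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)


def _hier_mean(df: pd.DataFrame, col: str) -> float:
    """trial -> session -> animal unweighted mean hierarchy."""
    levels = [c for c in ("session", "animal") if c in df.columns]
    if not levels:
        return float(df[col].mean())
    g = df.groupby(levels, sort=True)[col].mean()
    for lvl in reversed(levels[:-1]):
        g = g.groupby(level=lvl).mean()
    return float(g.mean())


def stratified_trial_metrics(
    trials: pd.DataFrame,
    schedule: StimSchedule,
    limb_max: np.ndarray | None = None,
) -> StratifiedMetrics:
    """Movement metrics stratified by light condition.

    ``trials`` must carry ``start``/``end``/``success``/``peak_velocity``/
    ``pull_distance`` (see behavior.score_trials) and may carry
    ``session``/``animal`` grouping columns, in which case means follow
    the trial -> session -> animal aggregation hierarchy (unweighted at
    each level).  ``limb_max`` optionally supplies per-trial maximum limb
    displacement.
    """
    df = assign_light_condition(trials, schedule)
    if limb_max is not None:
        df = df.assign(limb_max=np.asarray(limb_max, dtype=float))
    flags = []
    n_success = int(df.success.sum())
    if n_success == 0:
        flags.append("no successful trials: percent_successful_with_light_on undefined")
        pct_light = float("nan")
    else:
        pct_light = 100.0 * int((df.success & df.light_on).sum()) / n_success

    pct_cond, vel_cond, dist_cond, limb_cond = {}, {}, {}, {}
    for cond, sub in df.groupby("light_on"):
        key = "light_on" if cond else "light_off"
        pct_cond[key] = 100.0 * float(sub.success.mean())
        vel_cond[key] = _hier_mean(sub, "peak_velocity")
        dist_cond[key] = _hier_mean(sub, "pull_distance")
        if "limb_max" in sub.columns:
            valid = sub.dropna(subset=["limb_max"])
            limb_cond[key] = _hier_mean(valid, "limb_max") if len(valid) else float("nan")
    if not df.light_on.any():
        flags.append("no lighted trials")
    return StratifiedMetrics(pct_light, pct_cond, vel_cond, dist_cond, limb_cond, flags)


def limb_displacement(
    keypoints: KeypointTrack, intervals: np.ndarray, mode: str = "max"
) -> np.ndarray:
    """Per-interval keypoint displacement: max (pulls) or sum (locomotion).

    Frame-to-frame Euclidean distances of the tracked keypoint are
    computed within each ``[onset, offset)`` interval; ``mode="max"``
    returns the maximum single-frame displacement (wheel-pull trials),
    ``mode="sum"`` the summed path length (locomotion bouts).  Intervals
    with missing (NaN) frames yield NaN so they can be excluded from
    means.
    """
    if mode not in ("max", "sum"):
        raise ValueError("mode must be 'max' or 'sum'")
    t = keypoints.times
    out = np.full(len(intervals), np.nan)
    for i, (on, off) in enumerate(np.asarray(intervals, dtype=float)):
        sel = (t >= on) & (t < off)
        xy = keypoints.xy[sel]
        if xy.shape[0] < 2:
            continue
        if np.any(~np.isfinite(xy)):
            continue  # flagged missing -> NaN
        d = np.linalg.norm(np.diff(xy, axis=0), axis=1)
        out[i] = d.max() if mode == "max" else d.sum()
    return out
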