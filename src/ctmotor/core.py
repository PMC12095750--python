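"""Shared containers for session signals.

Time convention throughout the package: seconds from session start,
intervals half-open ``[onset, offset)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VelocityTrace",
    "ActivityMatrix",
    "KeypointTrack",
    "SweepSet",
    "make_event_table",
    "EVENT_COLUMNS",
]

#: Canonical columns of an event table.  ``value`` carries an event-type
#: specific scalar (peak velocity for pulls, pulse index for light, ...).
EVENT_COLUMNS = ["event", "onset_s", "offset_s", "value"]


def make_event_table(rows=None) -> pd.DataFrame:
    """Build an event table (one row per event) with the canonical columns.

    Parameters
    ----------
    rows
        Iterable of ``(event, onset_s, offset_s, value)`` tuples, or None
        for an empty table.
    """
    if rows is None:
        rows = []
    df = pd.DataFrame(list(rows), columns=EVENT_COLUMNS)
    return df.astype({"event": str, "onset_s": float, "offset_s": float, "value": float})


@dataclass
class VelocityTrace:
    """Uniformly sampled wheel velocity in cm/s."""

    samples: np.ndarray
    sample_rate: float
    t0: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("velocity samples must be finite")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.sample_rate

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    def resample(self, rate: float) -> "VelocityTrace":
        """Linear-interpolation resampling onto a new uniform clock."""
        if rate <= 0:
            raise ValueError("rate must be positive")
        n = int(round(self.duration * rate))
        t_new = self.t0 + np.arange(n) / rate
        return VelocityTrace(
            np.interp(t_new, self.times, self.samples), rate, t0=self.t0
        )


@dataclass
class ActivityMatrix:
    """Unit x time fluorescence (dF/F) at a uniform imaging rate."""

    dff: np.ndarray
    sample_rate: float
    unit_ids: np.ndarray = None
    t0: float = 0.0

    def __post_init__(self):
        self.dff = np.atleast_2d(np.asarray(self.dff, dtype=float))
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not np.all(np.isfinite(self.dff)):
            raise ValueError("dF/F values must be finite")
        if self.unit_ids is None:
            self.unit_ids = np.arange(self.dff.shape[0])
        self.unit_ids = np.asarray(self.unit_ids)
        if self.unit_ids.size != self.dff.shape[0]:
            raise ValueError("unit_ids length must match number of units")

    @property
    def n_units(self) -> int:
        return self.dff.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.dff.shape[1]) / self.sample_rate

    def select(self, mask) -> "ActivityMatrix":
        return ActivityMatrix(
            self.dff[mask], self.sample_rate, self.unit_ids[mask], t0=self.t0
        )


@dataclass
class KeypointTrack:
    """2-D keypoint coordinates (e.g. wrist) at a camera frame rate."""

    xy: np.ndarray  # frame x 2
    frame_rate: float
    t0: float = 0.0

    def __post_init__(self):
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise ValueError("xy must be a (n_frames, 2) array")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.xy.shape[0]) / self.frame_rate


@dataclass
class SweepSet:
    """Repeated voltage-clamp current sweeps at one holding potential."""

    sweeps: np.ndarray  # trial x time, pA
    sample_rate: float
    stim_onset: float  # s from sweep start
    stim_duration: float = 0.1
    holding_potential: float = -70.0  # mV
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.sweeps = np.atleast_2d(np.asarray(self.sweeps, dtype=float))
        if self.sweeps.shape[0] < 1:
            raise ValueError("need at least one sweep")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        sweep_dur = self.sweeps.shape[1] / self.sample_rate
        if not (0 <= self.stim_onset and self.stim_onset + self.stim_duration <= sweep_dur):
            raise ValueError("stimulus window must lie within the sweep")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.sweeps.shape[1]) / self.sample_rate

    @property
    def mean(self) -> np.ndarray:
        return self.sweeps.mean(axis=0)
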