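"""Seeded synthetic sessions with known ground truth.

Emulates the signals of a head-fixed wheel-pull task: wheel velocity with
discrete pulls, the gating channels used by the closed-loop task logic
(IR beam, rung capacitance, absolute encoder), calcium populations with
down/up/non-modulated classes, wrist keypoint tracks, and voltage-clamp
current sweeps.  Every generator is deterministic given its config and
seed, and returns the ground truth needed to test the downstream stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .core import ActivityMatrix, KeypointTrack, SweepSet, VelocityTrace, make_event_table

__all__ = [
    "SessionConfig",
    "PopulationConfig",
    "SyntheticSession",
    "generate_session",
    "generate_activity",
    "generate_keypoints",
    "generate_ephys",
    "sample_peak_velocities",
]

CLASS_LABELS = ("down", "up", "no_mod")


@dataclass
class SessionConfig:
    """Parameters of a synthetic wheel-task session.

    The wheel task: a trial commences when the animal breaks the IR beam,
    contacts the capacitive rungs and moves the wheel above a minimum
    velocity; a reward is delivered when the pull reaches the success
    velocity threshold within the success window.
    """

    duration: float = 300.0            # s
    sample_rate_behavior: float = 2000.0  # Hz (DAQ rate)
    sample_rate_imaging: float = 16.0     # Hz (effective 2p rate)
    wheel_diameter: float = 60.0       # mm
    encoder_resolution: int = 1024     # counts/rev (10-bit absolute encoder)
    n_trials: int = 60
    peak_velocity_distribution: tuple = ("lognormal", {"mu": 2.0, "sigma": 0.3})  # cm/s
    success_velocity_threshold: float = 8.0   # cm/s
    trial_min_velocity: float = 2.0    # cm/s, jitter-exclusion gate
    success_window: float = 0.2        # s after trial start
    pull_width: float = 0.5            # s, raised-cosine support
    pull_gap: float = 1.5              # s, minimum inter-pull spacing
    velocity_noise_sd: float = 0.05    # cm/s
    seed: int = 0

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.sample_rate_behavior <= 0 or self.sample_rate_imaging <= 0:
            raise ValueError("sampling rates must be positive")
        if self.n_trials < 0:
            raise ValueError("n_trials must be non-negative")
        if self.pull_width <= 0:
            raise ValueError("pull_width must be positive")


@dataclass
class PopulationConfig:
    """Ground-truth structure of a synthetic calcium population.

    class_proportions are (down, up, no_mod).  suppression_gain scales the
    per-pull transient amplitude with the pull's peak velocity (dF/F per
    cm/s); a negative response_lag places the transient before the velocity
    peak.  Duplicate "branches" model dendritic ROIs of an already-extracted
    unit: attenuated noisy copies of a parent trace hitting a target
    correlation.
    """

    n_units: int = 100
    class_proportions: tuple = (0.69, 0.16, 0.15)
    suppression_gain: float = 0.05     # dF/F per (cm/s) peak velocity
    response_lag: float = -0.15        # s; negative = precedes velocity peak
    calcium_kernel_tau: float = 0.7    # s, indicator decay
    noise_sd: float = 0.05             # dF/F
    baseline_dff: float = 0.2          # tonic dF/F level
    gain_heterogeneity: float = 0.2    # lognormal sigma of per-unit gain
    trial_jitter: float = 0.6          # lognormal sigma of per-unit, per-pull amplitude
    n_duplicate_branches: int = 0
    duplicate_correlation: float = 0.9
    duplicate_attenuation: float = 0.9

    def __post_init__(self):
        p = np.asarray(self.class_proportions, dtype=float)
        if p.size != 3 or np.any(p < 0) or np.any(p > 1):
            raise ValueError("class_proportions must be three fractions in [0, 1]")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("class_proportions must sum to 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not (0 < self.duplicate_correlation <= 1):
            raise ValueError("duplicate_correlation must be in (0, 1]")


@dataclass
class SyntheticSession:
    """Bundle returned by :func:`generate_session`."""

    velocity: VelocityTrace
    events: pd.DataFrame                 # ground-truth pulls/trials/rewards
    encoder_counts: np.ndarray           # raw absolute-encoder channel
    beam: np.ndarray                     # IR-beam broken (bool)
    capacitance: np.ndarray              # rung contact (bool)
    config: SessionConfig = field(repr=False, default=None)

    @property
    def trials(self) -> pd.DataFrame:
        return self.events[self.events.event == "trial"].reset_index(drop=True)

    @property
    def pulls(self) -> pd.DataFrame:
        return self.events[self.events.event == "pull"].reset_index(drop=True)


def sample_peak_velocities(distribution, n, rng) -> np.ndarray:
    """Draw n peak velocities (cm/s) from a named distribution family."""
    name, params = distribution
    if name == "lognormal":
        return rng.lognormal(mean=params["mu"], sigma=params["sigma"], size=n)
    if name == "normal":
        return np.clip(rng.normal(params["mu"], params["sigma"], size=n), 0.0, None)
    if name == "constant":
        return np.full(n, float(params["value"]))
    raise ValueError(f"unknown peak-velocity distribution {name!r}")


def _place_pull_onsets(n, duration, width, gap, rng) -> np.ndarray:
    """Non-overlapping pull onsets with minimum spacing width+gap."""
    spacing = width + gap
    slack = duration - n * spacing - gap
    if slack < 0:
        raise ValueError(
            f"cannot place {n} pulls of {spacing:.2f} s spacing in {duration:.1f} s"
        )
    jitter = np.sort(rng.uniform(0.0, slack, size=n))
    return gap / 2 + jitter + np.arange(n) * spacing


def generate_session(config: SessionConfig) -> SyntheticSession:
    """Synthesize one behavioral session.

    Pulls are raised-cosine velocity bumps whose peak velocities follow the
    configured distribution.  The IR-beam and capacitance channels are
    active for the duration of each pull, and the encoder channel is the
    wheel angle (integrated velocity) quantized to encoder counts.  The
    ground-truth event table contains one ``pull`` row per bump, one
    ``trial`` row per pull whose velocity exceeds the minimum trial gate,
    and one ``reward`` row per successful trial.
    """
    fs = config.sample_rate_behavior
    n_samp = int(round(config.duration * fs))
    t = np.arange(n_samp) / fs
    rng = np.random.default_rng(config.seed)

    v_clean = np.zeros(n_samp)
    beam = np.zeros(n_samp, dtype=bool)
    cap = np.zeros(n_samp, dtype=bool)
    rows = []

    if config.n_trials > 0:
        onsets = _place_pull_onsets(
            config.n_trials, config.duration, config.pull_width, config.pull_gap, rng
        )
        peaks = sample_peak_velocities(
            config.peak_velocity_distribution, config.n_trials, rng
        )
        for onset, pk in zip(onsets, peaks):
            offset = onset + config.pull_width
            i0, i1 = int(math.ceil(onset * fs)), int(math.floor(offset * fs))
            i1 = min(i1, n_samp - 1)
            seg = slice(i0, i1 + 1)
            phase = (t[seg] - onset) / config.pull_width
            v_clean[seg] += pk * 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))
            beam[seg] = True
            cap[seg] = True
            rows.append(("pull", onset, offset, pk))

            # trial starts at the first sample where the gate velocity is
            # reached (same predicate the behavior module applies)
            in_pull = np.flatnonzero(v_clean[seg] >= config.trial_min_velocity)
            if in_pull.size:
                start = t[seg][in_pull[0]]
                rows.append(("trial", start, offset, pk))
                crossing = np.flatnonzero(
                    v_clean[seg] >= config.success_velocity_threshold
                )
                if crossing.size and t[seg][crossing[0]] - start < config.success_window:
                    rows.append(("reward", t[seg][crossing[0]], t[seg][crossing[0]], 1.0))

    v = v_clean + rng.normal(0.0, config.velocity_noise_sd, size=n_samp)

    # wheel angle from the *noiseless* velocity, quantized to encoder counts
    r_cm = config.wheel_diameter / 10.0 / 2.0
    theta = np.concatenate([[0.0], np.cumsum(v_clean[:-1]) / fs]) / r_cm  # rad
    counts = np.floor(theta / (2 * np.pi) * config.encoder_resolution).astype(int)
    counts %= config.encoder_resolution

    events = make_event_table(rows).sort_values("onset_s", kind="stable").reset_index(drop=True)
    return SyntheticSession(
        velocity=VelocityTrace(v, fs),
        events=events,
        encoder_counts=counts,
        beam=beam,
        capacitance=cap,
        config=config,
    )


def _calcium_kernel(tau: float, rate: float) -> np.ndarray:
    """Single-exponential indicator kernel, unit peak, truncated at 5 tau."""
    n = max(int(round(5 * tau * rate)), 1)
    return np.exp(-np.arange(n) / (tau * rate))


def generate_activity(
    session: SyntheticSession, pop: PopulationConfig, seed: int = 0
) -> tuple[ActivityMatrix, pd.DataFrame]:
    """Synthesize a calcium population time-locked to the session's pulls.

    Down units subtract, up units add, a velocity-scaled kernel-convolved
    transient around each pull peak (amplitude = gain x peak velocity,
    centred at peak time + response_lag); no-mod units are baseline plus
    noise.  Duplicate branches are appended after the primary units as
    attenuated noisy copies of randomly chosen parents, constructed so the
    parent remains the highest-variance member of its group while the
    parent-branch correlation hits the configured target.

    Returns the dF/F matrix at the imaging rate plus a ground-truth table
    (unit_id, label, duplicate_of, gain).
    """
    fs = session.config.sample_rate_imaging
    if fs <= 0:
        raise ValueError("imaging rate must be positive")
    rng = np.random.default_rng(seed)
    n_t = int(round(session.config.duration * fs))

    pulls = session.pulls
    pull_idx, pull_amp = [], []
    for _, p in pulls.iterrows():
        t_peak = p.onset_s + session.config.pull_width / 2.0 + pop.response_lag
        idx = int(round(t_peak * fs))
        if 0 <= idx < n_t:
            pull_idx.append(idx)
            pull_amp.append(p.value)  # peak velocity, cm/s
    pull_idx = np.asarray(pull_idx, dtype=int)
    pull_amp = np.asarray(pull_amp, dtype=float)
    kernel = _calcium_kernel(pop.calcium_kernel_tau, fs)

    labels = rng.choice(3, size=pop.n_units, p=np.asarray(pop.class_proportions))
    gains = pop.suppression_gain * rng.lognormal(0.0, pop.gain_heterogeneity, pop.n_units)
    sign = np.where(labels == 0, -1.0, np.where(labels == 1, 1.0, 0.0))

    # per-unit, per-pull amplitude jitter: trial-to-trial response
    # variability, which also keeps distinct units from being mutually
    # correlated above the duplicate-exclusion threshold
    drive = np.zeros((pop.n_units, n_t))
    if pull_idx.size:
        jit = rng.lognormal(0.0, pop.trial_jitter, size=(pop.n_units, pull_idx.size))
        np.add.at(drive, (slice(None), pull_idx), pull_amp[None, :] * jit)
    transient = fftconvolve(drive, kernel[None, :], axes=1)[:, :n_t] if pull_idx.size else drive

    dff = (
        pop.baseline_dff
        + (sign * gains)[:, None] * transient
        + rng.normal(0.0, pop.noise_sd, size=(pop.n_units, n_t))
    )

    gt = pd.DataFrame(
        {
            "unit_id": np.arange(pop.n_units),
            "label": [CLASS_LABELS[k] for k in labels],
            "duplicate_of": np.full(pop.n_units, -1),
            "gain": np.where(sign != 0, gains, 0.0),
        }
    )

    if pop.n_duplicate_branches > 0:
        parents = rng.integers(0, pop.n_units, size=pop.n_duplicate_branches)
        rho, att = pop.duplicate_correlation, pop.duplicate_attenuation
        branches = []
        for pid in parents:
            parent = dff[pid]
            mu, sd = parent.mean(), parent.std()
            eps = rng.normal(0.0, 1.0, size=n_t)
            branch = mu + att * (rho * (parent - mu) + math.sqrt(1 - rho**2) * sd * eps)
            branches.append(branch)
        dff = np.vstack([dff, branches])
        gt_branches = pd.DataFrame(
            {
                "unit_id": pop.n_units + np.arange(pop.n_duplicate_branches),
                "label": gt.label.values[parents],
                "duplicate_of": parents,
                "gain": gt.gain.values[parents],
            }
        )
        gt = pd.concat([gt, gt_branches], ignore_index=True)

    return ActivityMatrix(dff, fs, unit_ids=gt.unit_id.values), gt


def generate_keypoints(
    session: SyntheticSession,
    seed: int = 0,
    frame_rate: float = 100.0,
    coupling: float = 0.1,
    jitter_sd: float = 0.0,
    direction: tuple = (1.0, 1.0),
) -> KeypointTrack:
    """Wrist keypoint track whose displacement follows wheel velocity.

    Per-frame displacement along a fixed direction equals
    ``coupling * velocity / frame_rate`` plus isotropic Gaussian jitter,
    emulating a pose-estimation output without running pose estimation.
    """
    rng = np.random.default_rng(seed)
    v = session.velocity.resample(frame_rate).samples
    u = np.asarray(direction, dtype=float)
    u /= np.linalg.norm(u)
    step = coupling * v / frame_rate
    path = np.cumsum(step)[:, None] * u[None, :]
    if jitter_sd > 0:
        path = path + rng.normal(0.0, jitter_sd, size=path.shape)
    return KeypointTrack(path, frame_rate)


def generate_ephys(
    n_sweeps: int,
    onset_latency: float,
    peak: float,
    steady_state: float,
    noise_sd: float,
    seed: int = 0,
    sample_rate: float = 10000.0,
    pre_stim: float = 0.05,
    stim_duration: float = 0.1,
    post_stim: float = 0.1,
    rise_ms: float = 2.0,
    decay_tau_ms: float = 10.0,
    holding_potential: float = -70.0,
) -> SweepSet:
    """Synthetic evoked-current sweeps with known onset latency and peak.

    Each sweep is baseline noise, then — starting ``onset_latency`` ms after
    photostimulation onset — a half-cosine rise to ``peak`` pA over
    ``rise_ms``, an exponential relaxation to ``steady_state`` pA held for
    the remainder of the 100 ms stimulus, and an exponential return to
    baseline after stimulus offset.  ``peak``/``steady_state`` carry the
    sign convention of the holding potential (negative inward at -70 mV).
    Ground truth is stored in ``SweepSet.meta``.
    """
    if n_sweeps < 1:
        raise ValueError("n_sweeps must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    lat_s = onset_latency / 1000.0
    if not (0 <= lat_s < stim_duration):
        raise ValueError("onset latency must lie within the stimulus window")

    rng = np.random.default_rng(seed)
    n = int(round((pre_stim + stim_duration + post_stim) * sample_rate))
    t = np.arange(n) / sample_rate
    t_on = pre_stim + lat_s
    t_pk = t_on + rise_ms / 1000.0
    t_off = pre_stim + stim_duration
    tau = decay_tau_ms / 1000.0

    wave = np.zeros(n)
    rising = (t >= t_on) & (t < t_pk)
    wave[rising] = 0.5 * (1 - np.cos(np.pi * (t[rising] - t_on) / (rise_ms / 1000.0)))
    plateau = (t >= t_pk) & (t < t_off)
    ss = steady_state / peak if peak != 0 else 0.0
    wave[plateau] = ss + (1 - ss) * np.exp(-(t[plateau] - t_pk) / tau)
    after = t >= t_off
    level_at_off = ss + (1 - ss) * np.exp(-(t_off - t_pk) / tau) if t_off > t_pk else 1.0
    wave[after] = level_at_off * np.exp(-(t[after] - t_off) / tau)
    wave *= peak

    sweeps = wave[None, :] + rng.normal(0.0, noise_sd, size=(n_sweeps, n))
    return SweepSet(
        sweeps,
        sample_rate,
        stim_onset=pre_stim,
        stim_duration=stim_duration,
        holding_potential=holding_potential,
        meta={
            "onset_latency_ms": onset_latency,
            "peak_pA": peak,
            "steady_state_pA": steady_state,
            "noise_sd": noise_sd,
        },
    )
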