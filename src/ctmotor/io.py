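"""Session manifests, file formats, and the end-to-end pipeline driver.

Bundle layout on disk: ``events.tsv`` (one row per event), ``traces.h5``
(velocity + dF/F matrix + unit ids + ground truth), ``keypoints.tsv``,
``sweeps.h5`` and a ``manifest.yaml`` describing rates, geometry,
analysis parameters and seeds.  Tables are tab-delimited UTF-8 with a
single header row; times in seconds with 6 decimals.  Every output file
records the code version, the manifest hash, and the seeds used.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import behavior, imaging, opto, photoconversion, synth
from .core import ActivityMatrix, SweepSet, VelocityTrace

__all__ = [
    "SessionManifest",
    "ManifestError",
    "DependencyError",
    "load_manifest",
    "save_manifest",
    "write_table",
    "read_table",
    "write_traces",
    "read_traces",
    "run_pipeline",
    "PIPELINE_STAGES",
]


class ManifestError(ValueError):
    """Schema violation in a session manifest."""


class DependencyError(RuntimeError):
    """A pipeline stage was requested before its upstream stage."""


_REQUIRED = ("sample_rate_behavior", "sample_rate_imaging", "wheel_diameter")
_DEFAULTS = {
    "duration": 300.0,
    "n_trials": 60,
    "success_velocity_threshold": 8.0,
    "trial_min_velocity": 2.0,
    "rho_max": 0.8,
    "max_lag": 5.0,
    "seed": 0,
}


@dataclass
class SessionManifest:
    """Validated description of a session bundle and its analysis parameters."""

    sample_rate_behavior: float
    sample_rate_imaging: float
    wheel_diameter: float
    duration: float = 300.0
    n_trials: int = 60
    success_velocity_threshold: float = 8.0
    trial_min_velocity: float = 2.0
    rho_max: float = 0.8
    max_lag: float = 5.0
    seed: int = 0
    paths: dict = field(default_factory=dict)
    notes: str = ""

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_manifest(path) -> SessionManifest:
    """Load and validate a manifest; defaults are filled for optional keys."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for key in _REQUIRED:
        if key not in raw:
            raise ManifestError(f"missing required field '{key}'")
    for key in _REQUIRED + ("duration", "success_velocity_threshold"):
        if key in raw and not isinstance(raw[key], (int, float)):
            raise ManifestError(f"field '{key}' must be numeric, got {type(raw[key]).__name__}")
    known = {f for f in SessionManifest.__dataclass_fields__}
    fields = {k: v for k, v in raw.items() if k in known}
    for k, v in _DEFAULTS.items():
        fields.setdefault(k, v)
    return SessionManifest(**fields)


def save_manifest(manifest: SessionManifest, path) -> None:
    data = asdict(manifest)
    data["code_version"] = __version__
    data["manifest_hash"] = manifest.hash()
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def _provenance_header(manifest: SessionManifest | None) -> str:
    parts = [f"# ctmotor {__version__}"]
    if manifest is not None:
        parts.append(f"# manifest_hash {manifest.hash()}")
        parts.append(f"# seed {manifest.seed}")
    return "\n".join(parts) + "\n"


def write_table(df: pd.DataFrame, path, manifest: SessionManifest | None = None) -> None:
    """Tab-delimited table with a provenance comment header (6-decimal floats)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_provenance_header(manifest))
        df.to_csv(fh, sep="\t", index=False, float_format="%.6f", lineterminator="\n")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_traces(
    path,
    velocity: VelocityTrace | None = None,
    activity: ActivityMatrix | None = None,
    ground_truth: pd.DataFrame | None = None,
    manifest: SessionManifest | None = None,
) -> None:
    """HDF5 trace bundle: velocity, dff matrix, unit ids, ground-truth labels."""
    with h5py.File(path, "w") as fh:
        fh.attrs["code_version"] = __version__
        if manifest is not None:
            fh.attrs["manifest_hash"] = manifest.hash()
            fh.attrs["seed"] = manifest.seed
        if velocity is not None:
            d = fh.create_dataset("velocity", data=velocity.samples)
            d.attrs["sample_rate"] = velocity.sample_rate
            d.attrs["units"] = "cm/s"
        if activity is not None:
            d = fh.create_dataset("dff", data=activity.dff)
            d.attrs["sample_rate"] = activity.sample_rate
            d.attrs["dims"] = "unit x time"
            fh.create_dataset("unit_ids", data=np.asarray(activity.unit_ids, dtype=int))
        if ground_truth is not None:
            g = fh.create_group("ground_truth")
            for col in ground_truth.columns:
                vals = ground_truth[col].to_numpy()
                if vals.dtype == object:
                    vals = vals.astype("S")
                g.create_dataset(col, data=vals)


def read_traces(path) -> dict:
    out = {}
    with h5py.File(path, "r") as fh:
        if "velocity" in fh:
            out["velocity"] = VelocityTrace(fh["velocity"][...], fh["velocity"].attrs["sample_rate"])
        if "dff" in fh:
            out["activity"] = ActivityMatrix(
                fh["dff"][...], fh["dff"].attrs["sample_rate"], unit_ids=fh["unit_ids"][...]
            )
        if "ground_truth" in fh:
            g = fh["ground_truth"]
            cols = {}
            for k in g:
                v = g[k][...]
                cols[k] = v.astype(str) if v.dtype.kind == "S" else v
            out["ground_truth"] = pd.DataFrame(cols)
    return out


def write_sweeps(path, sweeps: SweepSet) -> None:
    with h5py.File(path, "w") as fh:
        fh.attrs["code_version"] = __version__
        d = fh.create_dataset("sweeps", data=sweeps.sweeps)
        d.attrs["sample_rate"] = sweeps.sample_rate
        d.attrs["stim_onset"] = sweeps.stim_onset
        d.attrs["stim_duration"] = sweeps.stim_duration
        d.attrs["holding_potential"] = sweeps.holding_potential
        for k, v in sweeps.meta.items():
            d.attrs[f"meta_{k}"] = v


def read_sweeps(path) -> SweepSet:
    with h5py.File(path, "r") as fh:
        d = fh["sweeps"]
        meta = {k[5:]: d.attrs[k] for k in d.attrs if k.startswith("meta_")}
        return SweepSet(
            d[...], d.attrs["sample_rate"], d.attrs["stim_onset"],
            d.attrs["stim_duration"], d.attrs["holding_potential"], meta=meta,
        )


PIPELINE_STAGES = ("simulate", "behavior", "imaging", "opto", "labeling")
_STAGE_DEPS = {
    "behavior": "simulate",
    "imaging": "behavior",
    "opto": "behavior",
    "labeling": "behavior",
}


def run_pipeline(manifest: SessionManifest, stages, out_dir) -> dict:
    """Execute the requested pipeline stages and write their outputs.

    Stages: simulate (synthetic session + population), behavior (trials
    and pulls), imaging (dedup + classification + cross-correlation),
    opto (closed-loop schedule + stratified metrics), labeling
    (trials-ON/OFF photolabeling comparison).  Each stage requires its
    upstream stage in the same run; a machine-readable ``run_log.json``
    records parameters, seeds, the manifest hash and code version.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages = list(stages)
    done: dict = {}
    for st in stages:
        dep = _STAGE_DEPS.get(st)
        if dep is not None and dep not in stages[: stages.index(st)]:
            raise DependencyError(f"stage '{st}' requires upstream stage '{dep}'")

    for st in stages:
        if st == "simulate":
            cfg = synth.SessionConfig(
                duration=manifest.duration,
                sample_rate_behavior=manifest.sample_rate_behavior,
                sample_rate_imaging=manifest.sample_rate_imaging,
                wheel_diameter=manifest.wheel_diameter,
                n_trials=manifest.n_trials,
                success_velocity_threshold=manifest.success_velocity_threshold,
                trial_min_velocity=manifest.trial_min_velocity,
                seed=manifest.seed,
            )
            session = synth.generate_session(cfg)
            activity, gt = synth.generate_activity(session, synth.PopulationConfig(), seed=manifest.seed + 1)
            write_table(session.events, out_dir / "events.tsv", manifest)
            write_traces(out_dir / "traces.h5", session.velocity, activity, gt, manifest)
            done["simulate"] = {"session": session, "activity": activity, "ground_truth": gt}
        elif st == "behavior":
            session = done["simulate"]["session"]
            starts = behavior.detect_trials(
                session.velocity, session.beam, session.capacitance, manifest.trial_min_velocity
            )
            trials = pd.DataFrame({"start": starts})
            trials["end"] = np.minimum(trials.start + 1.0, session.velocity.duration)
            trials = behavior.score_trials(trials, session.velocity, manifest.success_velocity_threshold)
            pulls = behavior.detect_pulls(session.velocity, manifest.trial_min_velocity)
            pulls = behavior.bin_pulls_by_velocity(pulls)
            write_table(trials, out_dir / "trials.tsv", manifest)
            write_table(pulls, out_dir / "pulls.tsv", manifest)
            done["behavior"] = {"trials": trials, "pulls": pulls}
        elif st == "imaging":
            activity = done["simulate"]["activity"]
            pulls = done["behavior"]["pulls"]
            dedup, info = imaging.deduplicate_units(activity, manifest.rho_max)
            z, valid = imaging.zscore(dedup, mode="whole_session")
            aligned = imaging.align_to_events(z, pulls.peak_time.to_numpy())
            cls = imaging.classify_modulation(aligned)
            table = pd.DataFrame(
                {"unit_id": dedup.unit_ids, "label": cls.labels, "degenerate": cls.degenerate}
            )
            for b in range(imaging.N_BINS):
                table[f"z_bin{b:02d}"] = cls.bin_z[:, b]
            write_table(table, out_dir / "classification.tsv", manifest)
            v_im = done["simulate"]["session"].velocity.resample(manifest.sample_rate_imaging)
            n = min(v_im.samples.size, z.dff.shape[1])
            correlograms = [
                imaging.cross_correlate(z.dff[u, :n], v_im.samples[:n], manifest.sample_rate_imaging, manifest.max_lag)
                for u in range(z.n_units)
            ]
            xcorr = pd.DataFrame(
                {
                    "unit_id": dedup.unit_ids,
                    "min_value": [c.min_value for c in correlograms],
                    "lag_of_min": [c.lag_of_min for c in correlograms],
                }
            )
            write_table(xcorr, out_dir / "xcorr.tsv", manifest)
            done["imaging"] = {"classification": cls, "table": table, "correlograms": correlograms, "dedup_info": info}
        elif st == "opto":
            trials = done["behavior"]["trials"]
            sched = opto.schedule_closed_loop(trials, seed=manifest.seed + 2, session_duration=manifest.duration)
            metrics = opto.stratified_trial_metrics(trials, sched)
            write_table(
                pd.DataFrame({"train_onset_s": sched.train_onsets}), out_dir / "schedule.tsv", manifest
            )
            rows = [("percent_successful_with_light_on", metrics.percent_successful_with_light_on)]
            for d_name, d in (
                ("percent_success", metrics.percent_success_by_condition),
                ("mean_max_velocity", metrics.mean_max_velocity),
                ("mean_pull_distance", metrics.mean_pull_distance),
            ):
                rows += [(f"{d_name}_{k}", v) for k, v in sorted(d.items())]
            write_table(pd.DataFrame(rows, columns=["metric", "value"]), out_dir / "metrics.tsv", manifest)
            done["opto"] = {"schedule": sched, "metrics": metrics}
        elif st == "labeling":
            activity = done["simulate"]["activity"]
            trials = done["behavior"]["trials"]
            cfg_on = photoconversion.LightDeliveryConfig(
                pulse_width=0.5, mode="trials_on", total_duration=manifest.duration
            )
            cfg_off = photoconversion.LightDeliveryConfig(
                pulse_width=0.5, mode="trials_off", total_duration=manifest.duration
            )
            s_on = photoconversion.build_light_schedule(cfg_on, trials)
            s_off = photoconversion.build_light_schedule(
                cfg_off, trials, seed=manifest.seed + 3, n_pulses=len(s_on.events)
            )
            cmp = photoconversion.compare_labeling(activity, s_on, s_off)
            write_table(
                pd.DataFrame(
                    {
                        "unit_id": activity.unit_ids,
                        "score_trials_on": cmp["scores_on"],
                        "score_trials_off": cmp["scores_off"],
                    }
                ),
                out_dir / "labeling.tsv",
                manifest,
            )
            done["labeling"] = cmp
        else:
            raise ValueError(f"unknown stage {st!r}")

    log = {
        "code_version": __version__,
        "manifest_hash": manifest.hash(),
        "seed": manifest.seed,
        "stages": stages,
        "parameters": asdict(manifest),
    }
    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True, default=str)
    return done
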