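"""Session manifest and trial file I/O.

Trials are interchanged as plain CSV, one row per millisecond, with units
embedded in column names (angles in degrees, positions in meters, raw EMG
in acquisition units).  The manifest is a YAML file listing the subject
profile, arm model, perturbation/trigger/filter parameters and the paths
and metadata of every trial; it round-trips losslessly.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .emg import FilterParams
from .kinematics import ArmModel
from .perturbation import PerturbationSpec, PhaseTriggerConfig
from .simulator import (
    MUSCLES,
    SessionDataset,
    SubjectProfile,
    TaskGeometry,
    TrialRecording,
)

__all__ = [
    "TrialParseError",
    "read_trial",
    "write_trial",
    "write_session",
    "read_session",
    "run_pipeline",
]

KINEMATIC_COLUMNS = [
    "t_ms", "x_m", "y_m", "vx_mps", "vy_mps",
    "shoulder_deg", "elbow_deg", "shoulder_dps", "elbow_dps",
]
EMG_COLUMNS = [f"emg_{m}" for m in MUSCLES]
REQUIRED_COLUMNS = KINEMATIC_COLUMNS + EMG_COLUMNS + ["event"]


class TrialParseError(ValueError):
    pass


def write_trial(path: str | Path, trial: TrialRecording) -> None:
    n = trial.n_samples
    events = [""] * n
    fs = trial.sampling_rate
    for name, t in trial.events.items():
        i = int(round((t - trial.time[0]) * fs))
        if 0 <= i < n:
            events[i] = (events[i] + ";" + name).lstrip(";")
    df = pd.DataFrame(
        {
            "t_ms": np.round(trial.time * 1000.0).astype(int),
            "x_m": trial.position[:, 0],
            "y_m": trial.position[:, 1],
            "vx_mps": trial.velocity[:, 0],
            "vy_mps": trial.velocity[:, 1],
            "shoulder_deg": trial.shoulder_angle,
            "elbow_deg": trial.elbow_angle,
            "shoulder_dps": trial.shoulder_velocity,
            "elbow_dps": trial.elbow_velocity,
        }
        | {f"emg_{m}": trial.emg[m] for m in MUSCLES}
        | {"event": events}
    )
    df.to_csv(path, index=False, float_format="%.12g")


def read_trial(path: str | Path, meta: dict | None = None) -> TrialRecording:
    path = Path(path)
    try:
        df = pd.read_csv(path, keep_default_na=False, na_values=[])
    except pd.errors.EmptyDataError as exc:
        raise TrialParseError(f"{path}: empty trial file") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TrialParseError(f"{path}: missing column(s) {missing} (line 1)")
    t = df["t_ms"].to_numpy(float) / 1000.0
    dt = np.diff(t)
    if len(dt) and not np.allclose(dt, 0.001, atol=1e-9):
        bad = int(np.argmax(~np.isclose(dt, 0.001, atol=1e-9)))
        raise TrialParseError(
            f"{path}: non-1 kHz sample spacing at line {bad + 3}"
        )
    events: dict[str, float] = {}
    ev = df["event"].astype(str).to_numpy()
    for i, cell in enumerate(ev):
        if cell and cell != "nan":
            for name in cell.split(";"):
                events[name] = float(t[i])
    return TrialRecording(
        time=t,
        position=df[["x_m", "y_m"]].to_numpy(float),
        velocity=df[["vx_mps", "vy_mps"]].to_numpy(float),
        shoulder_angle=df["shoulder_deg"].to_numpy(float),
        elbow_angle=df["elbow_deg"].to_numpy(float),
        shoulder_velocity=df["shoulder_dps"].to_numpy(float),
        elbow_velocity=df["elbow_dps"].to_numpy(float),
        emg={m: df[f"emg_{m}"].to_numpy(float) for m in MUSCLES},
        events=events,
        meta=dict(meta or {}),
    )


def _asdict_plain(obj) -> dict:
    d = dataclasses.asdict(obj)

    def conv(v):
        if isinstance(v, dict):
            return {k: conv(x) for k, x in v.items()}
        if isinstance(v, (tuple, list)):
            return [conv(x) for x in v]
        if isinstance(v, (np.floating, np.integer)):
            return v.item()
        return v

    return {k: conv(v) for k, v in d.items()}


def _tupled(cls, data: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if isinstance(v, list):
            v = tuple(v)
        kwargs[f.name] = v
    return cls(**kwargs)


def write_session(
    directory: str | Path,
    session: SessionDataset,
    spec: PerturbationSpec | None = None,
    trigger: PhaseTriggerConfig | None = None,
    params: FilterParams | None = None,
) -> Path:
    """Write all trials as CSV plus a YAML manifest; returns the manifest
    path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    trials_meta = []

    def emit(trial: TrialRecording, name: str, role: str):
        write_trial(directory / name, trial)
        entry = {"file": name, "role": role}
        for k, v in trial.meta.items():
            if isinstance(v, (np.floating, np.integer)):
                v = v.item()
            if isinstance(v, (str, int, float, bool, type(None))):
                entry[k] = v
        trials_meta.append(entry)

    for muscle, trials in session.mvc_trials.items():
        for k, tr in enumerate(trials):
            emit(tr, f"mvc_{muscle}_{k}.csv", "mvc")
    for k, tr in enumerate(session.mvv_trials):
        emit(tr, f"mvv_{k}.csv", "mvv")
    for k, tr in enumerate(session.task_trials):
        emit(tr, f"task_{k:03d}.csv", "task")

    manifest = {
        "subject": _asdict_plain(session.subject),
        "arm": _asdict_plain(session.arm),
        "geometry": _asdict_plain(session.geometry),
        "perturbation": _asdict_plain(spec or PerturbationSpec()),
        "trigger": _asdict_plain(trigger or PhaseTriggerConfig()),
        "filters": _asdict_plain(params or FilterParams()),
        "seed": session.seed,
        "trials": trials_meta,
    }
    mpath = directory / "manifest.yaml"
    with open(mpath, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return mpath


def read_session(
    manifest_path: str | Path,
) -> tuple[SessionDataset, PerturbationSpec, PhaseTriggerConfig, FilterParams]:
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    root = manifest_path.parent
    subject = _tupled(SubjectProfile, manifest["subject"])
    arm = _tupled(ArmModel, manifest["arm"])
    geometry = _tupled(TaskGeometry, manifest["geometry"])
    spec = _tupled(PerturbationSpec, manifest["perturbation"])
    trigger = _tupled(PhaseTriggerConfig, manifest["trigger"])
    params = _tupled(FilterParams, manifest["filters"])

    mvc: dict[str, list[TrialRecording]] = {m: [] for m in MUSCLES}
    mvv: list[TrialRecording] = []
    task: list[TrialRecording] = []
    for entry in manifest["trials"]:
        fpath = root / entry["file"]
        if not fpath.exists():
            raise TrialParseError(f"manifest references missing file {fpath}")
        meta = {k: v for k, v in entry.items() if k not in ("file", "role")}
        trial = read_trial(fpath, meta=meta)
        role = entry["role"]
        if role == "mvc":
            mvc[entry["mvc_muscle"]].append(trial)
        elif role == "mvv":
            mvv.append(trial)
        else:
            task.append(trial)
    session = SessionDataset(subject, arm, geometry, mvc, mvv, task,
                             seed=manifest.get("seed"))
    return session, spec, trigger, params


def run_pipeline(manifest_path: str | Path):
    """MVC -> MVV -> process -> clean -> quantify on a session manifest.

    Returns ``(ReflexResult, report_dict)``; deterministic for a given
    manifest.  Stage failures raise with a stage-tagged message.
    """
    from .reflex import quantify_session

    session, spec, trigger, params = read_session(manifest_path)
    if not any(not t.meta.get("perturbed") for t in session.task_trials):
        raise ValueError("quantify: session has no unperturbed trials")
    try:
        result, mvc, mvv = quantify_session(
            session, config=trigger, spec=spec, params=params
        )
    except Exception as exc:
        raise RuntimeError(f"quantify: {exc}") from exc
    report = {
        "mvv_mps": mvv.mvv,
        "mvv_peaks": mvv.peaks,
        "mvc": mvc.values,
        "n_task_trials": len(session.task_trials),
        "n_retained": len(result.cleaning.retained),
        "discarded": result.cleaning.discarded,
        "filters": _asdict_plain(params),
    }
    return result, report
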