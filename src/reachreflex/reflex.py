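"""Trial cleaning, %MVV window alignment, and the reflexive-EMG statistic.

Reflexive EMG for a muscle, motion phase, and latency window (SLR
25-75 ms, LLR 75-125 ms after perturbation onset) is the mean over
retained perturbed trials of the window-averaged % MVC envelope, minus
the mean over all unperturbed trials of the envelope averaged over the
*equivalent* window — the window anchored where the phase's trigger
would have fired in that unperturbed trial (fixed delay after home
acquisition for pre-motion; the %MVV crossing during the acceleration
phase for early/peak motion).  Positive values mean the perturbation
increased activity relative to unperturbed reaching; negative values, a
decrease.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .emg import FilterParams, MvcTable, MvvValue, ProcessedEmg, process_emg
from .perturbation import (
    PerturbationSpec,
    PhaseTriggerConfig,
    PHASES,
    detect_trigger,
    velocity_profile,
)
from .simulator import MUSCLES, SessionDataset, TrialRecording

__all__ = [
    "ReflexWindows",
    "ReflexResult",
    "CleaningReport",
    "clean_trials",
    "equivalent_window_start",
    "reflexive_emg",
    "movement_onset",
    "agonist_onset_lead",
    "quantify_session",
]


@dataclass(frozen=True)
class ReflexWindows:
    """SLR and LLR windows, seconds after perturbation onset.  Windows are
    half-open, contiguous, and ordered, so they never share samples."""

    slr: tuple[float, float] = (0.025, 0.075)
    llr: tuple[float, float] = (0.075, 0.125)

    def __post_init__(self) -> None:
        if not (self.slr[0] < self.slr[1] <= self.llr[0] < self.llr[1]):
            raise ValueError("windows must be ordered and non-overlapping")

    def items(self):
        return (("slr", self.slr), ("llr", self.llr))


@dataclass
class CleaningReport:
    """Retained/discarded partition of task trials with reasons."""

    retained: list[int]
    discarded: dict[int, str] = field(default_factory=dict)

    @property
    def retention_fraction(self) -> float:
        n = len(self.retained) + len(self.discarded)
        return len(self.retained) / n if n else 1.0


def _perturbation_conformance_rms(
    trial: TrialRecording, spec: PerturbationSpec
) -> float:
    """RMS deviation (deg/s) of measured elbow angular velocity from the
    commanded ramp-and-hold profile over the perturbation window."""
    fs = trial.sampling_rate
    i0 = int(round((trial.events["perturbation_onset"] - trial.time[0]) * fs))
    v0 = float(trial.meta.get(
        "perturbation_v0",
        trial.elbow_velocity[i0 - 1] if i0 > 0 else 0.0,
    ))
    commanded = velocity_profile(spec, v0)
    i1 = min(i0 + len(commanded), trial.n_samples)
    measured = trial.elbow_velocity[i0:i1]
    return float(np.sqrt(np.mean((measured - commanded[: len(measured)]) ** 2)))


def clean_trials(
    trials: list[TrialRecording],
    mvv: float,
    spec: PerturbationSpec | None = None,
    conformance_rms_fraction: float = 0.10,
) -> CleaningReport:
    """Discard trials with peak endpoint speed <= 90% MVV, and perturbed
    trials whose measured elbow velocity deviates from the commanded
    profile by more than ``conformance_rms_fraction`` of the plateau (RMS
    over the perturbation window)."""
    spec = spec or PerturbationSpec()
    report = CleaningReport(retained=[])
    tol = conformance_rms_fraction * spec.plateau_velocity
    for i, trial in enumerate(trials):
        peak = float(np.max(trial.speed))
        if peak <= 0.90 * mvv:
            report.discarded[i] = (
                f"peak speed {peak:.3f} m/s <= 90% MVV ({0.9 * mvv:.3f} m/s)"
            )
            continue
        if trial.perturbed:
            rms = _perturbation_conformance_rms(trial, spec)
            if rms > tol:
                report.discarded[i] = (
                    f"elbow velocity deviates from commanded profile "
                    f"(RMS {rms:.1f} deg/s > {tol:.1f} deg/s)"
                )
                continue
        report.retained.append(i)
    return report


def equivalent_window_start(
    trial: TrialRecording,
    phase: str,
    mvv: float,
    config: PhaseTriggerConfig | None = None,
) -> float | None:
    """Where the phase's trigger *would* have fired in an unperturbed
    trial; None (excluded from that phase's baseline) when the %MVV
    threshold is never crossed in the acceleration phase."""
    config = config or PhaseTriggerConfig()
    if trial.perturbed:
        raise ValueError("equivalent windows are defined on unperturbed trials")
    return detect_trigger(
        config, phase, trial.speed, mvv, trial.events["home_acquired"],
        sampling_rate=trial.sampling_rate, t0=float(trial.time[0]),
    )


def _window_mean(env: np.ndarray, fs: float, t0: float, start: float,
                 window: tuple[float, float]) -> float:
    i0 = int(round((start + window[0] - t0) * fs))
    i1 = int(round((start + window[1] - t0) * fs))
    if i0 < 0 or i1 > len(env) or i1 <= i0:
        raise ValueError("reflex window outside the trial span")
    return float(np.mean(env[i0:i1]))


@dataclass
class ReflexResult:
    """Reflexive EMG per muscle x phase x window, % MVC.

    ``table`` is tidy long format (one row per cell); ``per_trial`` keeps
    the per-perturbed-trial differences behind each cell's mean."""

    table: pd.DataFrame
    per_trial: pd.DataFrame
    cleaning: CleaningReport | None = None

    def value(self, muscle: str, phase: str, window: str) -> float:
        df = self.table
        row = df[(df.muscle == muscle) & (df.phase == phase) & (df.window == window)]
        return float(row.value_pct_mvc.iloc[0])


def reflexive_emg(
    perturbed: dict[str, list[tuple[TrialRecording, ProcessedEmg]]],
    unperturbed: list[tuple[TrialRecording, ProcessedEmg]],
    mvv: float,
    windows: ReflexWindows | None = None,
    config: PhaseTriggerConfig | None = None,
    subject_id: str = "",
    muscles: tuple[str, ...] = MUSCLES,
) -> ReflexResult:
    """The core outcome statistic.

    ``perturbed`` maps phase -> retained (trial, envelope) pairs;
    ``unperturbed`` lists all retained unperturbed pairs.  Cells with no
    perturbed trial or no alignable unperturbed trial are flagged missing
    (NaN), never silently zero.
    """
    windows = windows or ReflexWindows()
    config = config or PhaseTriggerConfig()
    rows, trial_rows = [], []
    for phase in PHASES:
        base_starts = []
        for trial, _ in unperturbed:
            start = equivalent_window_start(trial, phase, mvv, config)
            base_starts.append(start)
        for wname, w in windows.items():
            for muscle in muscles:
                base_vals = [
                    _window_mean(env[muscle], trial.sampling_rate, float(trial.time[0]), s, w)
                    for (trial, env), s in zip(unperturbed, base_starts)
                    if s is not None
                ]
                pert_vals = [
                    _window_mean(
                        env[muscle], trial.sampling_rate, float(trial.time[0]),
                        trial.events["perturbation_onset"], w,
                    )
                    for trial, env in perturbed.get(phase, [])
                ]
                n_p, n_u = len(pert_vals), len(base_vals)
                if n_p and n_u:
                    baseline = float(np.mean(base_vals))
                    diffs = np.asarray(pert_vals) - baseline
                    value = float(np.mean(diffs))
                    sd = float(np.std(diffs, ddof=1)) if n_p > 1 else np.nan
                    for k, dv in enumerate(diffs):
                        trial_rows.append(
                            dict(subject=subject_id, muscle=muscle, phase=phase,
                                 window=wname, trial=k, value_pct_mvc=float(dv))
                        )
                else:
                    value, sd = np.nan, np.nan
                rows.append(
                    dict(subject=subject_id, muscle=muscle, phase=phase, window=wname,
                         value_pct_mvc=value, sd=sd, n_perturbed=n_p, n_unperturbed=n_u)
                )
    return ReflexResult(pd.DataFrame(rows), pd.DataFrame(trial_rows))


def movement_onset(
    trial: TrialRecording,
    mvv: float,
    threshold_fraction: float = 0.05,
    sustain_s: float = 0.020,
) -> float | None:
    """First time endpoint speed crosses ``threshold_fraction * MVV`` and
    stays above it for at least ``sustain_s``; None if never crossed."""
    fs = trial.sampling_rate
    speed = trial.speed
    thr = threshold_fraction * mvv
    above = speed >= thr if thr > 0 else speed > 0
    need = max(1, int(round(sustain_s * fs)))
    run = 0
    for i, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= need:
            return float(trial.time[i - need + 1])
    return None


def agonist_onset_lead(
    trial: TrialRecording,
    processed: ProcessedEmg,
    mvv: float,
    muscle: str = "TRI",
    config: PhaseTriggerConfig | None = None,
    k_sd: float = 3.0,
    sustain_s: float = 0.025,
    background_window_s: float = 0.100,
) -> float | None:
    """Lead of agonist EMG onset over movement onset (s; positive = EMG
    first).  EMG onset is the first time the envelope exceeds background
    mean + ``k_sd`` background SDs for at least ``sustain_s``; background
    is taken from the pre-motion window of the same trial."""
    config = config or PhaseTriggerConfig()
    onset = movement_onset(trial, mvv)
    if onset is None:
        return None
    fs = trial.sampling_rate
    env = processed[muscle]
    t0 = float(trial.time[0])
    b0 = int(round((trial.events["home_acquired"] + config.pre_motion_delay - t0) * fs))
    b1 = b0 + int(round(background_window_s * fs))
    bg = env[max(b0, 0):b1]
    thr = float(np.mean(bg)) + k_sd * float(np.std(bg))
    # search from the background window onward: earlier samples carry
    # zero-phase filter edge transients that are not muscle activity
    above = env > thr  # strict: a zero-variance background needs a real rise
    need = max(1, int(round(sustain_s * fs)))
    run = 0
    emg_onset = None
    for i in range(max(b0, 0), len(above)):
        run = run + 1 if above[i] else 0
        if run >= need:
            emg_onset = float(trial.time[i - need + 1])
            break
    if emg_onset is None:
        return None
    return onset - emg_onset


def quantify_session(
    session: SessionDataset,
    windows: ReflexWindows | None = None,
    config: PhaseTriggerConfig | None = None,
    spec: PerturbationSpec | None = None,
    params: FilterParams | None = None,
    mvc: MvcTable | None = None,
    mvv: MvvValue | None = None,
) -> tuple[ReflexResult, MvcTable, MvvValue]:
    """Full pipeline on a session: MVC -> MVV -> process -> clean ->
    reflexive EMG.  Precomputed MVC/MVV tables may be supplied."""
    from .emg import compute_mvc, compute_mvv  # local to avoid cycle at import

    params = params or FilterParams()
    spec = spec or PerturbationSpec()
    if mvc is None:
        fs = next(iter(session.mvc_trials.values()))[0].sampling_rate
        mvc = compute_mvc(
            {m: [tr.emg[m] for tr in trials] for m, trials in session.mvc_trials.items()},
            fs, params,
        )
    if mvv is None:
        mvv = compute_mvv([tr.speed for tr in session.mvv_trials])
    cleaning = clean_trials(session.task_trials, mvv.mvv, spec)
    retained = [session.task_trials[i] for i in cleaning.retained]
    processed = [
        (tr, process_emg(tr.emg, tr.sampling_rate, mvc, params)) for tr in retained
    ]
    perturbed: dict[str, list] = {p: [] for p in PHASES}
    unperturbed = []
    for tr, env in processed:
        if tr.perturbed:
            perturbed[tr.meta["phase"]].append((tr, env))
        else:
            unperturbed.append((tr, env))
    result = reflexive_emg(
        perturbed, unperturbed, mvv.mvv, windows, config,
        subject_id=session.subject.subject_id,
    )
    result.cleaning = cleaning
    return result, mvc, mvv
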