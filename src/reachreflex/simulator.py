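"""Synthetic participant: ballistic reaches, perturbations, and surface EMG.

The generator stands in for the robot + participant so the whole pipeline
is testable without recordings.  It emulates:

* minimum-jerk ballistic reaches whose peak endpoint speed is drawn near
  the subject's maximal voluntary velocity (MVV);
* the triphasic agonist/antagonist EMG pattern of ballistic movement
  (extensor burst leading movement onset, flexor braking burst after peak
  speed), with cohort-dependent background tone;
* ramp-and-hold elbow-extension perturbations injected at %MVV phase
  triggers via the perturbation module;
* perturbation-evoked short- and long-latency reflex bursts in the
  stretched elbow flexor, threshold-linear in stretch velocity and scaled
  down by reciprocal inhibition from the active antagonist;
* raw EMG as envelope-modulated broadband noise plus 60 Hz mains
  interference, so the conditioning chain is genuinely exercised.

Muscle-stretch velocity is proxied by elbow angular extension velocity
(any constant moment arm is absorbed into the reflex gains).  Everything
is deterministic under a fixed seed; session-level seeds derive per-trial
seeds through a spawned ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .kinematics import ArmModel, _unit
from .perturbation import (
    PerturbationSpec,
    PhaseTriggerConfig,
    PHASES,
    _profile_integral,
    detect_trigger,
)

__all__ = [
    "MUSCLES",
    "SubjectProfile",
    "TaskGeometry",
    "TrialRecording",
    "SessionDataset",
    "stroke_preset",
    "control_preset",
    "default_arm",
    "minimum_jerk",
    "simulate_reach",
    "synthesize_emg",
    "simulate_mvc_trials",
    "session_schedule",
    "generate_session",
]

MUSCLES = ("BIC", "TRI", "PEC", "ADL", "MDL", "PDL")

SAMPLING_RATE = 1000.0
PRE_MOVEMENT_REST = 3.0  # s of rest between home acquisition and movement
HOME_SETTLE = 0.2  # s of recording before the home target is acquired
POST_REACH = 0.8  # s recorded after the reach completes
RELAX_TAU = 0.25  # s, passive decay of the perturbation displacement


@dataclass(frozen=True)
class SubjectProfile:
    """Cohort parameters controlling the synthetic participant.

    Reflex gains are in (% MVC)/(deg/s above threshold); the reflex
    threshold is on muscle-stretch (elbow extension) velocity.  The
    reciprocal-inhibition coefficient rho in [0, 1] scales reflex bursts
    by ``1 - rho * antagonist_activation``.
    """

    cohort: str = "control"
    subject_id: str = "S01"
    mvv_target: float = 1.09  # m/s
    mvc_amplitude: dict[str, float] = field(
        default_factory=lambda: {m: 1.0 for m in MUSCLES}
    )
    background_tone: dict[str, float] = field(
        default_factory=lambda: {m: 1.6 for m in MUSCLES}
    )  # % MVC
    reflex_threshold: float = 300.0  # deg/s of stretch velocity
    slr_gain: float = 0.12
    llr_gain: float = 0.08
    slr_latency: float = 0.025
    llr_latency: float = 0.075
    reciprocal_inhibition: float = 0.9
    agonist_onset_lead: float = 0.110
    agonist_sustain: float = 0.20  # s, duration of the extensor plateau
    braking_amplitude: float = 0.35  # flexor braking burst, fraction of MVC
    mains_amplitude: float = 0.10  # raw units
    peak_speed_jitter: float = 0.05  # fractional SD of the per-trial peak speed

    def __post_init__(self) -> None:
        if self.mvv_target <= 0:
            raise ValueError("MVV_target must be positive")
        if not 0.0 <= self.reciprocal_inhibition <= 1.0:
            raise ValueError("reciprocal_inhibition must be in [0, 1]")
        if not self.slr_latency < self.llr_latency:
            raise ValueError("SLR latency must precede LLR latency")


def control_preset(**overrides) -> SubjectProfile:
    """Neurologically intact participant: higher MVV, low background tone,
    stretch-velocity threshold above the perturbation plateau (no reflex at
    the tested velocities), effective reciprocal inhibition."""
    return replace(SubjectProfile(), **overrides)


def stroke_preset(**overrides) -> SubjectProfile:
    """Chronic hemiparetic preset: slower reaches, elevated flexor tone,
    lowered reflex threshold, weakened reciprocal inhibition, sustained
    extensor activity, and a minimal flexor braking burst."""
    base = SubjectProfile(
        cohort="stroke",
        mvv_target=0.78,
        background_tone={m: 3.9 for m in MUSCLES},
        reflex_threshold=150.0,
        slr_gain=0.15,
        llr_gain=0.10,
        reciprocal_inhibition=0.3,
        agonist_onset_lead=0.140,
        agonist_sustain=0.60,
        braking_amplitude=0.08,
    )
    return replace(base, **overrides)


@dataclass(frozen=True)
class TaskGeometry:
    """Start and reaching target in the table frame (m)."""

    start: tuple[float, float] = (0.25, 0.0)
    target: tuple[float, float] = (0.58, 0.0)

    @property
    def distance(self) -> float:
        return float(np.hypot(self.target[0] - self.start[0], self.target[1] - self.start[1]))


def default_arm() -> ArmModel:
    return ArmModel(upper_arm_length=0.30, forearm_length=0.35)


@dataclass
class TrialRecording:
    """1 kHz multichannel trial: kinematics, raw EMG, events, metadata."""

    time: np.ndarray
    position: np.ndarray  # (n, 2) m
    velocity: np.ndarray  # (n, 2) m/s
    shoulder_angle: np.ndarray  # deg
    elbow_angle: np.ndarray  # deg
    shoulder_velocity: np.ndarray  # deg/s
    elbow_velocity: np.ndarray  # deg/s, extension-positive
    emg: dict[str, np.ndarray]
    events: dict[str, float]
    sampling_rate: float = SAMPLING_RATE
    meta: dict = field(default_factory=dict)
    truth_envelopes: dict[str, np.ndarray] | None = None  # % MVC, simulator truth

    @property
    def speed(self) -> np.ndarray:
        return np.hypot(self.velocity[:, 0], self.velocity[:, 1])

    @property
    def perturbed(self) -> bool:
        return "perturbation_onset" in self.events

    @property
    def n_samples(self) -> int:
        return len(self.time)

    def validate(self) -> None:
        dt = np.diff(self.time)
        if not np.allclose(dt, 1.0 / self.sampling_rate, atol=1e-9):
            raise ValueError("non-uniform sampling")
        for name, t in self.events.items():
            if not (self.time[0] - 1e-9 <= t <= self.time[-1] + 1e-9):
                raise ValueError(f"event {name!r} at {t} s outside the trial span")
        if self.perturbed != bool(self.meta.get("perturbed", self.perturbed)):
            raise ValueError("perturbed flag inconsistent with events")


@dataclass
class SessionDataset:
    """All trials of one synthetic session."""

    subject: SubjectProfile
    arm: ArmModel
    geometry: TaskGeometry
    mvc_trials: dict[str, list[TrialRecording]]
    mvv_trials: list[TrialRecording]
    task_trials: list[TrialRecording]
    seed: int | None = None


def minimum_jerk(tau: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Normalized minimum-jerk position s(tau) and derivative ds/dtau on
    [0, 1]; peak ds/dtau = 1.875 at tau = 0.5."""
    tau = np.clip(np.asarray(tau, float), 0.0, 1.0)
    s = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    ds = 30 * tau**2 - 60 * tau**3 + 30 * tau**4
    return s, ds


def _ik_arrays(arm: ArmModel, pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-link inverse kinematics (same branch rule as
    :func:`reachreflex.kinematics.inverse_kinematics`)."""
    p = pos - np.asarray(arm.shoulder_position, float)
    r = np.hypot(p[:, 0], p[:, 1])
    lu, lf = arm.upper_arm_length, arm.forearm_length
    cos_e = np.clip((lu**2 + lf**2 - r**2) / (2 * lu * lf), -1.0, 1.0)
    elbow = np.degrees(np.arccos(cos_e))
    cos_b = np.clip((lu**2 + r**2 - lf**2) / (2 * lu * r), -1.0, 1.0)
    beta = np.degrees(np.arccos(cos_b))
    shoulder = np.degrees(np.arctan2(p[:, 1], p[:, 0])) - arm.branch_sign * beta
    return shoulder, elbow


def _fk_arrays(arm: ArmModel, shoulder: np.ndarray, elbow: np.ndarray) -> np.ndarray:
    sh = np.asarray(arm.shoulder_position, float)
    elb = sh + arm.upper_arm_length * _unit(shoulder)
    heading = shoulder + arm.branch_sign * (180.0 - elbow)
    return elb + arm.forearm_length * _unit(heading)


def _pulse(
    t: np.ndarray, t_on: float, rise: float, plateau: float, fall: float, amp: float
) -> np.ndarray:
    """Flat-top pulse with raised-cosine edges, starting at ``t_on``."""
    out = np.zeros_like(t)
    up = (t >= t_on) & (t < t_on + rise)
    out[up] = 0.5 * (1 - np.cos(np.pi * (t[up] - t_on) / rise))
    flat = (t >= t_on + rise) & (t < t_on + rise + plateau)
    out[flat] = 1.0
    t_f = t_on + rise + plateau
    down = (t >= t_f) & (t < t_f + fall)
    out[down] = 0.5 * (1 + np.cos(np.pi * (t[down] - t_f) / fall))
    return amp * out


def _reflex_burst(t: np.ndarray, start: float, duration: float, amp: float) -> np.ndarray:
    """Reflex burst: full amplitude across [start, start+duration] with
    short raised-cosine flanks outside the window, so the window-averaged
    amplitude equals ``amp``."""
    flank = 0.006
    return _pulse(t, start - flank, flank, duration, flank, amp)


def synthesize_emg(
    subject: SubjectProfile,
    time: np.ndarray,
    elbow_velocity: np.ndarray,
    movement_onset: float | None,
    peak_speed_time: float | None,
    perturbation_onset: float | None,
    rng: np.random.Generator,
    perturbation_duration: float = 0.070,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Raw EMG channels (and the % MVC truth envelopes) for one trial.

    Each muscle's activation envelope is background tone plus volitional
    bursts; the elbow flexor (BIC) additionally carries threshold-linear
    reflex bursts at the SLR/LLR latencies when the perturbation's stretch
    velocity exceeds the subject's threshold, scaled by reciprocal
    inhibition from the instantaneous extensor activation.  The raw signal
    is the envelope modulating zero-mean broadband noise plus 60 Hz mains.
    """
    t = np.asarray(time, float)
    env = {m: np.full_like(t, subject.background_tone[m] / 100.0) for m in MUSCLES}

    if movement_onset is not None:
        tri_on = movement_onset - subject.agonist_onset_lead
        env["TRI"] += _pulse(t, tri_on, 0.020, subject.agonist_sustain, 0.150, 0.55)
        env["PEC"] += _pulse(t, tri_on + 0.010, 0.030, subject.agonist_sustain, 0.150, 0.30)
        env["ADL"] += _pulse(t, tri_on + 0.010, 0.030, subject.agonist_sustain, 0.150, 0.30)
        env["MDL"] += _pulse(t, movement_onset, 0.050, 0.150, 0.150, 0.05)
        env["PDL"] += _pulse(t, movement_onset, 0.050, 0.150, 0.150, 0.05)
    if peak_speed_time is not None:
        # flexor braking burst after peak speed, then a second extensor burst
        env["BIC"] += _pulse(t, peak_speed_time + 0.050, 0.050, 0.100, 0.150,
                             subject.braking_amplitude)
        env["TRI"] += _pulse(t, peak_speed_time + 0.250, 0.050, 0.080, 0.120, 0.20)

    if perturbation_onset is not None:
        i0 = int(round((perturbation_onset - t[0]) * SAMPLING_RATE))
        i1 = min(i0 + int(round(perturbation_duration * SAMPLING_RATE)) + 1, len(t))
        stretch_peak = float(np.max(elbow_velocity[i0:i1])) if i1 > i0 else 0.0
        drive = max(0.0, stretch_peak - subject.reflex_threshold)
        if drive > 0.0:
            antagonist = float(np.clip(env["TRI"][i0], 0.0, 1.0))
            scale = 1.0 - subject.reciprocal_inhibition * antagonist
            window = subject.llr_latency - subject.slr_latency
            slr_amp = subject.slr_gain * drive * scale / 100.0
            llr_amp = subject.llr_gain * drive * scale / 100.0
            env["BIC"] += _reflex_burst(t, perturbation_onset + subject.slr_latency, window, slr_amp)
            env["BIC"] += _reflex_burst(t, perturbation_onset + subject.llr_latency, window, llr_amp)

    raw: dict[str, np.ndarray] = {}
    mains_phase = rng.uniform(0, 2 * np.pi, size=len(MUSCLES))
    for k, m in enumerate(MUSCLES):
        noise = rng.standard_normal(len(t))
        raw[m] = env[m] * subject.mvc_amplitude[m] * noise + subject.mains_amplitude * np.sin(
            2 * np.pi * 60.0 * t + mains_phase[k]
        )
    truth = {m: env[m] * 100.0 for m in MUSCLES}
    return raw, truth


def simulate_reach(
    subject: SubjectProfile,
    arm: ArmModel,
    geometry: TaskGeometry | None = None,
    phase: str | None = None,
    seed: int = 0,
    spec: PerturbationSpec | None = None,
    trigger_config: PhaseTriggerConfig | None = None,
    peak_speed: float | None = None,
) -> TrialRecording:
    """One ballistic reaching trial, optionally perturbed at ``phase``.

    The endpoint follows a minimum-jerk path from the start to the
    reaching target with a per-trial peak speed drawn near the subject's
    MVV (``peak_speed`` pins it for noiseless checks); joint kinematics
    follow by inverse kinematics.  When a phase is requested, the ramp-
    and-hold perturbation is injected at the detected trigger: elbow
    extension velocity follows the commanded profile on top of the
    volitional motion, and the added displacement then decays passively
    (the subject is instructed to relax, not to react).  If the trigger
    threshold is never reached the trial is returned unperturbed with
    ``meta['trigger_failed'] = True``.
    """
    geometry = geometry or TaskGeometry()
    spec = spec or PerturbationSpec()
    trigger_config = trigger_config or PhaseTriggerConfig()
    rng = np.random.default_rng(seed)

    if peak_speed is None:
        vp = subject.mvv_target * (1.0 + subject.peak_speed_jitter * rng.standard_normal())
        vp = max(vp, 0.3 * subject.mvv_target)
    else:
        vp = peak_speed
    d = geometry.distance
    duration = 1.875 * d / vp
    home_t = HOME_SETTLE
    onset_t = home_t + PRE_MOVEMENT_REST
    total = onset_t + duration + POST_REACH
    n = int(round(total * SAMPLING_RATE)) + 1
    t = np.arange(n) / SAMPLING_RATE

    tau = (t - onset_t) / duration
    s, ds = minimum_jerk(tau)
    direction = (np.asarray(geometry.target) - np.asarray(geometry.start)) / d
    pos = np.asarray(geometry.start) + np.outer(s * d, direction)
    shoulder, elbow = _ik_arrays(arm, pos)
    peak_time = onset_t + duration / 2.0  # volitional speed peak (minimum jerk)

    events = {"home_acquired": home_t, "movement_onset": onset_t}
    meta = {
        "subject_id": subject.subject_id,
        "cohort": subject.cohort,
        "seed": seed,
        "phase": phase,
        "perturbed": False,
        "peak_speed_drawn": vp,
    }

    if phase is not None:
        vel_vol = np.gradient(pos, axis=0) * SAMPLING_RATE
        speed_vol = np.hypot(vel_vol[:, 0], vel_vol[:, 1])
        trig = detect_trigger(
            trigger_config, phase, speed_vol, subject.mvv_target, home_t,
            sampling_rate=SAMPLING_RATE,
        )
        if trig is None:
            meta["trigger_failed"] = True
        else:
            # position-control mode: elbow velocity follows the commanded
            # ramp-and-hold profile exactly during the window, then the
            # displacement relative to the volitional path decays passively
            # back onto it once admittance control resumes
            i = int(round(trig * SAMPLING_RATE))
            dt = 1.0 / SAMPLING_RATE
            v0 = (elbow[i] - elbow[i - 1]) / dt if i > 0 else 0.0
            rel = t - trig
            elbow_pert = elbow.copy()
            active = (rel >= 0.0) & (rel <= spec.duration)
            elbow_pert[active] = elbow[i] + _profile_integral(spec, v0, rel[active])
            t_end = trig + spec.duration
            j = int(round(t_end * SAMPLING_RATE))
            offset_end = elbow[i] + spec.displacement(v0) - elbow[min(j, n - 1)]
            after = rel > spec.duration
            elbow_pert[after] = elbow[after] + offset_end * np.exp(
                -(rel[after] - spec.duration) / RELAX_TAU
            )
            elbow = np.minimum(elbow_pert, 180.0)
            pos = _fk_arrays(arm, shoulder, elbow)
            events["perturbation_onset"] = trig
            events["mode_switch"] = t_end
            meta["perturbed"] = True
            meta["perturbation_v0"] = v0

    vel = np.gradient(pos, axis=0) * SAMPLING_RATE
    shoulder_vel = np.gradient(shoulder) * SAMPLING_RATE
    elbow_vel = np.gradient(elbow) * SAMPLING_RATE

    raw, truth = synthesize_emg(
        subject, t, elbow_vel, onset_t, peak_time,
        events.get("perturbation_onset"), rng,
        perturbation_duration=spec.duration,
    )
    return TrialRecording(
        time=t, position=pos, velocity=vel,
        shoulder_angle=shoulder, elbow_angle=elbow,
        shoulder_velocity=shoulder_vel, elbow_velocity=elbow_vel,
        emg=raw, events=events, meta=meta, truth_envelopes=truth,
    )


def simulate_mvc_trials(
    subject: SubjectProfile,
    arm: ArmModel,
    geometry: TaskGeometry | None = None,
    seed: int = 0,
    n_trials: int = 3,
) -> dict[str, list[TrialRecording]]:
    """Isometric maximal-contraction trials: per muscle, ``n_trials``
    recordings with a ramped 3 s plateau at the muscle's MVC amplitude
    (other channels stay at background tone).  The posture is static at
    the start target."""
    geometry = geometry or TaskGeometry()
    ss = np.random.SeedSequence(seed)
    out: dict[str, list[TrialRecording]] = {}
    total = 4.5
    n = int(round(total * SAMPLING_RATE)) + 1
    t = np.arange(n) / SAMPLING_RATE
    shoulder0, elbow0 = _ik_arrays(arm, np.asarray(geometry.start, float)[None, :])
    for muscle in MUSCLES:
        trials = []
        for k in range(n_trials):
            rng = np.random.default_rng(ss.spawn(1)[0])
            env = {m: np.full(n, subject.background_tone[m] / 100.0) for m in MUSCLES}
            env[muscle] += _pulse(t, 0.5, 0.25, 3.0, 0.25, 1.0)
            raw = {}
            for j, m in enumerate(MUSCLES):
                noise = rng.standard_normal(n)
                raw[m] = env[m] * subject.mvc_amplitude[m] * noise + (
                    subject.mains_amplitude * np.sin(2 * np.pi * 60.0 * t + rng.uniform(0, 2 * np.pi))
                )
            pos = np.repeat(np.asarray(geometry.start, float)[None, :], n, axis=0)
            trials.append(
                TrialRecording(
                    time=t, position=pos, velocity=np.zeros((n, 2)),
                    shoulder_angle=np.full(n, shoulder0[0]),
                    elbow_angle=np.full(n, elbow0[0]),
                    shoulder_velocity=np.zeros(n), elbow_velocity=np.zeros(n),
                    emg=raw, events={"home_acquired": 0.0},
                    meta={"subject_id": subject.subject_id, "mvc_muscle": muscle,
                          "seed": seed, "trial": k, "perturbed": False},
                    truth_envelopes={m: env[m] * 100.0 for m in MUSCLES},
                )
            )
        out[muscle] = trials
    return out


def session_schedule(
    n_perturbed_per_phase: int, rng: np.random.Generator
) -> list[str | None]:
    """Trial order for a session: perturbed catch trials (random phase
    among those still owed) each followed by Uniform{1..5} unperturbed
    trials, until every phase has its quota.  ``None`` = unperturbed."""
    remaining = {p: n_perturbed_per_phase for p in PHASES}
    order: list[str | None] = []
    while any(v > 0 for v in remaining.values()):
        open_phases = [p for p in PHASES if remaining[p] > 0]
        phase = open_phases[int(rng.integers(len(open_phases)))]
        remaining[phase] -= 1
        order.append(phase)
        order.extend([None] * int(rng.integers(1, 6)))
    return order


def generate_session(
    subject: SubjectProfile,
    arm: ArmModel | None = None,
    geometry: TaskGeometry | None = None,
    n_perturbed_per_phase: int = 3,
    seed: int = 0,
    spec: PerturbationSpec | None = None,
    trigger_config: PhaseTriggerConfig | None = None,
    n_unperturbed: int | None = None,
) -> SessionDataset:
    """A full synthetic session: MVC trials, 3 MVV reaches, and the
    interleaved catch/unperturbed task schedule.

    A perturbed trial whose trigger threshold is never reached stays in
    the dataset unperturbed and the phase's quota is re-attempted.  When
    ``n_unperturbed`` is given the random schedule is replaced by a fixed
    count of unperturbed trials after the catch trials.
    """
    arm = arm or default_arm()
    geometry = geometry or TaskGeometry()
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])

    def next_seed() -> int:
        return int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))

    mvc = simulate_mvc_trials(subject, arm, geometry, seed=next_seed())
    mvv = [
        simulate_reach(subject, arm, geometry, phase=None, seed=next_seed(),
                       spec=spec, trigger_config=trigger_config)
        for _ in range(3)
    ]

    if n_unperturbed is not None:
        order: list[str | None] = [p for p in PHASES for _ in range(n_perturbed_per_phase)]
        order += [None] * n_unperturbed
    else:
        order = session_schedule(n_perturbed_per_phase, rng)

    task: list[TrialRecording] = []
    pending = list(order)
    while pending:
        phase = pending.pop(0)
        trial = simulate_reach(subject, arm, geometry, phase=phase, seed=next_seed(),
                               spec=spec, trigger_config=trigger_config)
        task.append(trial)
        if phase is not None and not trial.perturbed:
            pending.append(phase)  # quota not met; retry at the end
    return SessionDataset(subject, arm, geometry, mvc, mvv, task, seed=seed)
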