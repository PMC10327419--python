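"""Ramp-and-hold angular-velocity perturbations and %MVV phase triggers.

A perturbation rises linearly from the elbow angular velocity at onset
(``v0``) to a plateau, holds, and returns to ``v0``.  The default profile
(20 ms ramp-up, 270 deg/s plateau held 30 ms, 20 ms ramp-down) sweeps
13.5 deg of elbow extension when started from rest.  Triggers fire either
at a fixed delay after home-target acquisition (pre-motion) or at the
first crossing of a fraction of the subject's maximal voluntary velocity
(MVV) during the acceleration phase of the reach.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinematics import ArmModel, JointState, arc_point, forward_kinematics

__all__ = [
    "PerturbationSpec",
    "PhaseTriggerConfig",
    "PerturbationError",
    "SafetyResult",
    "CommandedTrajectory",
    "velocity_profile",
    "tick_increments",
    "detect_trigger",
    "acceleration_phase",
    "apply_arc_increments",
    "commanded_endpoint_trajectory",
    "safety_check",
    "PHASES",
]

PHASES = ("pre", "early", "peak")


class PerturbationError(ValueError):
    pass


@dataclass(frozen=True)
class PerturbationSpec:
    """Ramp-and-hold elbow-extension perturbation parameters.

    Durations in seconds, velocities in deg/s.  The plateau must respect
    the safety limit (default 300 deg/s endpoint-equivalent)."""

    plateau_velocity: float = 270.0
    ramp_up: float = 0.020
    hold: float = 0.030
    ramp_down: float = 0.020
    direction: str = "elbow_extension"
    update_rate: float = 1000.0
    safety_velocity_limit: float = 300.0

    def __post_init__(self) -> None:
        if min(self.ramp_up, self.hold, self.ramp_down) <= 0:
            raise PerturbationError("all durations must be > 0")
        if self.plateau_velocity > self.safety_velocity_limit:
            raise PerturbationError(
                f"plateau {self.plateau_velocity} deg/s exceeds safety limit "
                f"{self.safety_velocity_limit} deg/s"
            )
        if self.direction != "elbow_extension":
            raise PerturbationError("only elbow_extension perturbations are supported")

    @property
    def duration(self) -> float:
        return self.ramp_up + self.hold + self.ramp_down

    @property
    def n_ticks(self) -> int:
        return int(round(self.duration * self.update_rate))

    def displacement(self, v0: float = 0.0) -> float:
        """Closed-form swept angle (deg): trapezoid of the velocity profile."""
        return v0 * self.duration + (self.plateau_velocity - v0) * (
            self.ramp_up / 2.0 + self.hold + self.ramp_down / 2.0
        )


@dataclass(frozen=True)
class PhaseTriggerConfig:
    """When each perturbation phase fires.

    pre-motion: a fixed delay after home-target acquisition.  early/peak
    motion: the first sample in the acceleration phase (movement onset up
    to the first speed peak) where endpoint speed reaches the stated
    fraction of MVV."""

    pre_motion_delay: float = 2.0
    early_fraction: float = 0.15
    peak_fraction: float = 0.90
    onset_fraction: float = 0.05  # defines movement onset for the phase bounds

    def fraction(self, phase: str) -> float:
        return {"early": self.early_fraction, "peak": self.peak_fraction}[phase]


def _profile_value(spec: PerturbationSpec, v0: float, t) -> np.ndarray:
    """Piecewise-linear profile value at time(s) t in [0, duration]."""
    t = np.asarray(t, float)
    vp = spec.plateau_velocity
    t1, t2 = spec.ramp_up, spec.ramp_up + spec.hold
    out = np.full_like(t, vp)
    up = t < t1
    out[up] = v0 + (vp - v0) * t[up] / spec.ramp_up
    down = t > t2
    out[down] = vp - (vp - v0) * np.minimum((t[down] - t2) / spec.ramp_down, 1.0)
    return out


def velocity_profile(spec: PerturbationSpec, v0: float = 0.0) -> np.ndarray:
    """Sampled angular-velocity series (deg/s) at the update rate.

    Samples run from t=0 to t=duration inclusive, so both endpoints equal
    ``v0`` exactly.  Raises if ``v0`` is at or above the plateau (the
    perturbation would decelerate the stretch rather than drive it).
    """
    if v0 >= spec.plateau_velocity:
        raise PerturbationError(
            f"onset velocity {v0} deg/s at/above plateau {spec.plateau_velocity} deg/s"
        )
    t = np.arange(spec.n_ticks + 1) / spec.update_rate
    v = _profile_value(spec, v0, t)
    v[0] = v[-1] = v0
    return v


def _profile_integral(spec: PerturbationSpec, v0: float, t) -> np.ndarray:
    """Antiderivative of the piecewise-linear profile at time(s) t (deg)."""
    t = np.asarray(t, float)
    vp = spec.plateau_velocity
    t1, t2, T = spec.ramp_up, spec.ramp_up + spec.hold, spec.duration
    f1 = v0 * t1 + (vp - v0) * t1 / 2.0
    f2 = f1 + vp * spec.hold
    tc = np.clip(t, 0.0, T)
    out = np.where(
        tc <= t1,
        v0 * tc + (vp - v0) * tc**2 / (2.0 * spec.ramp_up),
        np.where(
            tc <= t2,
            f1 + vp * (tc - t1),
            f2 + vp * (tc - t2) - (vp - v0) * (tc - t2) ** 2 / (2.0 * spec.ramp_down),
        ),
    )
    return out + v0 * np.maximum(t - T, 0.0)


def tick_increments(spec: PerturbationSpec, v0: float = 0.0) -> np.ndarray:
    """Exact per-tick angular increments (deg): the analytic integral of
    the piecewise-linear profile over each tick, so the cumulative
    displacement is discretization-invariant (sums to the trapezoid
    closed form regardless of update rate)."""
    if v0 >= spec.plateau_velocity:
        raise PerturbationError(
            f"onset velocity {v0} deg/s at/above plateau {spec.plateau_velocity} deg/s"
        )
    dt = 1.0 / spec.update_rate
    n_full = int(np.floor(spec.duration * spec.update_rate + 1e-9))
    edges = np.arange(n_full + 1) * dt
    if edges[-1] < spec.duration - 1e-12:  # rate does not divide duration
        edges = np.append(edges, spec.duration)
    F = _profile_integral(spec, v0, edges)
    return np.diff(F)


def acceleration_phase(
    speed: np.ndarray, mvv: float, config: PhaseTriggerConfig
) -> tuple[int, int] | None:
    """[onset, first speed peak) sample bounds of the acceleration phase.

    Movement onset is the first crossing of ``onset_fraction * MVV``; the
    phase ends at the first local speed maximum at or after onset.  Returns
    None when the onset threshold is never crossed.
    """
    speed = np.asarray(speed, float)
    above = np.nonzero(speed >= config.onset_fraction * mvv)[0]
    if above.size == 0:
        return None
    onset = int(above[0])
    d = np.diff(speed[onset:])
    falling = np.nonzero(d < 0)[0]
    peak = onset + int(falling[0]) if falling.size else speed.size - 1
    return onset, peak


def detect_trigger(
    config: PhaseTriggerConfig,
    phase: str,
    speed: np.ndarray,
    mvv: float,
    home_acquired_time: float,
    sampling_rate: float = 1000.0,
    t0: float = 0.0,
) -> float | None:
    """Time at which the perturbation for ``phase`` fires, or None.

    ``speed`` is the endpoint-speed stream sampled at ``sampling_rate``
    starting at time ``t0``.  pre-motion returns ``home_acquired_time +
    pre_motion_delay``; early/peak return the first sample in the
    acceleration phase whose speed reaches the phase's %MVV threshold.
    A threshold never crossed before the speed peak yields None (the trial
    cannot be perturbed at that phase).
    """
    if phase not in PHASES:
        raise ValueError(f"unknown phase {phase!r}; expected one of {PHASES}")
    if mvv <= 0:
        raise ValueError("MVV must be positive")
    if phase == "pre":
        return home_acquired_time + config.pre_motion_delay
    bounds = acceleration_phase(speed, mvv, config)
    if bounds is None:
        return None
    onset, peak = bounds
    seg = np.asarray(speed[onset:peak], float)
    hit = np.nonzero(seg >= config.fraction(phase) * mvv)[0]
    if hit.size == 0:
        return None
    return t0 + (onset + int(hit[0])) / sampling_rate


@dataclass
class CommandedTrajectory:
    """Commanded endpoint samples during a perturbation window."""

    start_index: int
    positions: np.ndarray  # (n_ticks+1, 2), first row = endpoint at onset
    elbow_angles: np.ndarray  # commanded elbow angle at each tick edge
    truncated: bool = False


def apply_arc_increments(
    arm: ArmModel,
    shoulder_angles: np.ndarray,
    elbow_start: float,
    increments: np.ndarray,
) -> CommandedTrajectory:
    """Advance the endpoint along the elbow-centered arc tick by tick.

    ``shoulder_angles`` gives the (possibly moving) shoulder angle at each
    tick edge, so the arc center is recomputed from the instantaneous elbow
    position.  An all-zero increment array reproduces the volitional
    endpoint path unchanged.  Motion past full elbow extension truncates
    the commanded stream and flags the trial.
    """
    shoulder_angles = np.asarray(shoulder_angles, float)
    n = len(increments)
    if len(shoulder_angles) != n + 1:
        raise ValueError("need one shoulder angle per tick edge (n_increments + 1)")
    elbow = float(elbow_start)
    angles = np.empty(n + 1)
    pos = np.empty((n + 1, 2))
    angles[0] = elbow
    pos[0], _ = forward_kinematics(arm, JointState(shoulder_angles[0], elbow))
    truncated = False
    for k in range(n):
        js = JointState(shoulder_angles[k + 1], elbow)
        p, clamped = arc_point(arm, js, float(increments[k]))
        elbow = min(elbow + float(increments[k]), 180.0)
        angles[k + 1] = elbow
        pos[k + 1] = p
        if clamped:
            truncated = True
            angles = angles[: k + 2]
            pos = pos[: k + 2]
            break
    return CommandedTrajectory(0, pos, angles, truncated)


def commanded_endpoint_trajectory(
    arm: ArmModel,
    shoulder_angle: np.ndarray,
    elbow_angle: np.ndarray,
    spec: PerturbationSpec,
    trigger_index: int,
    freeze_shoulder: bool = False,
) -> CommandedTrajectory:
    """Commanded endpoint positions for a perturbation starting at
    ``trigger_index`` of the volitional joint-angle streams (1 kHz).

    The elbow angular velocity at onset (finite difference of the stream)
    is the profile's ``v0``.  During the window the shoulder either keeps
    moving at its onset angular velocity (default; the controller updates
    the arc center every tick to follow the limb) or is frozen.
    """
    shoulder_angle = np.asarray(shoulder_angle, float)
    elbow_angle = np.asarray(elbow_angle, float)
    if not (0 <= trigger_index < len(elbow_angle)):
        raise PerturbationError("trigger index outside the stream")
    dt = 1.0 / spec.update_rate
    i = trigger_index
    v0 = (elbow_angle[i] - elbow_angle[i - 1]) / dt if i > 0 else 0.0
    inc = tick_increments(spec, v0)
    if freeze_shoulder:
        sh = np.full(len(inc) + 1, shoulder_angle[i])
    else:
        w0 = (shoulder_angle[i] - shoulder_angle[i - 1]) / dt if i > 0 else 0.0
        sh = shoulder_angle[i] + w0 * dt * np.arange(len(inc) + 1)
    traj = apply_arc_increments(arm, sh, float(elbow_angle[i]), inc)
    traj.start_index = trigger_index
    return traj


@dataclass
class SafetyResult:
    passed: bool
    max_velocity: float
    limit: float
    reason: str = ""


def safety_check(
    spec: PerturbationSpec,
    commanded_elbow_velocity: np.ndarray,
    endpoint_positions: np.ndarray | None = None,
    work_area: tuple[tuple[float, float], tuple[float, float]] | None = None,
) -> SafetyResult:
    """Validate a commanded stream against the endpoint velocity limit and
    (optionally) the rectangular work-area bounds.

    The limit applies to the *commanded* equivalent elbow angular velocity;
    an empty stream passes vacuously.
    """
    v = np.asarray(commanded_elbow_velocity, float)
    vmax = float(np.max(np.abs(v))) if v.size else 0.0
    if vmax > spec.safety_velocity_limit:
        return SafetyResult(
            False,
            vmax,
            spec.safety_velocity_limit,
            f"commanded velocity {vmax:.1f} deg/s exceeds limit "
            f"{spec.safety_velocity_limit:.1f} deg/s",
        )
    if endpoint_positions is not None and work_area is not None:
        p = np.asarray(endpoint_positions, float)
        (xlo, xhi), (ylo, yhi) = work_area
        if p.size and (
            p[:, 0].min() < xlo or p[:, 0].max() > xhi
            or p[:, 1].min() < ylo or p[:, 1].max() > yhi
        ):
            return SafetyResult(
                False, vmax, spec.safety_velocity_limit,
                "commanded endpoint leaves the configured work area",
            )
    return SafetyResult(True, vmax, spec.safety_velocity_limit)
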