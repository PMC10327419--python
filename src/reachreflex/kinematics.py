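"""Planar two-link arm model: forward/inverse kinematics and the
elbow-centered arc geometry used by velocity perturbations.

Conventions
-----------
The table frame has its origin at the shoulder (configurable), +x pointing
anteriorly (toward the reaching target) and +y toward the contralateral
side.  The shoulder angle is measured CCW-positive from +x to the
upper-arm vector.  The elbow angle is the *interior* angle between upper
arm and forearm, so 180 deg is full extension and an elbow-extension
perturbation increases it.  Handedness selects the elbow branch: for a
right arm, elbow flexion rotates the forearm CCW relative to the upper
arm; for a left arm, CW.  Within a trial the branch never switches.

The task plane sits at a fixed shoulder abduction, so abduction is a
constant of the setup, not a state, and endpoint speed reduces to the
planar speed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ArmModel",
    "JointState",
    "EndpointState",
    "KinematicsError",
    "UnreachableError",
    "SingularConfigurationError",
    "forward_kinematics",
    "elbow_position",
    "inverse_kinematics",
    "joint_velocities_from_endpoint",
    "arc_point",
]

#: Default physiological elbow range, degrees (interior angle).
DEFAULT_ELBOW_RANGE = (30.0, 180.0)

#: Tolerance band (meters) within which a near-full-extension endpoint is
#: clamped to 180 deg rather than rejected.
FULL_EXTENSION_TOL = 1e-6


class KinematicsError(ValueError):
    """Base class for kinematic domain errors."""


class UnreachableError(KinematicsError):
    """Endpoint outside the reachable annulus."""


class SingularConfigurationError(KinematicsError):
    """Jacobian is singular (elbow at 0 or 180 deg)."""


@dataclass(frozen=True)
class ArmModel:
    """Participant-specific planar arm: segment lengths, shoulder location
    in the table frame (assumed constant for a session), and handedness."""

    upper_arm_length: float
    forearm_length: float
    shoulder_position: tuple[float, float] = (0.0, 0.0)
    handedness: str = "right"
    elbow_range: tuple[float, float] = DEFAULT_ELBOW_RANGE

    def __post_init__(self) -> None:
        if self.upper_arm_length <= 0 or self.forearm_length <= 0:
            raise KinematicsError("segment lengths must be strictly positive")
        if self.handedness not in ("left", "right"):
            raise KinematicsError(f"handedness must be 'left' or 'right', got {self.handedness!r}")
        lo, hi = self.elbow_range
        if not (0.0 <= lo < hi <= 180.0):
            raise KinematicsError(f"invalid elbow range {self.elbow_range}")

    @property
    def branch_sign(self) -> float:
        """+1 for a right arm, -1 for a left arm.

        Forearm heading = shoulder_angle + branch_sign * (180 - elbow_angle).
        """
        return 1.0 if self.handedness == "right" else -1.0

    @property
    def reach_min(self) -> float:
        return abs(self.upper_arm_length - self.forearm_length)

    @property
    def reach_max(self) -> float:
        return self.upper_arm_length + self.forearm_length


@dataclass
class JointState:
    """Shoulder/elbow angles (deg) and angular velocities (deg/s).

    Elbow velocity is extension-positive (increasing interior angle)."""

    shoulder_angle: float
    elbow_angle: float
    shoulder_velocity: float = 0.0
    elbow_velocity: float = 0.0


@dataclass
class EndpointState:
    """Endpoint position (m), velocity (m/s) and speed (m/s) in the table
    frame.  Speed is the Euclidean norm of the planar velocity."""

    position: np.ndarray
    velocity: np.ndarray = field(default_factory=lambda: np.zeros(2))

    @property
    def speed(self) -> float:
        return float(np.hypot(*self.velocity))


def _check_elbow_range(arm: ArmModel, elbow_angle: float) -> None:
    lo, hi = arm.elbow_range
    if not (lo <= elbow_angle <= hi):
        raise KinematicsError(
            f"elbow angle {elbow_angle:.3f} deg outside configured range [{lo}, {hi}]"
        )


def _unit(angle_deg: float | np.ndarray) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    return np.stack([np.cos(a), np.sin(a)], axis=-1)


def elbow_position(arm: ArmModel, joints: JointState) -> np.ndarray:
    """Elbow location in the table frame for the given joint state."""
    return np.asarray(arm.shoulder_position, float) + arm.upper_arm_length * _unit(
        joints.shoulder_angle
    )


def _forearm_heading(arm: ArmModel, shoulder_angle, elbow_angle):
    return shoulder_angle + arm.branch_sign * (180.0 - elbow_angle)


def forward_kinematics(arm: ArmModel, joints: JointState) -> tuple[np.ndarray, np.ndarray]:
    """Map joint angles to endpoint position.

    Returns ``(endpoint, elbow)`` positions in meters, table frame.  Raises
    :class:`KinematicsError` if the elbow angle lies outside the configured
    physiological range.
    """
    _check_elbow_range(arm, joints.elbow_angle)
    elb = elbow_position(arm, joints)
    heading = _forearm_heading(arm, joints.shoulder_angle, joints.elbow_angle)
    endpoint = elb + arm.forearm_length * _unit(heading)
    return endpoint, elb


def inverse_kinematics(arm: ArmModel, endpoint) -> JointState:
    """Closed-form two-link inverse kinematics.

    The elbow branch is fixed by handedness (no per-sample switching), so
    the solution is deterministic.  Points outside the reachable annulus
    raise :class:`UnreachableError`; points within a small tolerance of
    full extension are clamped to 180 deg with a warning.
    """
    p = np.asarray(endpoint, float) - np.asarray(arm.shoulder_position, float)
    r = float(np.hypot(*p))
    lu, lf = arm.upper_arm_length, arm.forearm_length
    if r > arm.reach_max + FULL_EXTENSION_TOL or r < arm.reach_min - FULL_EXTENSION_TOL:
        raise UnreachableError(
            f"endpoint at distance {r:.6f} m outside reachable annulus "
            f"[{arm.reach_min:.6f}, {arm.reach_max:.6f}] m"
        )
    cos_elbow = (lu**2 + lf**2 - r**2) / (2.0 * lu * lf)
    if cos_elbow < -1.0:  # within tolerance of full extension
        if r > arm.reach_max - FULL_EXTENSION_TOL:
            warnings.warn("endpoint at full extension; elbow clamped to 180 deg", stacklevel=2)
        cos_elbow = -1.0
    cos_elbow = min(cos_elbow, 1.0)
    elbow = float(np.degrees(np.arccos(cos_elbow)))
    # interior angle convention: law of cosines gives the angle at the elbow
    # between elbow->shoulder and elbow->endpoint directly
    cos_beta = (lu**2 + r**2 - lf**2) / (2.0 * lu * r)
    beta = float(np.degrees(np.arccos(np.clip(cos_beta, -1.0, 1.0))))
    shoulder = float(np.degrees(np.arctan2(p[1], p[0]))) - arm.branch_sign * beta
    return JointState(shoulder_angle=shoulder, elbow_angle=elbow)


def jacobian(arm: ArmModel, joints: JointState) -> np.ndarray:
    """2x2 Jacobian d(endpoint)/d(shoulder_angle, elbow_angle), m/deg."""
    s = arm.branch_sign
    heading = _forearm_heading(arm, joints.shoulder_angle, joints.elbow_angle)
    du = _unit(joints.shoulder_angle + 90.0)  # d/dtheta of unit vector
    df = _unit(heading + 90.0)
    col_s = arm.upper_arm_length * du + arm.forearm_length * df
    col_e = -s * arm.forearm_length * df
    return np.deg2rad(np.stack([col_s, col_e], axis=1))


def joint_velocities_from_endpoint(
    arm: ArmModel, joints: JointState, endpoint_velocity
) -> tuple[float, float]:
    """Solve the linearized (Jacobian) relation for joint angular velocities.

    Returns ``(shoulder_velocity, elbow_velocity)`` in deg/s, elbow
    extension-positive.  Raises :class:`SingularConfigurationError` at full
    extension/flexion where the Jacobian loses rank; estimate by finite
    differences of consecutive inverse-kinematics samples instead.
    """
    sin_e = np.sin(np.deg2rad(joints.elbow_angle))
    if abs(sin_e) < 1e-8:
        raise SingularConfigurationError(
            "elbow at a kinematic singularity (0 or 180 deg); use a "
            "finite-difference fallback on consecutive IK samples"
        )
    v = np.asarray(endpoint_velocity, float)
    qdot = np.linalg.solve(jacobian(arm, joints), v)
    return float(qdot[0]), float(qdot[1])


def arc_point(
    arm: ArmModel, joints: JointState, delta_elbow: float
) -> tuple[np.ndarray, bool]:
    """Endpoint after rotating about the current elbow by ``delta_elbow``
    degrees in the extension direction (radius = forearm length).

    Returns ``(point, clamped)``; ``clamped`` is True when the motion would
    exceed full extension and the elbow was held at 180 deg.
    """
    clamped = False
    target = joints.elbow_angle + delta_elbow
    if target > 180.0:
        target = 180.0
        clamped = True
    elb = elbow_position(arm, joints)
    heading = _forearm_heading(arm, joints.shoulder_angle, target)
    return elb + arm.forearm_length * _unit(heading), clamped
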