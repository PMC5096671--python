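"""Center-out reaching task geometry and kinematics.

The standard instructed-delay center-out task: targets equally spaced on a
circle, reaches with bell-shaped speed profiles. Every simulator and decoder
in this package consumes the :class:`ReachTask` / :class:`KinematicSet`
objects defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ReachTask",
    "KinematicSet",
    "make_targets",
    "bell_profile",
    "kinematic_traces",
]

DEFAULT_REACH_RADIUS_CM = 20.0


@dataclass(frozen=True)
class ReachTask:
    """A set of center-out reach conditions.

    Parameters
    ----------
    target_angles
        Target angle per condition, radians.
    reach_radius
        Distance from center to target, cm.
    """

    target_angles: np.ndarray
    reach_radius: float = DEFAULT_REACH_RADIUS_CM

    def __post_init__(self) -> None:
        angles = np.atleast_1d(np.asarray(self.target_angles, dtype=float))
        object.__setattr__(self, "target_angles", angles)
        if angles.ndim != 1 or angles.size < 2:
            raise ValueError("a reach task needs at least 2 target directions")
        wrapped = np.sort(np.mod(angles, 2 * np.pi))
        if np.any(np.diff(wrapped) < 1e-12) and angles.size > 1:
            # also catch the wrap-around pair
            raise ValueError("target angles must be distinct modulo 2*pi")
        if (wrapped[0] + 2 * np.pi) - wrapped[-1] < 1e-12:
            raise ValueError("target angles must be distinct modulo 2*pi")
        if self.reach_radius <= 0:
            raise ValueError("reach_radius must be positive")

    @property
    def n_conditions(self) -> int:
        return int(self.target_angles.size)


@dataclass
class KinematicSet:
    """Kinematic traces for every condition of a reach task.

    ``speed`` is shared across conditions (straight center-out reaches differ
    only in direction); ``velocity``, ``position``, ``acceleration`` and
    ``jerk`` have shape (conditions, time, 2).
    """

    time_ms: np.ndarray
    dt: float
    speed: np.ndarray
    velocity: np.ndarray
    position: np.ndarray
    acceleration: np.ndarray
    jerk: np.ndarray
    target_angles: np.ndarray = field(default=None)
    reach_radius: float = DEFAULT_REACH_RADIUS_CM

    @property
    def n_conditions(self) -> int:
        return self.velocity.shape[0]

    def to_hdf5(self, group) -> None:
        """Write all traces into an open h5py group."""
        for name in ("time_ms", "speed", "velocity", "position", "acceleration", "jerk"):
            group.create_dataset(name, data=getattr(self, name))
        group.attrs["dt"] = self.dt
        group.attrs["reach_radius"] = self.reach_radius
        group.create_dataset("target_angles", data=self.target_angles)

    @classmethod
    def from_hdf5(cls, group) -> "KinematicSet":
        return cls(
            time_ms=group["time_ms"][...],
            dt=float(group.attrs["dt"]),
            speed=group["speed"][...],
            velocity=group["velocity"][...],
            position=group["position"][...],
            acceleration=group["acceleration"][...],
            jerk=group["jerk"][...],
            target_angles=group["target_angles"][...],
            reach_radius=float(group.attrs["reach_radius"]),
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (condition, time, variable, x/y components)."""
        rows = []
        for c in range(self.n_conditions):
            df = pd.DataFrame(
                {
                    "condition": c,
                    "time_ms": self.time_ms,
                    "speed": self.speed,
                    "vx": self.velocity[c, :, 0],
                    "vy": self.velocity[c, :, 1],
                    "px": self.position[c, :, 0],
                    "py": self.position[c, :, 1],
                    "ax": self.acceleration[c, :, 0],
                    "ay": self.acceleration[c, :, 1],
                    "jx": self.jerk[c, :, 0],
                    "jy": self.jerk[c, :, 1],
                }
            )
            rows.append(df)
        return pd.concat(rows, ignore_index=True)


def make_targets(
    n_conditions: int,
    start_angle: float = 0.0,
    reach_radius: float = DEFAULT_REACH_RADIUS_CM,
) -> ReachTask:
    """Equally spaced reach targets around the circle.

    The classic task uses 13 directions; any count >= 2 is accepted.
    """
    if n_conditions < 2:
        raise ValueError("n_conditions must be >= 2 for a center-out task")
    angles = start_angle + 2 * np.pi * np.arange(n_conditions) / n_conditions
    return ReachTask(target_angles=np.mod(angles, 2 * np.pi), reach_radius=reach_radius)


def bell_profile(
    duration: float,
    dt: float,
    peak_fraction: float = 0.5,
    radius: float = DEFAULT_REACH_RADIUS_CM,
) -> np.ndarray:
    """Bell-shaped speed profile on the grid t = 0, dt, ..., duration - dt.

    Realized as a Gaussian with SD = duration/6 centered at
    ``peak_fraction * duration``, baseline-subtracted so the profile is
    exactly zero at t = 0 and t = duration, and rescaled so that
    ``sum(profile) * dt == radius`` (units cm per ms when duration is in ms).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if dt <= 0:
        raise ValueError("dt must be positive")
    n = int(round(duration / dt))
    if abs(n * dt - duration) > 1e-9 * duration:
        raise ValueError("dt must divide duration")
    t = np.arange(n) * dt
    sd = duration / 6.0
    mu = peak_fraction * duration
    g = np.exp(-0.5 * ((t - mu) / sd) ** 2)
    floor = np.exp(-0.5 * (mu / sd) ** 2)  # value at t = 0 (and duration, if centered)
    prof = np.clip(g - floor, 0.0, None)
    prof *= radius / (prof.sum() * dt)
    return prof


def kinematic_traces(task: ReachTask, profile: np.ndarray, dt: float) -> KinematicSet:
    """Assemble velocity/position/acceleration/jerk traces from a speed profile.

    Velocity is ``speed * (cos, sin)`` of the target angle; position is the
    running integral of velocity (right Riemann sum, so the final position
    lands exactly on the target circle); acceleration and jerk are successive
    discrete derivatives of velocity.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.ndim != 1:
        raise ValueError("profile must be a 1-D speed trace")
    n = profile.size
    time_ms = np.arange(n) * dt
    direction = np.stack(
        [np.cos(task.target_angles), np.sin(task.target_angles)], axis=-1
    )  # (C, 2)
    velocity = direction[:, None, :] * profile[None, :, None]  # (C, T, 2)
    position = np.cumsum(velocity, axis=1) * dt
    acceleration = np.gradient(velocity, dt, axis=1)
    jerk = np.gradient(acceleration, dt, axis=1)
    return KinematicSet(
        time_ms=time_ms,
        dt=float(dt),
        speed=profile,
        velocity=velocity,
        position=position,
        acceleration=acceleration,
        jerk=jerk,
        target_angles=task.target_angles,
        reach_radius=task.reach_radius,
    )
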