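"""From cortical activity to movement: population-vector readout, motor
plant, and target hit evaluation.

Each cortex unit whose output exceeds a threshold ``eta`` votes for the
workspace point of its grid location, with strength proportional to its
output; the movement target ``X_M`` is the activity-weighted mean of the
voting points.  A first-order motor plant relaxes the effector position
toward ``X_M`` by a fraction ``lam_m`` per step.  Only the end position
``x_p(T_E)`` is evaluated: a target of radius ``theta = 1.1`` grid units
is hit when the end position is strictly within ``theta`` of its center
(so a channel-centered target is hit from its center point and its four
orthogonal neighbors, but not from diagonal neighbors).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .circuit import channel_points
from .dynamics import N_CHANNELS

__all__ = [
    "Target",
    "MotorState",
    "readout_movement_target",
    "motor_step",
    "evaluate_hit",
    "DEFAULT_ETA",
    "DEFAULT_LAM_M",
    "WORKSPACE_CENTER",
]

DEFAULT_ETA = 0.5  #: cortical voting threshold
DEFAULT_LAM_M = 0.2  #: motor plant relaxation gain per step
WORKSPACE_CENTER = (6.5, 6.5)  #: start position of every trial


@dataclass(frozen=True)
class Target:
    """A circular target area in the workspace."""

    id: str
    center: tuple
    radius: float = 1.1

    def __post_init__(self) -> None:
        if not (1.0 < self.radius < np.sqrt(2.0)):
            raise ValueError(
                "target radius must lie in (1, sqrt(2)) so that exactly a "
                f"channel point and its 4 orthogonal neighbors fit inside; got {self.radius}"
            )

    def distance(self, point) -> float:
        return float(np.hypot(point[0] - self.center[0], point[1] - self.center[1]))

    def contains(self, point) -> bool:
        return self.distance(point) < self.radius


@dataclass
class MotorState:
    """Effector position and motor plant gain."""

    x_p: np.ndarray = field(default=None)  # type: ignore[assignment]
    lam_m: float = DEFAULT_LAM_M
    start: tuple = WORKSPACE_CENTER

    def __post_init__(self) -> None:
        if not (0.0 < self.lam_m <= 1.0):
            raise ValueError(f"lam_m must be in (0, 1], got {self.lam_m}")
        if self.x_p is None:
            self.x_p = np.array(self.start, dtype=float)

    def reset(self) -> None:
        self.x_p = np.array(self.start, dtype=float)


def readout_movement_target(cortex_outputs, eta: float = DEFAULT_ETA):
    """Population-vector movement target, or ``None`` if no unit votes.

    Returns the activity-weighted mean of the workspace points of all
    units with output strictly greater than ``eta``.
    """
    y = np.asarray(cortex_outputs, dtype=float)
    if y.shape != (N_CHANNELS,):
        raise ValueError(f"expected {N_CHANNELS} cortex outputs")
    mask = y > eta
    if not mask.any():
        return None
    w = y[mask]
    return (w[:, None] * channel_points()[mask]).sum(axis=0) / w.sum()


def motor_step(motor: MotorState, x_m) -> MotorState:
    """Relax the position toward ``x_m``; no-op when ``x_m`` is ``None``."""
    if x_m is not None:
        motor.x_p = motor.x_p + motor.lam_m * (np.asarray(x_m, dtype=float) - motor.x_p)
    return motor


def evaluate_hit(x_p_final, targets) -> str | None:
    """Id of the target strictly within radius of the end position, if any.

    Experiment layouts keep targets far enough apart that at most one can
    match; two matches indicate overlapping targets and raise an error.
    """
    hits = [t.id for t in targets if t.contains(x_p_final)]
    if len(hits) > 1:
        raise ValueError(f"overlapping targets both hit: {hits}")
    return hits[0] if hits else None
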