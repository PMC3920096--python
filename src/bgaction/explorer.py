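"""Exploratory drive to Cortex.

For every trial one channel, ``G_exp``, is chosen as the focus of
excitation.  The Explorer's output field then evolves through three
phases, emulating the evidence-accumulation-like activity seen in
cortical decision areas:

1. *broad phase* -- every channel is weakly excited; amplitude falls off
   with grid distance from the focus through a Gaussian profile, and the
   focus channel rises linearly toward one;
2. *focused phase* (``t_focus <= t < t_off``) -- only the focus channel
   is active, at exactly one; channels switch off one by one beforehand,
   the farthest first (distance-ranked turn-off schedule);
3. *off phase* (``t >= t_off``) -- all outputs are zero.

``G_exp`` is selected either uniformly at random over the grid, or under
the *Cognitive bias* policy: uniformly over a disc centered on the
target which shrinks geometrically each time the target is hit.  The
latter is a phenomenological stand-in for sophisticated cognitive
"zooming-in" strategies and involves no plasticity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .circuit import ChannelIndex, channel_points
from .dynamics import GRID_SIDE, N_CHANNELS

__all__ = [
    "ExplorerParams",
    "CognitiveBiasState",
    "explorer_field",
    "explorer_field_stack",
    "select_gexp_uniform",
    "select_gexp_cognitive",
    "shrink_cognitive_area",
]

#: largest possible grid distance between two channels
_D_MAX = math.sqrt(2.0) * (GRID_SIDE - 1)


@dataclass(frozen=True)
class ExplorerParams:
    """Timing and shape of the exploratory excitation pattern.

    ``trial_steps`` is the trial length T_E; ``t_focus`` the step by
    which only the focus channel remains active; ``t_off`` the step at
    which every output drops to zero.  ``sigma_e`` (grid units) sets the
    spatial width of the broad-phase Gaussian profile and ``baseline``
    the weak early excitation level.  ``t_decay`` is the number of steps
    a non-focus channel takes to ramp from its peak down to zero.
    """

    trial_steps: int = 80
    t_focus: int = 50
    t_off: int = 70
    sigma_e: float = 3.0
    baseline: float = 0.1
    t_decay: int = 5

    def __post_init__(self) -> None:
        if not (0 < self.t_focus < self.t_off <= self.trial_steps):
            raise ValueError(
                "require 0 < t_focus < t_off <= trial_steps, got "
                f"t_focus={self.t_focus}, t_off={self.t_off}, T_E={self.trial_steps}"
            )
        if self.sigma_e <= 0:
            raise ValueError(f"sigma_e must be > 0, got {self.sigma_e}")
        if not (0.0 < self.baseline < 1.0):
            raise ValueError(f"baseline must be in (0, 1), got {self.baseline}")
        if self.t_decay < 1 or self.t_decay >= self.t_focus:
            raise ValueError("t_decay must be in [1, t_focus)")


def _field_profile(gexp: ChannelIndex, params: ExplorerParams):
    """Per-channel peak amplitude and turn-off onset time."""
    pts = channel_points()
    d = np.hypot(pts[:, 0] - gexp.col, pts[:, 1] - gexp.row)
    amp = params.baseline + (1.0 - params.baseline) * np.exp(
        -(d ** 2) / (2.0 * params.sigma_e ** 2)
    )
    # farthest channels start their decay earliest; every non-focus decay
    # finishes by t_focus, so the focused phase is a pure indicator field
    t_end = (params.t_focus - params.t_decay) * (1.0 - d / (2.0 * _D_MAX))
    return d, amp, t_end


def explorer_field(
    gexp: ChannelIndex, t: int, params: ExplorerParams | None = None
) -> np.ndarray:
    """Explorer output field (196 values in [0, 1]) at time step ``t``."""
    if params is None:
        params = ExplorerParams()
    if not (0 <= t < params.trial_steps):
        raise ValueError(f"t={t} outside trial of {params.trial_steps} steps")
    return explorer_field_stack(gexp, params)[t]


def explorer_field_stack(
    gexp: ChannelIndex, params: ExplorerParams | None = None
) -> np.ndarray:
    """Whole-trial field, shape ``(trial_steps, 196)``.

    Equivalent to stacking :func:`explorer_field` over ``t``; computed in
    one vectorized pass because the simulation consumes full trials.
    """
    if params is None:
        params = ExplorerParams()
    d, amp, t_end = _field_profile(gexp, params)
    t = np.arange(params.trial_steps)[:, None].astype(float)
    rise = params.baseline + (amp - params.baseline) * np.minimum(
        t / params.t_focus, 1.0
    )
    peak = params.baseline + (amp - params.baseline) * (t_end / params.t_focus)
    decay = peak * np.clip(1.0 - (t - t_end) / params.t_decay, 0.0, 1.0)
    field = np.where(t < t_end, rise, decay)
    g = gexp.flat
    field[:, g] = params.baseline + (1.0 - params.baseline) * np.minimum(
        t[:, 0] / params.t_focus, 1.0
    )
    field[params.t_off:, :] = 0.0
    return np.clip(field, 0.0, 1.0)


def select_gexp_uniform(rng: np.random.Generator) -> ChannelIndex:
    """Focus of excitation drawn uniformly over the 196 channels."""
    return ChannelIndex.from_flat(int(rng.integers(N_CHANNELS)))


@dataclass(frozen=True)
class CognitiveBiasState:
    """Shrinking selection disc of the Cognitive-bias policy.

    ``radius`` is the current selection radius in grid units; each target
    hit shrinks it geometrically by ``gamma`` down to ``floor`` (the
    target radius), so in the many-hit limit every selected focus lies
    inside the target and every movement hits.
    """

    center: tuple
    radius: float = _D_MAX + 1.0
    gamma: float = 0.8
    floor: float = 1.1
    hits_so_far: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.gamma < 1.0):
            raise ValueError(f"gamma must be in (0, 1), got {self.gamma}")
        if self.radius < self.floor:
            raise ValueError("radius below floor radius")

    def candidate_channels(self) -> np.ndarray:
        """Flat indices of channels whose point lies within the disc."""
        pts = channel_points()
        d = np.hypot(pts[:, 0] - self.center[0], pts[:, 1] - self.center[1])
        return np.flatnonzero(d <= self.radius)


def select_gexp_cognitive(
    state: CognitiveBiasState, rng: np.random.Generator
) -> ChannelIndex:
    """Focus drawn uniformly over channels inside the current disc."""
    cand = state.candidate_channels()
    if cand.size == 0:  # unreachable while floor >= 1: disc covers >= 5 channels
        raise RuntimeError("cognitive bias candidate set is empty")
    return ChannelIndex.from_flat(int(cand[rng.integers(cand.size)]))


def shrink_cognitive_area(state: CognitiveBiasState) -> CognitiveBiasState:
    """Shrink the disc after a target hit: ``r <- max(floor, gamma * r)``."""
    return replace(
        state,
        radius=max(state.floor, state.gamma * state.radius),
        hits_so_far=state.hits_so_far + 1,
    )
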