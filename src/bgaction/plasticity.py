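"""Corticostriatal plasticity: reinforcement with habituation, extinction,
weight bounds, and habituation resets at reinforcement-schedule changes.

Four weight vectors are plastic, all indexed by channel: Context -> D1,
Context -> D2, Cortex -> D1 and Cortex -> D2.  When a movement hits the
reinforced target ``k``, the four weights of the single active channel
are increased by the Hebbian rule with a soft ceiling and a habituation
factor::

    dw = alpha * beta**(N_k - 1) * y_pre * y_post * (W_max - w)

where ``N_k`` counts reinforced hits of target ``k`` (the hit being
reinforced included), ``beta = 0.825``, and ``W_max = 1``.  Habituation
stands in for the declining phasic dopamine response as the outcome
becomes predicted: the first hit of a (newly) reinforced target is fully
novel (factor 1) and each further hit reinforces less.

When a movement is made but no reinforced target is hit, the active
channel's four weights are *decreased* (extinction) by an
activity-gated linear decrement ``alpha_dec * y_pre * y_post``, clipped
at the floors.  Unvisited channels never decay: extinction requires an
actual movement through the channel.

Floors: Cortex -> striatum weights are non-negative; Context -> striatum
weights may go weakly negative (floor -0.1), approximating inhibition by
striatal interneurons and implementing an a-priori bias *against*
movements that repeatedly went unreinforced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .circuit import ChannelIndex
from .dynamics import N_CHANNELS

__all__ = [
    "PlasticWeights",
    "HabituationState",
    "habituation_factor",
    "reinforce_update",
    "extinction_update",
    "phase_transition_reset",
    "BETA",
    "W_MAX",
    "CTX_FLOOR",
]

BETA = 0.825  #: habituation base
W_MAX = 1.0  #: soft ceiling of every plastic weight
CTX_FLOOR = -0.1  #: lower bound of Context -> striatum weights
DEFAULT_ALPHA = 0.11  #: reinforcement step size
DEFAULT_ALPHA_DEC = 0.005  #: extinction step size (far slower than acquisition)

#: initial Cortex -> striatum weight; positive so that the untrained
#: circuit responds to cortical drive and selects the explorer's focus
INIT_W_M = 0.5


@dataclass
class PlasticWeights:
    """The four plastic weight vectors with their bounds.

    ``w_ctx_*`` start at zero (no context bias before learning);
    ``w_m_*`` start at :data:`INIT_W_M`.
    """

    w_ctx_d1: np.ndarray = field(default=None)  # type: ignore[assignment]
    w_ctx_d2: np.ndarray = field(default=None)  # type: ignore[assignment]
    w_m_d1: np.ndarray = field(default=None)  # type: ignore[assignment]
    w_m_d2: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.w_ctx_d1 is None:
            self.w_ctx_d1 = np.zeros(N_CHANNELS)
        if self.w_ctx_d2 is None:
            self.w_ctx_d2 = np.zeros(N_CHANNELS)
        if self.w_m_d1 is None:
            self.w_m_d1 = np.full(N_CHANNELS, INIT_W_M)
        if self.w_m_d2 is None:
            self.w_m_d2 = np.full(N_CHANNELS, INIT_W_M)

    def copy(self) -> "PlasticWeights":
        return PlasticWeights(
            self.w_ctx_d1.copy(), self.w_ctx_d2.copy(),
            self.w_m_d1.copy(), self.w_m_d2.copy(),
        )

    def check_bounds(self) -> bool:
        """True iff every weight is within its [floor, W_max] interval."""
        return bool(
            (self.w_ctx_d1 >= CTX_FLOOR).all() and (self.w_ctx_d1 <= W_MAX).all()
            and (self.w_ctx_d2 >= CTX_FLOOR).all() and (self.w_ctx_d2 <= W_MAX).all()
            and (self.w_m_d1 >= 0.0).all() and (self.w_m_d1 <= W_MAX).all()
            and (self.w_m_d2 >= 0.0).all() and (self.w_m_d2 <= W_MAX).all()
        )


@dataclass
class HabituationState:
    """Per-target reinforced-hit counts driving the habituation factor."""

    counts: dict = field(default_factory=dict)
    beta: float = BETA

    def count(self, target_id: str) -> int:
        return self.counts.get(target_id, 0)

    def record_hit(self, target_id: str) -> int:
        """Increment and return the updated count ``N_k``."""
        self.counts[target_id] = self.count(target_id) + 1
        return self.counts[target_id]


def habituation_factor(n_k: int, beta: float = BETA) -> float:
    """``beta ** (N_k - 1)``: 1 for the first (novel) hit, shrinking after."""
    if n_k < 1:
        raise ValueError(f"N_k must be >= 1 (the reinforced hit is counted), got {n_k}")
    return beta ** (n_k - 1)


def reinforce_update(
    weights: PlasticWeights,
    active_channel: ChannelIndex,
    y_pre_ctx: float,
    y_pre_m: float,
    y_post_d1: float,
    y_post_d2: float,
    alpha: float = DEFAULT_ALPHA,
    n_k: int = 1,
    beta: float = BETA,
) -> PlasticWeights:
    """Apply the reinforcement rule to the active channel's four weights."""
    i = active_channel.flat
    h = alpha * habituation_factor(n_k, beta)
    for w, y_pre, y_post in (
        (weights.w_ctx_d1, y_pre_ctx, y_post_d1),
        (weights.w_ctx_d2, y_pre_ctx, y_post_d2),
        (weights.w_m_d1, y_pre_m, y_post_d1),
        (weights.w_m_d2, y_pre_m, y_post_d2),
    ):
        w[i] = min(W_MAX, w[i] + h * y_pre * y_post * (W_MAX - w[i]))
    return weights


def extinction_update(
    weights: PlasticWeights,
    active_channel: ChannelIndex,
    y_pre_ctx: float,
    y_pre_m: float,
    y_post_d1: float,
    y_post_d2: float,
    alpha_dec: float = DEFAULT_ALPHA_DEC,
) -> PlasticWeights:
    """Activity-gated weight decrease after an unreinforced movement."""
    i = active_channel.flat
    for w, floor, y_pre, y_post in (
        (weights.w_ctx_d1, CTX_FLOOR, y_pre_ctx, y_post_d1),
        (weights.w_ctx_d2, CTX_FLOOR, y_pre_ctx, y_post_d2),
        (weights.w_m_d1, 0.0, y_pre_m, y_post_d1),
        (weights.w_m_d2, 0.0, y_pre_m, y_post_d2),
    ):
        w[i] = max(floor, w[i] - alpha_dec * y_pre * y_post)
    return weights


def phase_transition_reset(
    hab: HabituationState,
    old_reinforced: set,
    new_reinforced: set,
) -> HabituationState:
    """Reset ``N_k`` for every target whose reinforced status changes.

    Called exactly at reinforcement-schedule boundaries.  A target that
    starts or stops being reinforced becomes novel again; targets with
    unchanged status keep their counts.  Idempotent for an unchanged map.
    """
    for target_id in old_reinforced.symmetric_difference(new_reinforced):
        hab.counts[target_id] = 0
    return hab
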