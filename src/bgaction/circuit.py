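"""Full cortico-basal-ganglia-thalamo-cortical network.

The model is a channelized selection architecture: 196 action channels,
arranged as a 14 x 14 grid, are replicated across seven areas --
Cortex (M), Thalamus (T), striatal D1 and D2 populations, STN, GPe and
SNr.  An exploratory drive excites Cortex; Cortex and Thalamus form a
per-channel positive feedback loop whose gain is controlled by tonic
inhibition from SNr.  Within the basal ganglia, D1 supplies focused
(channelwise) inhibition of SNr while STN supplies diffuse (one-to-all)
excitation, so the most strongly driven channel is *disinhibited* at
thalamus while all competitors are inhibited further (off-center
on-surround selection).  The D2 -> GPe pathway regulates STN so the
diffuse excitation stays in balance for any number of active channels.

A single Context unit with constant output projects to D1, D2 (plastic
weights -- see :mod:`bgaction.plasticity`) and STN, and implements the
learned, context-dependent bias toward previously reinforced movements.

Tonic dopamine is a fixed scalar ``lam_da`` scaling striatal input
(facilitatory ``1 + lam_da`` on D1, suppressive ``1 - lam_da`` on D2);
phasic dopamine is not simulated explicitly -- its effect enters only
through the reinforcement rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import GRID_SIDE, N_CHANNELS, AreaParams, AreaState
from . import _kernels

__all__ = [
    "ChannelIndex",
    "ModelParams",
    "NetworkState",
    "assemble_network",
    "network_step",
    "apply_signal_dependent_noise",
    "reset_state",
    "channel_points",
]

# ---------------------------------------------------------------------------
# grid <-> workspace geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChannelIndex:
    """One action channel: a cell of the 14 x 14 grid.

    Channel ``(row, col)`` represents a movement to workspace point
    ``(col, row)``; nearest-neighbor channels are exactly one grid unit
    apart, so a target of radius 1.1 centered on a channel's point covers
    that point and its four orthogonal neighbors.
    """

    row: int
    col: int

    def __post_init__(self) -> None:
        if not (0 <= self.row < GRID_SIDE and 0 <= self.col < GRID_SIDE):
            raise ValueError(f"channel ({self.row}, {self.col}) outside 14x14 grid")

    @property
    def flat(self) -> int:
        """Row-major flat index in [0, 195]."""
        return self.row * GRID_SIDE + self.col

    @property
    def point(self) -> np.ndarray:
        """Workspace point (x, y) = (col, row)."""
        return np.array([float(self.col), float(self.row)])

    @classmethod
    def from_flat(cls, i: int) -> "ChannelIndex":
        return cls(int(i) // GRID_SIDE, int(i) % GRID_SIDE)

    @classmethod
    def nearest(cls, point) -> "ChannelIndex":
        """Channel whose workspace point is closest to ``point``."""
        x, y = float(point[0]), float(point[1])
        col = min(max(int(round(x)), 0), GRID_SIDE - 1)
        row = min(max(int(round(y)), 0), GRID_SIDE - 1)
        return cls(row, col)


def channel_points() -> np.ndarray:
    """(196, 2) array of workspace points, row-major channel order."""
    rows, cols = np.divmod(np.arange(N_CHANNELS), GRID_SIDE)
    return np.column_stack([cols.astype(float), rows.astype(float)])


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

#: order of areas in the packed state arrays used by the kernels
AREA_ORDER = ("m", "t", "d1", "d2", "stn", "gpe", "snr")


def _default_areas() -> dict:
    # Decay rate 0.25 everywhere (integration over ~4 steps).  SNr and GPe
    # have negative output thresholds, giving tonic output 0.2 at rest so
    # thalamus is tonically inhibited; STN has a positive threshold and is
    # silent at rest (its constant Context drive is balanced by tonic GPe
    # inhibition), so the diffuse surround is recruited only by channels
    # with strong cortical support.  D1/D2 slope 2 keeps striatal output
    # graded, so the SNr dip deepens smoothly with the learned bias.
    return {
        "m": AreaParams(k=0.25, epsilon=0.0, m=1.0, name="m"),
        "t": AreaParams(k=0.25, epsilon=0.0, m=1.0, name="t"),
        "d1": AreaParams(k=0.25, epsilon=0.15, m=2.0, name="d1"),
        "d2": AreaParams(k=0.25, epsilon=0.15, m=2.0, name="d2"),
        "stn": AreaParams(k=0.25, epsilon=0.4, m=1.0, name="stn"),
        "gpe": AreaParams(k=0.25, epsilon=-0.2, m=1.0, name="gpe"),
        "snr": AreaParams(k=0.25, epsilon=-0.2, m=1.0, name="snr"),
    }


@dataclass(frozen=True)
class ModelParams:
    """Fixed (non-plastic) gains and area parameters of the network.

    All inter-area projections are channelwise one-to-one except the STN
    efferents, which are diffuse (each STN unit excites every SNr and GPe
    unit).  Inhibitory projections enter the net input with a negative
    sign; the gain values themselves are non-negative magnitudes.
    """

    w_em: float = 0.47  #: Explorer -> Cortex (suppressed channels stay just below eta)
    w_tm: float = 1.5  #: Thalamus -> Cortex (loop gain > 1 for hysteresis)
    w_mt: float = 1.0  #: Cortex -> Thalamus
    w_snr_t: float = 1.0  #: SNr -| Thalamus
    w_m_stn: float = 1.0  #: Cortex -> STN
    w_c_stn: float = 0.2  #: Context -> STN
    w_d1_snr: float = 0.5  #: D1 -| SNr (focused)
    w_d2_gpe: float = 1.0  #: D2 -| GPe
    w_stn_snr: float = 0.9  #: STN -> SNr (diffuse, applied to channel sum)
    w_stn_gpe: float = 0.9  #: STN -> GPe (diffuse)
    w_gpe_stn: float = 1.0  #: GPe -| STN
    w_gpe_snr: float = 0.1  #: GPe -| SNr
    lam_da: float = 0.2  #: tonic dopamine scaling of striatal input
    context_out: float = 1.0  #: constant output of the single Context unit
    areas: dict = field(default_factory=_default_areas)

    def __post_init__(self) -> None:
        for name in AREA_ORDER:
            if name not in self.areas:
                raise ValueError(f"missing area parameters for {name!r}")
        for g in (
            "w_em", "w_tm", "w_mt", "w_snr_t", "w_m_stn", "w_c_stn",
            "w_d1_snr", "w_d2_gpe", "w_stn_snr", "w_stn_gpe",
            "w_gpe_stn", "w_gpe_snr",
        ):
            if getattr(self, g) < 0:
                raise ValueError(f"gain {g} must be a non-negative magnitude")
        if not (0.0 <= self.lam_da < 1.0):
            raise ValueError("lam_da must be in [0, 1)")

    def packed(self) -> tuple:
        """(gains, k, eps, m) arrays in kernel layout."""
        gains = np.array(
            [
                self.w_em, self.w_tm, self.w_mt, self.w_snr_t,
                self.w_m_stn, self.w_c_stn, self.w_d1_snr, self.w_d2_gpe,
                self.w_stn_snr, self.w_stn_gpe, self.w_gpe_stn,
                self.w_gpe_snr, self.lam_da, self.context_out,
            ]
        )
        k = np.array([self.areas[n].k for n in AREA_ORDER])
        eps = np.array([self.areas[n].epsilon for n in AREA_ORDER])
        m = np.array([self.areas[n].m for n in AREA_ORDER])
        return gains, k, eps, m


# ---------------------------------------------------------------------------
# network state
# ---------------------------------------------------------------------------


@dataclass
class NetworkState:
    """Activations and outputs of all seven areas plus the Context drive.

    The per-area state lives in two packed ``(7, 196)`` arrays (rows in
    :data:`AREA_ORDER`) shared with the numba kernels; :class:`AreaState`
    views are exposed through :meth:`area` for inspection.
    """

    params: ModelParams
    a: np.ndarray = field(default=None)  # type: ignore[assignment]
    y: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.a is None:
            self.a = np.zeros((len(AREA_ORDER), N_CHANNELS))
        if self.y is None:
            self.y = np.zeros((len(AREA_ORDER), N_CHANNELS))
            self._refresh_outputs()

    def _refresh_outputs(self) -> None:
        for i, name in enumerate(AREA_ORDER):
            p = self.params.areas[name]
            self.y[i] = np.clip(p.m * (self.a[i] - p.epsilon), 0.0, 1.0)

    @property
    def context_output(self) -> float:
        return self.params.context_out

    def area(self, name: str) -> AreaState:
        """A view of one area's state (arrays share memory)."""
        i = AREA_ORDER.index(name)
        st = AreaState.__new__(AreaState)
        st.params = self.params.areas[name]
        st.a = self.a[i]
        st.y = self.y[i]
        return st

    def cortex_output(self) -> np.ndarray:
        return self.y[0]

    def snr_output(self) -> np.ndarray:
        return self.y[6]


def assemble_network(params: ModelParams | None = None) -> NetworkState:
    """Build a zero-activation network with the given (or default) params.

    Tonic areas (SNr, GPe) start with positive output as implied by their
    negative output thresholds at zero activation.
    """
    if params is None:
        params = ModelParams()
    return NetworkState(params=params)


def reset_state(state: NetworkState) -> NetworkState:
    """Zero all activations and recompute resting outputs; idempotent.

    Plastic weights are not part of :class:`NetworkState` and are untouched.
    """
    state.a[:] = 0.0
    state._refresh_outputs()
    return state


# ---------------------------------------------------------------------------
# stepping
# ---------------------------------------------------------------------------


def apply_signal_dependent_noise(y, sigma: float, rng: np.random.Generator):
    """Multiplicative (signal-dependent) Gaussian noise with clipping.

    ``y <- clip(y + y * n, 0, 1)`` with ``n ~ Normal(0, sigma)`` drawn
    independently per element.  ``sigma = 0`` returns ``y`` unchanged.
    """
    if sigma < 0:
        raise ValueError(f"noise sigma must be >= 0, got {sigma}")
    y = np.asarray(y, dtype=float)
    if sigma == 0.0:
        return y.copy() if y.ndim else float(y)
    n = rng.normal(0.0, sigma, size=y.shape)
    out = np.clip(y + y * n, 0.0, 1.0)
    return out if y.ndim else float(out)


def network_step(
    state: NetworkState,
    explorer_field: np.ndarray,
    weights,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
) -> NetworkState:
    """One update sweep of the whole network.

    Areas are updated in feedforward sweep order
    Cortex -> (noise) -> {D1, D2, STN} -> GPe -> SNr -> Thalamus, each
    area integrating once using the freshly computed upstream outputs
    (STN reads the previous step's GPe output, closing the STN-GPe loop).
    Noise, when ``noise_sigma > 0``, is applied to the cortical outputs
    only, and the noisy outputs are what every downstream projection and
    the movement readout see.
    """
    if noise_sigma < 0:
        raise ValueError(f"noise sigma must be >= 0, got {noise_sigma}")
    explorer_field = np.asarray(explorer_field, dtype=float)
    if explorer_field.shape != (N_CHANNELS,):
        raise ValueError(f"explorer field must have {N_CHANNELS} entries")
    if noise_sigma > 0.0:
        if rng is None:
            raise ValueError("rng required when noise_sigma > 0")
        noise = rng.standard_normal(N_CHANNELS) * noise_sigma
    else:
        noise = np.zeros(N_CHANNELS)
    gains, k, eps, m = state.params.packed()
    _kernels.step(
        state.a, state.y, explorer_field,
        weights.w_ctx_d1, weights.w_ctx_d2, weights.w_m_d1, weights.w_m_d2,
        gains, k, eps, m, noise, noise_sigma > 0.0,
    )
    return state
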