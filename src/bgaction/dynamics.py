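"""Leaky-integrator rate units shared by every brain area in the model.

Each area is a population of units whose scalar *activation* relaxes toward
its net input and whose *output* (interpreted as a normalized firing rate in
[0, 1]) is a piecewise-linear ramp of the activation.  The same functional
form is used for cortex, thalamus and all basal-ganglia nuclei; areas differ
only in their decay rate, output threshold and output slope.  Tonically
active nuclei (SNr, GPe, STN if desired) are obtained with a *negative*
output threshold, so that zero net input already yields a positive output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

N_CHANNELS = 196  #: units per area: a 14 x 14 grid of action channels
GRID_SIDE = 14


@dataclass(frozen=True)
class AreaParams:
    """Parameters of one leaky-integrator area.

    Parameters
    ----------
    k :
        Decay (relaxation) rate per time step, in ``(0, 1]``.  ``k = 1``
        makes the unit memoryless; smaller values integrate the input over
        roughly ``1/k`` steps.
    epsilon :
        Output threshold, in activation units.  Output is zero for
        activations at or below ``epsilon``.  A negative threshold yields
        tonic output at rest.
    m :
        Output slope (1/activation units).  Output saturates at one for
        activations at or above ``epsilon + 1/m``.
    name :
        Label used in error messages and activity dumps.
    """

    k: float
    epsilon: float
    m: float
    name: str = "area"

    def __post_init__(self) -> None:
        if not (0.0 < self.k <= 1.0):
            raise ValueError(
                f"area {self.name!r}: decay rate k must be in (0, 1], got {self.k}"
            )
        if not self.m > 0.0:
            raise ValueError(
                f"area {self.name!r}: output slope m must be > 0, got {self.m}"
            )


@dataclass
class AreaState:
    """Activation and output vectors of one area of ``N_CHANNELS`` units."""

    params: AreaParams
    a: np.ndarray = field(default=None)  # type: ignore[assignment]
    y: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.a is None:
            self.a = np.zeros(N_CHANNELS)
        if self.y is None:
            self.y = ramp_output(self.a, self.params)

    def reset(self) -> None:
        """Zero activations and recompute outputs (tonic areas rest > 0)."""
        self.a[:] = 0.0
        self.y[:] = ramp_output(self.a, self.params)

    def step(self, u: np.ndarray) -> np.ndarray:
        """Integrate net input ``u`` for one time step and return outputs."""
        self.a[:] = leaky_step(self.a, u, self.params)
        self.y[:] = ramp_output(self.a, self.params)
        return self.y


def ramp_output(a, params: AreaParams):
    """Piecewise-linear output nonlinearity.

    Returns 0 for ``a <= epsilon``, 1 for ``a >= epsilon + 1/m`` and is
    linear with slope ``m`` in between.  Works elementwise on arrays.
    """
    return np.clip(params.m * (np.asarray(a, dtype=float) - params.epsilon), 0.0, 1.0)


def leaky_step(a, u, params: AreaParams):
    """One discrete-time leaky-integration update ``a <- (1 - k) a + k u``.

    The fixed point is ``a = u``; convergence toward a constant input is
    geometric with ratio ``1 - k``.
    """
    k = params.k
    return (1.0 - k) * np.asarray(a, dtype=float) + k * np.asarray(u, dtype=float)
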