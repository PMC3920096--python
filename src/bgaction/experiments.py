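"""Trial and run orchestration: the five experiment presets, the
bias-zone mapping procedure, seeding and result tables.

A *trial* is one movement: the network is reset, a focus of excitation
``G_exp`` is chosen (uniformly, or from the Cognitive-bias disc), the
network is simulated for ``T_E`` steps while the motor plant tracks the
cortical population vector, the end position is evaluated against the
targets, and the plastic weights are updated (reinforcement on a
reinforced hit, extinction on any other movement).  A *run* is a
sequence of trials with independent random state; an *experiment* is a
battery of independent runs sharing a configuration, with reinforcement
phases (which target pays off when) partitioning the trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd

from . import _kernels
from .behavior import (DEFAULT_ETA, DEFAULT_LAM_M, WORKSPACE_CENTER, Target,
                       evaluate_hit)
from .circuit import (ChannelIndex, ModelParams, NetworkState, assemble_network,
                      channel_points, reset_state)
from .dynamics import N_CHANNELS
from .explorer import (CognitiveBiasState, ExplorerParams, explorer_field_stack,
                       select_gexp_cognitive, select_gexp_uniform,
                       shrink_cognitive_area)
from .plasticity import (BETA, DEFAULT_ALPHA, DEFAULT_ALPHA_DEC, HabituationState,
                         PlasticWeights, extinction_update,
                         phase_transition_reset, reinforce_update)

__all__ = [
    "Phase",
    "ExperimentConfig",
    "TrialRecord",
    "ExperimentResult",
    "BiasZoneMap",
    "run_trial",
    "run_experiment",
    "map_bias_zone",
    "preset_experiments",
    "trace_trial",
    "PRESET_NAMES",
    "DEFAULT_TARGETS",
]

#: default target layout: G1 lower right, G2far upper left, G2near ~3 grid
#: units from G1 (outside its radius)
DEFAULT_TARGETS = {
    "G1": Target("G1", (10.0, 3.0)),
    "G2far": Target("G2far", (3.0, 10.0)),
    "G2near": Target("G2near", (7.0, 3.0)),
}

BIAS_MODES = ("bg", "cognitive", "both")


@dataclass(frozen=True)
class Phase:
    """A block of trials with a fixed set of reinforced target ids."""

    n_trials: int
    reinforced: tuple

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("phase must contain at least one trial")


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce an experiment battery."""

    name: str = "custom"
    n_runs: int = 50
    phases: tuple = (Phase(300, ("G1",)),)
    target_ids: tuple = ("G1",)
    bias_mode: str = "bg"
    noise_sigma: float = 0.0
    seed: int = 0
    model: ModelParams = field(default_factory=ModelParams)
    explorer: ExplorerParams = field(default_factory=ExplorerParams)
    eta: float = DEFAULT_ETA
    lam_m: float = DEFAULT_LAM_M
    start: tuple = WORKSPACE_CENTER
    alpha: float = DEFAULT_ALPHA
    alpha_dec: float = DEFAULT_ALPHA_DEC
    beta: float = BETA
    cognitive_gamma: float = 0.8
    log_weights: str | None = None  #: None, "segments" or "trials"

    def __post_init__(self) -> None:
        if self.bias_mode not in BIAS_MODES:
            raise ValueError(f"bias_mode must be one of {BIAS_MODES}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        unknown = [t for p in self.phases for t in p.reinforced
                   if t not in self.target_ids]
        if unknown:
            raise ValueError(f"phase reinforces unknown target(s) {unknown}")
        if self.log_weights not in (None, "segments", "trials"):
            raise ValueError("log_weights must be None, 'segments' or 'trials'")

    @property
    def targets(self) -> dict:
        return {tid: DEFAULT_TARGETS[tid] for tid in self.target_ids}

    @property
    def plasticity_on(self) -> bool:
        """Cognitive-only biasing disables corticostriatal plasticity."""
        return self.bias_mode in ("bg", "both")

    @property
    def cognitive_on(self) -> bool:
        return self.bias_mode in ("cognitive", "both")

    @property
    def total_trials(self) -> int:
        return sum(p.n_trials for p in self.phases)


@dataclass
class TrialRecord:
    """Outcome of one movement."""

    run: int
    trial: int
    phase: int
    gexp: ChannelIndex
    x_p: np.ndarray
    moved: bool
    hit: str | None
    reinforced_hit: bool
    distances: dict
    hab_counts: dict


@dataclass
class ExperimentResult:
    """Battery output: tidy per-trial table plus optional weight logs."""

    config: ExperimentConfig
    trials: pd.DataFrame
    #: (run, phase_index) -> Context->D1 weight vector at that phase's end
    weight_segments: dict = field(default_factory=dict)
    #: run -> (total_trials, 196) float32 Context->D1 trajectory
    weight_trials: dict = field(default_factory=dict)

    def run_table(self, run: int) -> pd.DataFrame:
        return self.trials[self.trials["run"] == run]


@lru_cache(maxsize=512)
def _cached_field_stack(flat: int, params: ExplorerParams):
    stack = explorer_field_stack(ChannelIndex.from_flat(flat), params)
    stack.setflags(write=False)
    return stack


class _TrialEngine:
    """Reusable buffers + packed parameters for fast trial simulation."""

    def __init__(self, config: ExperimentConfig):
        self.config = config
        self.state = assemble_network(config.model)
        self.gains, self.k, self.eps, self.m = config.model.packed()
        self.coords = channel_points()
        t_e = config.explorer.trial_steps
        self._zero_noise = np.zeros((t_e, N_CHANNELS))
        self.targets = list(config.targets.values())

    def simulate(self, gexp: ChannelIndex, weights: PlasticWeights,
                 rng: np.random.Generator | None):
        """One movement; returns (x_p_final, moved, cortex_y, d1_y, d2_y)."""
        cfg = self.config
        reset_state(self.state)
        e_stack = _cached_field_stack(gexp.flat, cfg.explorer)
        if cfg.noise_sigma > 0.0:
            noise = rng.standard_normal(e_stack.shape) * cfg.noise_sigma
        else:
            noise = self._zero_noise
        xp = np.array(cfg.start, dtype=float)
        moved = _kernels.run_trial_steps(
            self.state.a, self.state.y, e_stack,
            weights.w_ctx_d1, weights.w_ctx_d2, weights.w_m_d1, weights.w_m_d2,
            self.gains, self.k, self.eps, self.m,
            noise, cfg.noise_sigma > 0.0,
            cfg.eta, cfg.lam_m, xp, self.coords,
        )
        y = self.state.y
        return xp, bool(moved), y[_kernels.M], y[_kernels.D1], y[_kernels.D2]


def _active_channel(cortex_y: np.ndarray) -> ChannelIndex | None:
    """Argmax cortex channel at trial end; ties break lexicographically
    by (row, col) because the grid is stored row-major."""
    if cortex_y.max() <= 0.0:
        return None
    return ChannelIndex.from_flat(int(np.argmax(cortex_y)))


def _learn(config, weights, hab, hit, reinforced, moved, cortex_y, d1_y, d2_y):
    """Apply the trial's weight update; returns True on a reinforced hit."""
    ch = _active_channel(cortex_y) if moved else None
    if ch is None:
        # no movement: no defined pre/post pair, so no weight change
        return False
    i = ch.flat
    c_out = config.model.context_out
    if hit is not None and hit in reinforced:
        n_k = hab.record_hit(hit)
        reinforce_update(weights, ch, c_out, cortex_y[i], d1_y[i], d2_y[i],
                         alpha=config.alpha, n_k=n_k, beta=config.beta)
        return True
    extinction_update(weights, ch, c_out, cortex_y[i], d1_y[i], d2_y[i],
                      alpha_dec=config.alpha_dec)
    return False


def run_trial(
    config: ExperimentConfig,
    weights: PlasticWeights,
    hab: HabituationState,
    rng: np.random.Generator,
    reinforced: tuple | None = None,
    cognitive: CognitiveBiasState | None = None,
    gexp: ChannelIndex | None = None,
    learning: bool = True,
    engine: _TrialEngine | None = None,
    run: int = 0,
    trial: int = 1,
    phase: int = 0,
) -> tuple:
    """Execute one movement and its learning update.

    Returns ``(TrialRecord, cognitive_state)`` -- the cognitive disc
    shrinks on reinforced hits when the Cognitive bias is active.
    ``gexp`` may be forced (bias-zone mapping); otherwise it is selected
    per the configured bias mode.
    """
    if engine is None:
        engine = _TrialEngine(config)
    if reinforced is None:
        reinforced = config.phases[phase].reinforced
    if gexp is None:
        if config.cognitive_on:
            if cognitive is None:
                raise ValueError("cognitive bias mode requires a CognitiveBiasState")
            gexp = select_gexp_cognitive(cognitive, rng)
        else:
            gexp = select_gexp_uniform(rng)

    xp, moved, cortex_y, d1_y, d2_y = engine.simulate(gexp, weights, rng)
    hit = evaluate_hit(xp, engine.targets)
    reinforced_hit = False
    if learning and config.plasticity_on:
        reinforced_hit = _learn(config, weights, hab, hit, reinforced, moved,
                                cortex_y, d1_y, d2_y)
    elif hit is not None and hit in reinforced:
        # cognitive-only runs still track habituation-free hit counts for
        # the shrinking disc; weights stay untouched
        reinforced_hit = True
    if config.cognitive_on and cognitive is not None and reinforced_hit:
        cognitive = shrink_cognitive_area(cognitive)

    record = TrialRecord(
        run=run, trial=trial, phase=phase, gexp=gexp, x_p=xp, moved=moved,
        hit=hit, reinforced_hit=reinforced_hit,
        distances={t.id: t.distance(xp) for t in engine.targets},
        hab_counts=dict(hab.counts),
    )
    return record, cognitive


def _fresh_cognitive(config: ExperimentConfig, phase: Phase) -> CognitiveBiasState | None:
    if not config.cognitive_on:
        return None
    tid = phase.reinforced[0]
    target = config.targets[tid]
    return CognitiveBiasState(center=tuple(target.center),
                              gamma=config.cognitive_gamma,
                              floor=target.radius)


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Run the full battery: ``n_runs`` independent runs of all phases.

    Each run draws its own child seed from the master seed, so any run
    can be reproduced in isolation.  Phase boundaries reset the
    habituation counts of every target whose reinforced status changes.
    """
    engine = _TrialEngine(config)
    children = np.random.SeedSequence(config.seed).spawn(config.n_runs)
    rows = []
    weight_segments: dict = {}
    weight_trials: dict = {}
    target_ids = list(config.targets)

    for run_idx in range(config.n_runs):
        rng = np.random.Generator(np.random.PCG64(children[run_idx]))
        weights = PlasticWeights()
        hab = HabituationState(beta=config.beta)
        cognitive = _fresh_cognitive(config, config.phases[0])
        if config.log_weights == "trials":
            traj = np.empty((config.total_trials, N_CHANNELS), dtype=np.float32)
        trial_idx = 0
        for phase_idx, phase in enumerate(config.phases):
            if phase_idx > 0:
                phase_transition_reset(
                    hab, set(config.phases[phase_idx - 1].reinforced),
                    set(phase.reinforced))
                if config.cognitive_on:
                    cognitive = _fresh_cognitive(config, phase)
            for _ in range(phase.n_trials):
                trial_idx += 1
                rec, cognitive = run_trial(
                    config, weights, hab, rng, reinforced=phase.reinforced,
                    cognitive=cognitive, engine=engine, run=run_idx,
                    trial=trial_idx, phase=phase_idx)
                row = {
                    "run": run_idx, "trial": trial_idx, "phase": phase_idx,
                    "gexp_row": rec.gexp.row, "gexp_col": rec.gexp.col,
                    "x": rec.x_p[0], "y": rec.x_p[1], "moved": rec.moved,
                    "hit": rec.hit if rec.hit is not None else "",
                    "reinforced_hit": rec.reinforced_hit,
                }
                for tid in target_ids:
                    row[f"dist_{tid}"] = rec.distances[tid]
                    row[f"n_{tid}"] = rec.hab_counts.get(tid, 0)
                rows.append(row)
                if config.log_weights == "trials":
                    traj[trial_idx - 1] = weights.w_ctx_d1
            if config.log_weights is not None:
                weight_segments[(run_idx, phase_idx)] = weights.w_ctx_d1.copy()
        if config.log_weights == "trials":
            weight_trials[run_idx] = traj

    return ExperimentResult(config=config, trials=pd.DataFrame(rows),
                            weight_segments=weight_segments,
                            weight_trials=weight_trials)


def trace_trial(
    config: ExperimentConfig,
    gexp: ChannelIndex,
    weights: PlasticWeights | None = None,
    rng: np.random.Generator | None = None,
    areas: tuple = ("m", "t", "d1", "d2", "stn", "gpe", "snr"),
):
    """Step-by-step single trial recording all area activity.

    Slow path over :func:`bgaction.circuit.network_step` (one call per
    time step), used for activity dumps in the style of the
    neural-activity figures.  Returns ``(frame, x_p_final)`` where
    ``frame`` is a long-format table with one row per
    step x area x channel (columns: step, area, channel, row, col,
    activation, output).  Produces trajectories identical to the
    compiled whole-trial path.
    """
    from .behavior import MotorState, motor_step, readout_movement_target
    from .circuit import AREA_ORDER, network_step

    if weights is None:
        weights = PlasticWeights()
    if rng is None:
        rng = np.random.Generator(np.random.PCG64(0))
    state = assemble_network(config.model)
    e_stack = explorer_field_stack(gexp, config.explorer)
    motor = MotorState(lam_m=config.lam_m, start=config.start)
    idx = [AREA_ORDER.index(a) for a in areas]
    chans = np.arange(N_CHANNELS)
    rows_, cols_ = np.divmod(chans, 14)
    frames = []
    for t in range(config.explorer.trial_steps):
        network_step(state, e_stack[t], weights, config.noise_sigma, rng)
        x_m = readout_movement_target(state.cortex_output(), config.eta)
        motor_step(motor, x_m)
        for a_i, a_name in zip(idx, areas):
            frames.append(pd.DataFrame({
                "step": t, "area": a_name, "channel": chans,
                "row": rows_, "col": cols_,
                "activation": state.a[a_i].copy(),
                "output": state.y[a_i].copy(),
            }))
    return pd.concat(frames, ignore_index=True), motor.x_p


# ---------------------------------------------------------------------------
# bias-zone mapping
# ---------------------------------------------------------------------------


@dataclass
class BiasZoneMap:
    """Outcome of probing every possible ``G_exp`` after forced training.

    ``frame`` has one row per channel with booleans ``moved_to_gexp``
    (end position within the target radius of the focus's own point) and
    ``hit_target`` (end position within the trained target), plus a
    derived ``label`` giving ``moved_to_gexp`` precedence.
    """

    n_pretraining: int
    target_id: str
    frame: pd.DataFrame

    @property
    def hit_target_channels(self) -> set:
        f = self.frame
        return set(map(tuple, f.loc[f["hit_target"], ["row", "col"]].values))


def map_bias_zone(n_hits: int, config: ExperimentConfig | None = None,
                  target_id: str = "G1") -> BiasZoneMap:
    """Train by forcing ``G_exp`` onto the target center, then probe.

    A fresh model is given ``n_hits`` trials with ``G_exp`` fixed at the
    channel of the target center and learning on; learning is then
    frozen and one evaluation trial is run for each of the 196 possible
    ``G_exp`` values.  Deterministic (no noise is used even if the
    config requests it).
    """
    if n_hits < 0:
        raise ValueError("n_hits must be >= 0")
    if config is None:
        config = preset_experiments("exp1")
    config = replace(config, noise_sigma=0.0, bias_mode="bg")
    engine = _TrialEngine(config)
    target = config.targets[target_id]
    center_ch = ChannelIndex.nearest(target.center)
    weights = PlasticWeights()
    hab = HabituationState(beta=config.beta)
    rng = np.random.Generator(np.random.PCG64(0))  # unused: no noise, forced focus
    reinforced = (target_id,)
    for t in range(n_hits):
        run_trial(config, weights, hab, rng, reinforced=reinforced,
                  gexp=center_ch, engine=engine, trial=t + 1)

    rows = []
    for flat in range(N_CHANNELS):
        gexp = ChannelIndex.from_flat(flat)
        rec, _ = run_trial(config, weights, hab, rng, reinforced=reinforced,
                           gexp=gexp, learning=False, engine=engine)
        to_gexp = float(np.hypot(*(rec.x_p - gexp.point))) < target.radius
        hit_t = target.contains(rec.x_p)
        label = ("moved_to_gexp" if to_gexp
                 else "hit_target" if hit_t else "other")
        rows.append({"row": gexp.row, "col": gexp.col,
                     "moved_to_gexp": to_gexp, "hit_target": hit_t,
                     "label": label})
    return BiasZoneMap(n_pretraining=n_hits, target_id=target_id,
                       frame=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

PRESET_NAMES = (
    "exp1", "exp2", "exp3", "exp4-far", "exp4-near",
    "exp5-bg", "exp5-cognitive", "exp5-both",
)


def preset_experiments(name: str, **overrides) -> ExperimentConfig:
    """The standard experiment batteries.

    ``exp1``: one target (G1), BG biasing, 50 runs x 300 trials.
    ``exp2``: G1 and G2far reinforced simultaneously.
    ``exp3``: G1 / G2far / G1 over three 300-trial phases (900 trials).
    ``exp4-far`` / ``exp4-near``: G1 for 300 trials then G2far / G2near.
    ``exp5-bg`` / ``exp5-cognitive`` / ``exp5-both``: single target under
    BG-only, Cognitive-only (plasticity off) or combined biasing.
    """
    key = name.lower().replace("_", "-")
    presets = {
        "exp1": dict(phases=(Phase(300, ("G1",)),), target_ids=("G1",)),
        "exp2": dict(phases=(Phase(300, ("G1", "G2far")),),
                     target_ids=("G1", "G2far")),
        "exp3": dict(phases=(Phase(300, ("G1",)), Phase(300, ("G2far",)),
                             Phase(300, ("G1",))),
                     target_ids=("G1", "G2far")),
        "exp4-far": dict(phases=(Phase(300, ("G1",)), Phase(300, ("G2far",))),
                         target_ids=("G1", "G2far")),
        "exp4-near": dict(phases=(Phase(300, ("G1",)), Phase(300, ("G2near",))),
                          target_ids=("G1", "G2near")),
        "exp5-bg": dict(phases=(Phase(300, ("G1",)),), target_ids=("G1",),
                        bias_mode="bg"),
        "exp5-cognitive": dict(phases=(Phase(300, ("G1",)),),
                               target_ids=("G1",), bias_mode="cognitive"),
        "exp5-both": dict(phases=(Phase(300, ("G1",)),), target_ids=("G1",),
                          bias_mode="both"),
    }
    if key not in presets:
        raise ValueError(f"unknown experiment preset {name!r}; "
                         f"known: {', '.join(PRESET_NAMES)}")
    kwargs = dict(name=key, **presets[key])
    kwargs.update(overrides)
    return ExperimentConfig(**kwargs)
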