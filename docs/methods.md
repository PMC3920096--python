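# Methods

## Model structure

Every brain area is a population of 196 leaky-integrator rate units,
one per action channel on a 14 × 14 grid (Context is a single unit with
constant output 1).  Units update in discrete time,

    a(t+1) = (1 − k) a(t) + k u(t),      y = clip(m (a − ε), 0, 1),

with decay rate `k = 0.25` everywhere (integration over ≈ 4 steps).
A trial (one movement) lasts `T_E = 80` steps; all activations are
reset to zero between trials, so trials are independent movements.
The update sweep per step is Cortex → (noise) → {D1, D2, STN} → GPe →
SNr → Thalamus, each area reading the freshly computed upstream outputs
(STN reads the previous step's GPe).  A step-by-step reference path and
a compiled whole-trial path execute the same kernel and are verified
bit-identical in the tests.

### Wiring and signs

All projections are channelwise one-to-one except the STN efferents,
which are diffuse (each STN unit excites every SNr and GPe unit; the
kernels use the channel sum).  Striatal input is scaled by tonic
dopamine `λ_DA = 0.2` — facilitatory `(1+λ)` on D1, suppressive `(1−λ)`
on D2.  Phasic dopamine is not simulated; its effect enters only
through the reinforcement rule's habituation factor.

### Area and gain parameters (calibrated defaults)

The exact unit equations and constants of the original formulation are
not part of the public record, so the functional forms above follow the
standard channel-based selection architecture and the constants below
were fixed by a one-time calibration against three gates, then frozen:
(i) the untrained model must move to the focus `G_exp` for **all 196**
possible foci and hit a channel-centered target from exactly its 5
in-target foci; (ii) the bias zone must grow monotonically and
smoothly with forced training, reaching the whole grid in the saturated
limit; (iii) the single-target battery must reproduce the reference
acquisition statistics (hit proportion ≈ 0.8 at movement 300; streaks
≈ 40% / 80% by movements 100 / 300) and the noise ladder
0.82 / 0.64 / 0.53 / 0.20 with strict monotonicity.

| parameter | value | role |
|---|---|---|
| ε, m (Cortex) | 0.0, 1 | suppressed channels sit at `w_EM·e` |
| ε, m (Thalamus) | 0.0, 1 | gated purely by SNr inhibition |
| ε, m (D1, D2) | 0.15, 2 | graded striatal response; sets the bias-zone opening threshold |
| ε, m (STN) | 0.4, 1 | silent at rest; only near-winning channels recruit the surround |
| ε, m (GPe, SNr) | −0.2, 1 | tonic output 0.2 at rest |
| w_EM | 0.47 | Explorer→Cortex; keeps a blocked focus just below η |
| w_MT, w_TM | 1.0, 1.5 | loop gain 1.5 > 1: ignition is self-sustaining (hysteresis) |
| w_SNr→T | 1.0 | tonic gate |
| w_M→STN, w_C→STN | 1.0, 0.2 | action request + constant context drive |
| w_D1→SNr | 0.5 | focused dip, deliberately capped below the recruited surround |
| w_D2→GPe, w_GPe→STN | 1.0, 1.0 | STN regulation (capacity scaling) |
| w_STN→SNr, w_STN→GPe | 0.9, 0.9 | diffuse surround |
| w_GPe→SNr | 0.1 | mild equalization |

Two mechanisms were decisive in calibration.  First, the **direct
Explorer drive is sub-threshold** (`w_EM · 1 = 0.47 < η = 0.5`): a
focus channel crosses the voting threshold only with thalamic help, so
a trained channel that ignites first and recruits the diffuse surround
can block the focus entirely.  This is what makes the bias zone
possible, and it also makes performance genuinely noise-sensitive (the
margin below η is 0.03).  Second, the **D1→SNr gain is capped at 0.5**:
a channel's own dip cannot cancel a fully recruited surround, which
prevents two strongly driven channels from being co-selected (the
failure mode being an end position between the two).  A consequence is
that the winner's SNr output dips below tonic only during the ignition
window and partially recovers once the surround is up, ending as the
unique minimum (~0.25) far below the elevated surround (~0.65) rather
than below rest; selection is maintained by loop hysteresis, not by a
permanently silenced SNr channel.  A variant with a deeper dip
(gain 0.6) keeps the winner below tonic throughout but degrades the
streak statistics and the noise ladder, and was rejected.

## Explorer

For a chosen focus `G_exp`, every channel's early output is
`baseline + (A_i − baseline)·t/t_focus` with Gaussian amplitude profile
`A_i = baseline + (1−baseline)·exp(−d_i²/2σ_E²)` (baseline 0.1,
σ_E = 3 grid units, d_i the grid distance to the focus).  Non-focus
channels switch off on a distance-ranked schedule — turn-off onset
`(t_focus − t_decay)(1 − d_i/2d_max)`, linear decay over `t_decay = 5`
steps — so the farthest channels die first and every decay completes by
`t_focus = 50`.  From `t_focus` to `t_off = 70` the field is exactly
the indicator of `G_exp`; afterwards it is zero.  The field is
non-increasing in distance from the focus at every step.

The race between a trained channel's ignition (driven by the weak
baseline excitation plus its learned SNr dip) and the focus's turn-off
deadline is what grades the bias zone: deeper learned dips ignite
earlier and from weaker excitation, so the zone radius grows with the
learned weights.

## Behavior

Cortex units with output strictly above `η = 0.5` vote for their grid
point, weighted by output; the motor plant relaxes the position toward
the vote with gain `λ_m = 0.2` per step from the workspace center
(6.5, 6.5).  Only `x_p(T_E)` is evaluated; the hit test is strict
(`< θ_G = 1.1`), so a channel-centered target is hit from its center
and four orthogonal neighbors but not from diagonal neighbors.  A trial
in which no unit ever crosses η is recorded as "no movement", keeps
`x_p(T_E) = x_p(0)`, counts as a miss, and triggers no weight change.

## Plasticity

Reinforcement: `Δw = α β^(N_k−1) y_pre y_post (W_max − w)` applied to
the active channel's four weights, with α = 0.11 (calibrated),
β = 0.825, `W_max = 1`.  The active channel is the argmax cortex output
at `T_E` (ties broken by lowest (row, col); with the selection circuit
ties are a measure-zero event).  `N_k` counts *reinforced* hits of
target k; hits of a currently unreinforced target are treated as
misses (extinction), which is what drives unlearning in the
phase-change experiments.  Extinction: `Δw = −α_dec y_pre y_post`
(α_dec = 0.005, calibrated) with floor clipping at 0 (Cortex→striatum)
and −0.1 (Context→striatum).  Extinction is activity-gated: unvisited
channels never decay.  The slow extinction rate relative to
acquisition is required both for re-acquisition memory (the residual
weights behind faster relearning) and for stability under cortical
noise, where occasional misses at a learned channel must not erase it —
the habituated reinforcement cannot restore what extinction removes.
Cortex→striatum weights are initialized at 0.5 (the untrained circuit
must respond to cortical drive), Context→striatum at 0.

At a reinforcement-schedule boundary the habituation count of every
target whose reinforced status changes is reset to zero, so the first
hit after a schedule change is fully novel again.

## Cognitive biasing

The cognitive policy selects `G_exp` uniformly from a disc centered on
the target whose radius shrinks geometrically on each reinforced hit,
`r ← max(θ_G, 0.8 r)`, from an initial radius covering the grid.  At
the floor the candidate set is exactly the five in-target channels, so
the many-hit limit is pure repetition.  In cognitive-only mode
plasticity is off; in combined mode both mechanisms run.

## Synthetic data and what the tests show

All data are generated internally; there are no external inputs.  The
experiment batteries define the study conditions: 50 independent runs
per battery (each with a child seed spawned from the master seed), 300
movements per phase, targets G1 at (10, 3), G2far at (3, 10), G2near at
(7, 3), all of radius 1.1.  The generator emulates end-point reaching
with a deterministic plant and optional signal-dependent cortical
noise; it does not emulate trajectory costs, kinematic arms, gestural
action components, reaction times, or trial-to-trial carry-over of
neural state, so passing tests speak to end-point selection statistics
only, not to movement execution in real effectors.

## Numerical choices

- The whole-trial inner loop is compiled with numba (fastmath off);
  results are bit-reproducible for a given seed and identical to the
  step-by-step reference path.
- The redistribution fit minimizes raw-scale squared error of
  chunk-1-normalized counts against `e^{b(j−1)}` over b ∈ [−10, 10]
  (coarse grid then bounded Brent), so zero counts need no log
  transform; zones with no chunk-1 movements are invalid and exclude
  the run from condition comparisons.  Runs whose movements are fully
  confined within chunk 1 saturate all three rates at the bound and
  contribute zero pairwise differences; this dilutes the combined-bias
  condition's `b₂−b₁` comparison, whose one-tailed significance at 50
  runs is accordingly not robust (the `b₃−b₂` comparison is).
- One-sample one-tailed t-tests use the classical statistic; an
  all-zero difference sample is reported as t = 0, p = 0.5.
- Histogram binning for condition comparisons uses 20 uniform bins over
  the pooled range of all differences under comparison.

## Known limitations

- Absolute activity levels are calibration artifacts; only the
  qualitative circuit behavior (selection, disinhibition, surround,
  hysteresis) and the behavioral statistics were targeted.
- A single context is modeled (one Context unit); multi-context
  learning is out of scope.
- The combined-bias redistribution signature is weaker than the
  cognitive-only one (see above), matching the qualitative ordering of
  the two conditions but not always reaching significance at 50 runs.
- Batteries are sized exactly as the study conditions specify
  (50 × 300); the simulator runs ~4 s per battery on one CPU, so no
  scaling down was needed.
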