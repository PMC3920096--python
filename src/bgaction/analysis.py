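"""Behavioral statistics on the per-trial tables.

All functions here are pure functions of the result tables produced by
:mod:`bgaction.experiments`; re-running an analysis never touches
simulation state.  The centerpiece is the *redistribution* statistic:
misses are binned into three spatial zones (annuli around the target, in
units of the target radius) and three 100-trial temporal chunks; the
decline of each zone's counts across chunks is summarized by the rate
``b`` of an exponential fit ``e^{b (j - 1)}`` to chunk-normalized
counts.  Under BG-mediated biasing the zone nearest the target empties
first (``b_1 < b_2 < b_3``, pairwise differences positive); under
Cognitive biasing the farthest zone empties first and the differences
reverse sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "RedistributionFit",
    "ConditionComparison",
    "hit_proportion_curve",
    "streak_achieved_by",
    "streak_attainment",
    "classify_two_target_run",
    "assign_zone",
    "zone_chunk_counts",
    "fit_redistribution",
    "fit_exponential_rate",
    "bias_condition_differences",
    "pooled_bin_edges",
    "preferred_channel_tracking",
]

N_ZONES = 3
N_CHUNKS = 3
B_BOUNDS = (-10.0, 10.0)  #: search interval for the exponential rate


# ---------------------------------------------------------------------------
# hit curves, streaks, run classification
# ---------------------------------------------------------------------------


def _hit_matrix(trials: pd.DataFrame, column: str = "reinforced_hit") -> np.ndarray:
    """(n_runs, n_trials) boolean matrix, runs sorted, trials in order."""
    pivot = trials.pivot_table(index="run", columns="trial", values=column,
                               aggfunc="first")
    if pivot.isna().any().any():
        raise ValueError("runs have unequal trial counts")
    return pivot.to_numpy().astype(bool)


def hit_proportion_curve(trials: pd.DataFrame, target_id: str | None = None) -> pd.Series:
    """Fraction of runs whose trial-t movement hit, per trial index.

    By default a hit means "hit the currently reinforced target"; pass
    ``target_id`` to follow one specific target instead (as in the
    phase-change experiments where the curves of the old and new target
    are plotted separately).
    """
    if target_id is None:
        hits = _hit_matrix(trials)
    else:
        t = trials.copy()
        t["_hit_this"] = t["hit"] == target_id
        hits = _hit_matrix(t, "_hit_this")
    curve = hits.mean(axis=0)
    return pd.Series(curve, index=np.arange(1, curve.size + 1), name="hit_proportion")


def streak_achieved_by(run_hits, streak_len: int = 10,
                       by_trial: int | None = None) -> bool:
    """True iff ``streak_len`` consecutive hits complete at a trial <= ``by_trial``."""
    if streak_len < 1:
        raise ValueError("streak_len must be >= 1")
    h = np.asarray(run_hits, dtype=bool)
    if by_trial is not None:
        h = h[:by_trial]
    run = 0
    for v in h:
        run = run + 1 if v else 0
        if run >= streak_len:
            return True
    return False


def streak_attainment(trials: pd.DataFrame, streak_len: int = 10,
                      checkpoints=(50, 100, 150, 200, 250, 300)) -> pd.Series:
    """Proportion of runs with a completed streak by each checkpoint."""
    hits = _hit_matrix(trials)
    out = {c: np.mean([streak_achieved_by(h, streak_len, c) for h in hits])
           for c in checkpoints}
    return pd.Series(out, name="streak_attainment")


def classify_two_target_run(run_trials: pd.DataFrame,
                            first: str = "G1", second: str = "G2far") -> str:
    """Label a two-target run by where its movements went.

    Strict-majority rules take precedence: more than half of all
    movements hitting one target makes the run biased to that target;
    otherwise more than a quarter on each makes it ``both``; anything
    else is ``none``.
    """
    n = len(run_trials)
    h1 = int((run_trials["hit"] == first).sum())
    h2 = int((run_trials["hit"] == second).sum())
    if h1 * 2 > n:
        return f"{first}_biased"
    if h2 * 2 > n:
        return f"{second}_biased"
    if h1 * 4 > n and h2 * 4 > n:
        return "both"
    return "none"


# ---------------------------------------------------------------------------
# spatial zones and the redistribution fit
# ---------------------------------------------------------------------------


def assign_zone(d_x: float, theta_g: float = 1.1):
    """Spatial zone of a movement at distance ``d_x`` from target center.

    ``at_target`` for hits (``d_x < theta_g``, excluded from the zones);
    zone 1 for ``theta_g < d_x <= 5 theta_g``; zone 2 up to ``9 theta_g``
    (both upper bounds inclusive); zone 3 beyond.
    """
    if d_x < 0:
        raise ValueError("distance must be >= 0")
    if d_x < theta_g:
        return "at_target"
    if d_x <= 5 * theta_g:
        return 1
    if d_x <= 9 * theta_g:
        return 2
    return 3


def zone_chunk_counts(run_trials: pd.DataFrame, target_id: str = "G1",
                      chunk_size: int = 100, theta_g: float = 1.1) -> np.ndarray:
    """(3, 3) array of miss counts: ``counts[i - 1, j - 1]`` is the number
    of zone-``i`` movements in temporal chunk ``j``."""
    n = len(run_trials)
    if n != N_CHUNKS * chunk_size:
        raise ValueError(
            f"run has {n} trials; expected {N_CHUNKS} chunks of {chunk_size}")
    d = run_trials[f"dist_{target_id}"].to_numpy()
    counts = np.zeros((N_ZONES, N_CHUNKS), dtype=int)
    for j in range(N_CHUNKS):
        for dist in d[j * chunk_size:(j + 1) * chunk_size]:
            z = assign_zone(float(dist), theta_g)
            if z != "at_target":
                counts[z - 1, j] += 1
    return counts


def fit_exponential_rate(counts) -> float:
    """Least-squares rate ``b`` of ``e^{b (j - 1)}`` to chunk-1-normalized
    counts over chunks ``j = 1..3``.

    The fit is on the raw (not log) scale so zero counts are admissible;
    a coarse grid locates the basin and Brent refines, so the result
    matches a fine grid search over :data:`B_BOUNDS`.
    """
    c = np.asarray(counts, dtype=float)
    if c.shape != (N_CHUNKS,):
        raise ValueError(f"need {N_CHUNKS} chunk counts")
    if c[0] <= 0:
        raise ValueError("fit undefined when the first chunk has no movements")
    norm = c / c[0]
    j = np.arange(N_CHUNKS, dtype=float)

    def sse(b):
        return float(np.sum((np.exp(b * j) - norm) ** 2))

    grid = np.linspace(*B_BOUNDS, 801)
    b0 = grid[int(np.argmin([sse(b) for b in grid]))]
    lo = max(B_BOUNDS[0], b0 - 0.05)
    hi = min(B_BOUNDS[1], b0 + 0.05)
    res = optimize.minimize_scalar(sse, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-8})
    return float(res.x) if res.fun <= sse(b0) else float(b0)


@dataclass
class RedistributionFit:
    """Per-run zone-decline rates ``b_1, b_2, b_3`` with diagnostics."""

    b: tuple  #: rate per zone; ``nan`` where invalid
    valid: tuple  #: True where the zone had chunk-1 movements
    counts: np.ndarray  #: (3 zones, 3 chunks) miss counts

    @property
    def all_valid(self) -> bool:
        return all(self.valid)

    def difference(self, hi: int, lo: int) -> float:
        """``b_hi - b_lo`` (1-based zone indices)."""
        return self.b[hi - 1] - self.b[lo - 1]


def fit_redistribution(run_trials: pd.DataFrame, target_id: str = "G1",
                       chunk_size: int = 100, theta_g: float = 1.1) -> RedistributionFit:
    """Zone/chunk binning plus the exponential-rate fit for one run."""
    counts = zone_chunk_counts(run_trials, target_id, chunk_size, theta_g)
    b, valid = [], []
    for i in range(N_ZONES):
        if counts[i, 0] > 0:
            b.append(fit_exponential_rate(counts[i]))
            valid.append(True)
        else:
            b.append(float("nan"))
            valid.append(False)
    return RedistributionFit(b=tuple(b), valid=tuple(valid), counts=counts)


# ---------------------------------------------------------------------------
# condition comparison (pairwise b differences, one-tailed t-tests)
# ---------------------------------------------------------------------------


@dataclass
class ConditionComparison:
    """Per-run differences ``b_3 - b_2`` and ``b_2 - b_1`` for one bias
    condition, with one-tailed one-sample t-tests in a stated direction."""

    direction: str
    diffs_32: np.ndarray
    diffs_21: np.ndarray
    t_32: float
    p_32: float
    t_21: float
    p_21: float
    n_valid: int
    n_excluded: int
    bin_edges: np.ndarray | None = None


def _one_tailed_t(x: np.ndarray, direction: str) -> tuple:
    """One-sample t against mean 0; ``direction`` picks the alternative."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 valid runs for a t-test")
    if np.ptp(x) == 0.0:
        if x[0] == 0.0:
            return 0.0, 0.5  # degenerate all-zero sample: no evidence either way
        sign = np.sign(x[0]) if direction == "positive" else -np.sign(x[0])
        return float(sign * np.inf), 0.0 if sign > 0 else 1.0
    alt = "greater" if direction == "positive" else "less"
    res = stats.ttest_1samp(x, 0.0, alternative=alt)
    return float(res.statistic), float(res.pvalue)


def bias_condition_differences(fits, direction: str,
                               bin_edges: np.ndarray | None = None) -> ConditionComparison:
    """Pairwise-by-run ``b`` differences and their one-tailed tests.

    ``fits`` is a sequence of :class:`RedistributionFit`; runs lacking a
    valid ``b`` in any zone are excluded (and counted).  ``direction``
    is ``"positive"`` (BG-bias expectation) or ``"negative"``
    (Cognitive-bias expectation).  Histogram ``bin_edges`` covering the
    pooled range of all conditions under comparison may be supplied (see
    :func:`pooled_bin_edges`).
    """
    if direction not in ("positive", "negative"):
        raise ValueError("direction must be 'positive' or 'negative'")
    valid = [f for f in fits if f.all_valid]
    n_excluded = len(fits) - len(valid)
    if len(valid) < 2:
        raise ValueError("insufficient data: need >= 2 runs with all zones valid")
    d32 = np.array([f.difference(3, 2) for f in valid])
    d21 = np.array([f.difference(2, 1) for f in valid])
    t32, p32 = _one_tailed_t(d32, direction)
    t21, p21 = _one_tailed_t(d21, direction)
    return ConditionComparison(direction=direction, diffs_32=d32, diffs_21=d21,
                               t_32=t32, p_32=p32, t_21=t21, p_21=p21,
                               n_valid=len(valid), n_excluded=n_excluded,
                               bin_edges=bin_edges)


def pooled_bin_edges(difference_arrays, n_bins: int = 20) -> np.ndarray:
    """Twenty evenly-spaced bins over the pooled range of all b-differences
    from all conditions being compared."""
    pooled = np.concatenate([np.asarray(a, dtype=float).ravel()
                             for a in difference_arrays])
    if pooled.size == 0:
        raise ValueError("no differences to bin")
    lo, hi = float(pooled.min()), float(pooled.max())
    if lo == hi:
        lo, hi = lo - 0.5, hi + 0.5
    return np.linspace(lo, hi, n_bins + 1)


# ---------------------------------------------------------------------------
# preferred-channel weight tracking
# ---------------------------------------------------------------------------


def preferred_channel_tracking(segment_weights) -> tuple:
    """Preferred (argmax Context->D1 weight) channel per segment end.

    ``segment_weights`` is a sequence of weight vectors, one per
    300-movement segment end.  Returns ``(channels, excluded)`` where
    ``channels`` are flat channel indices and ``excluded`` is True iff
    the first and last segments disagree (runs whose preferred D1 unit
    changed are excluded from the weight-trajectory averages).  All-zero
    or tied vectors resolve to the lowest (row, col) channel.
    """
    segs = [np.asarray(w, dtype=float) for w in segment_weights]
    if not segs:
        raise ValueError("segment weight log is missing or empty")
    channels = tuple(int(np.argmax(w)) for w in segs)
    excluded = channels[0] != channels[-1]
    return channels, excluded
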