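"""Behavioral statistics: curves, streaks, classification, zones, the
exponential redistribution fit and its condition comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from bgaction.analysis import (RedistributionFit, assign_zone,
                               bias_condition_differences,
                               classify_two_target_run, fit_exponential_rate,
                               fit_redistribution, hit_proportion_curve,
                               pooled_bin_edges, preferred_channel_tracking,
                               streak_achieved_by, streak_attainment,
                               zone_chunk_counts)


def make_trials(hits_per_run, dists=None):
    """Trial table from per-run boolean hit sequences."""
    rows = []
    for run, hits in enumerate(hits_per_run):
        for t, h in enumerate(hits, start=1):
            d = 0.0 if h else (dists[run][t - 1] if dists is not None else 5.0)
            rows.append({"run": run, "trial": t, "phase": 0,
                         "hit": "G1" if h else "", "reinforced_hit": bool(h),
                         "dist_G1": d})
    return pd.DataFrame(rows)


class TestHitCurveAndStreaks:
    def test_all_hit_gives_one(self):
        t = make_trials([[True] * 5, [True] * 5])
        assert (hit_proportion_curve(t) == 1.0).all()

    def test_always_miss_stub_gives_zeros(self):
        t = make_trials([[False] * 5, [False] * 5])
        assert (hit_proportion_curve(t) == 0.0).all()

    def test_fraction_of_runs(self):
        t = make_trials([[True, False], [False, False], [True, True],
                         [True, False]])
        curve = hit_proportion_curve(t)
        assert curve.loc[1] == pytest.approx(3 / 4)
        assert curve.loc[2] == pytest.approx(1 / 4)

    def test_untrained_first_trial_expectation(self):
        """Enumerating every possible focus of the untrained model, the
        chance of hitting a channel-centered target is exactly the 5
        in-target channels out of 196."""
        from bgaction.experiments import _TrialEngine, preset_experiments
        from bgaction.circuit import ChannelIndex
        from bgaction.plasticity import PlasticWeights

        cfg = preset_experiments("exp1")
        eng = _TrialEngine(cfg)
        target = cfg.targets["G1"]
        w = PlasticWeights()
        hits = sum(
            target.contains(eng.simulate(ChannelIndex.from_flat(i), w, None)[0])
            for i in range(196))
        assert hits / 196 == pytest.approx(5 / 196)

    @pytest.mark.parametrize(
        "hits, by, expected",
        [(range(4, 14), 50, True),       # hits at trials 5..14 complete by 50
         (range(4, 13), 300, False),     # max nine consecutive
         (range(290, 300), 300, True),   # completes exactly at 300
         (range(290, 300), 250, False)],
        ids=["early", "nine-only", "at-300", "not-by-250"],
    )
    def test_streak_window_completion(self, hits, by, expected):
        seq = np.zeros(300, dtype=bool)
        seq[list(hits)] = True
        assert streak_achieved_by(seq, 10, by) is expected

    def test_attainment_is_cumulative(self):
        seq = np.zeros(300, dtype=bool)
        seq[120:135] = True
        t = make_trials([seq])
        att = streak_attainment(t)
        assert att.loc[100] == 0.0
        assert att.loc[150] == 1.0
        assert (att.diff().dropna() >= 0).all()


class TestTwoTargetClassification:
    def run(self, h1, h2, n=300):
        hit = [""] * n
        for i in range(h1):
            hit[i] = "G1"
        for i in range(h1, h1 + h2):
            hit[i] = "G2far"
        return pd.DataFrame({"hit": hit})

    @pytest.mark.parametrize("h1, h2, label", [
        (180, 0, "G1_biased"),       # strict majority
        (0, 160, "G2far_biased"),
        (80, 80, "both"),            # > quarter each
        (10, 10, "none"),
        (160, 90, "G1_biased"),      # majority rule precedes 'both'
        (150, 80, "both"),           # exactly half is not a majority
    ])
    def test_rules(self, h1, h2, label):
        assert classify_two_target_run(self.run(h1, h2)) == label


class TestZones:
    theta = 1.1

    @pytest.mark.parametrize("d_over_theta, zone", [
        (0.0, "at_target"), (0.99, "at_target"),
        (1.01, 1), (3.0, 1), (5.0, 1),       # upper bound inclusive
        (5.01, 2), (9.0, 2),
        (9.01, 3), (10.0, 3), (15.0, 3),
    ])
    def test_boundaries(self, d_over_theta, zone):
        assert assign_zone(d_over_theta * self.theta, self.theta) == zone

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            assign_zone(-0.1)

    def test_partition_counts_plus_hits_equals_total(self, rng):
        dists = rng.uniform(0, 16, size=(1, 300))
        hits = dists[0] < self.theta
        t = make_trials([hits], dists=dists)
        counts = zone_chunk_counts(t, "G1")
        assert counts.sum() + hits.sum() == 300

    def test_wrong_length_rejected(self):
        t = make_trials([[False] * 200])
        with pytest.raises(ValueError):
            zone_chunk_counts(t, "G1")


class TestExponentialRateFit:
    def _grid_oracle(self, counts, lo=-10.0, hi=10.0, step=1e-4):
        norm = np.asarray(counts, float) / counts[0]
        b = np.arange(lo, hi + step, step)
        j = np.arange(3.0)
        sse = ((np.exp(np.outer(b, j)) - norm) ** 2).sum(axis=1)
        return b[np.argmin(sse)]

    def test_constant_counts_give_zero_rate(self):
        assert fit_exponential_rate([40, 40, 40]) == pytest.approx(0.0, abs=1e-6)

    def test_collinear_counts_recover_exact_rate(self):
        # [100, 10, 1] lies exactly on e^{-ln(10) (j-1)}
        assert fit_exponential_rate([100, 10, 1]) == pytest.approx(
            -np.log(10), abs=1e-6)

    def test_zero_tail_handled_without_log(self):
        b = fit_exponential_rate([50, 0, 0])
        assert np.isfinite(b)
        assert b < -4
        assert b == pytest.approx(self._grid_oracle([50, 0, 0]), abs=1e-3)

    @given(st.tuples(st.integers(1, 120), st.integers(1, 120),
                     st.integers(1, 120)))
    def test_matches_grid_search_oracle(self, counts):
        """For all-positive count triples the least-squares rate agrees
        with a brute-force grid search to within 1e-3."""
        assert fit_exponential_rate(list(counts)) == pytest.approx(
            self._grid_oracle(counts), abs=1e-3)

    def test_first_chunk_zero_rejected(self):
        with pytest.raises(ValueError):
            fit_exponential_rate([0, 5, 5])

    def test_fit_redistribution_flags_invalid_zones(self):
        # all 300 movements in zone 3 -> zones 1 and 2 invalid
        dists = np.full((1, 300), 12.0)
        t = make_trials([[False] * 300], dists=dists)
        fit = fit_redistribution(t)
        assert fit.valid == (False, False, True)
        assert not fit.all_valid
        assert np.isnan(fit.b[0]) and np.isfinite(fit.b[2])


def make_fit(b1, b2, b3):
    return RedistributionFit(b=(b1, b2, b3), valid=(True,) * 3, counts=None)


class TestConditionComparison:
    def test_identical_rates_give_zero_t_and_half_p(self):
        fits = [make_fit(-2.0, -2.0, -2.0)] * 5
        cmp_ = bias_condition_differences(fits, "positive")
        assert cmp_.t_32 == 0.0 and cmp_.p_32 == 0.5
        assert cmp_.t_21 == 0.0 and cmp_.p_21 == 0.5

    def test_graded_rates_significant_in_stated_direction(self, rng):
        """b = (-3, -2, -1) plus small noise: both pairwise differences
        have mean 1 and a one-tailed test in the positive direction
        agrees with the textbook t formula."""
        fits = [make_fit(*(np.array([-3.0, -2.0, -1.0])
                           + rng.normal(0, 0.05, 3))) for _ in range(20)]
        cmp_ = bias_condition_differences(fits, "positive")
        assert cmp_.diffs_32.mean() == pytest.approx(1.0, abs=0.1)
        assert cmp_.diffs_21.mean() == pytest.approx(1.0, abs=0.1)
        assert cmp_.p_32 < 1e-6 and cmp_.p_21 < 1e-6
        x = cmp_.diffs_32
        t_manual = x.mean() / (x.std(ddof=1) / np.sqrt(len(x)))
        assert cmp_.t_32 == pytest.approx(t_manual)
        p_manual = stats.t.sf(t_manual, len(x) - 1)
        assert cmp_.p_32 == pytest.approx(p_manual)

    def test_opposite_direction_not_significant(self, rng):
        fits = [make_fit(*(np.array([-3.0, -2.0, -1.0])
                           + rng.normal(0, 0.05, 3))) for _ in range(20)]
        cmp_ = bias_condition_differences(fits, "negative")
        assert cmp_.p_32 > 0.5 and cmp_.p_21 > 0.5

    def test_invalid_runs_excluded_and_counted(self):
        fits = [make_fit(-3, -2, -1)] * 3 + [
            RedistributionFit(b=(np.nan, -2, -1), valid=(False, True, True),
                              counts=None)]
        cmp_ = bias_condition_differences(fits, "positive")
        assert cmp_.n_valid == 3 and cmp_.n_excluded == 1

    def test_insufficient_valid_runs_rejected(self):
        with pytest.raises(ValueError, match="insufficient"):
            bias_condition_differences([make_fit(-3, -2, -1)], "positive")

    def test_pooled_bins_are_uniform_twenty(self):
        edges = pooled_bin_edges([np.array([-2.0, 1.0]), np.array([0.5, 3.0])])
        assert len(edges) == 21
        assert edges[0] == -2.0 and edges[-1] == 3.0
        widths = np.diff(edges)
        assert widths == pytest.approx(np.full(20, widths[0]))


class TestPreferredChannelTracking:
    def test_stable_preference_included(self):
        w1 = np.zeros(196); w1[42] = 0.5
        w2 = np.zeros(196); w2[100] = 0.4
        w3 = np.zeros(196); w3[42] = 0.6
        channels, excluded = preferred_channel_tracking([w1, w2, w3])
        assert channels == (42, 100, 42)
        assert not excluded

    def test_changed_preference_excluded(self):
        w1 = np.zeros(196); w1[42] = 0.5
        w3 = np.zeros(196); w3[43] = 0.5
        _, excluded = preferred_channel_tracking([w1, w1, w3])
        assert excluded

    def test_all_zero_weights_tie_break_deterministic(self):
        channels, excluded = preferred_channel_tracking([np.zeros(196)] * 3)
        assert channels == (0, 0, 0)
        assert not excluded

    def test_missing_log_rejected(self):
        with pytest.raises(ValueError):
            preferred_channel_tracking([])
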