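"""Episode detection: runs, the 5-min merge rule, duration x severity
qualification, consecutive blood-pressure events and cumulative durations."""

import numpy as np
import pytest

from vitalwatch import (
    ThresholdTier,
    classify_episodes,
    cumulative_duration,
    detect_bp_episodes,
    detect_channel_episodes,
    detect_runs,
    merge_runs,
)
from vitalwatch.episodes import Run

from conftest import brute_force_episodes, make_grid, make_series


def tier(channel="SPO2", direction="below", threshold=85, persist=5):
    return ThresholdTier(channel=channel, direction=direction,
                         threshold=threshold, min_persistence=persist)


class TestDetectRuns:
    def test_sustained_stretch_is_one_run(self):
        g = make_grid("HR", [115.0] * 60)
        runs = detect_runs(g, "HR", "above", 110)
        assert runs == [Run("HR", 0, 59, 60)]

    def test_interrupted_condition_gives_two_runs(self):
        g = make_grid("SPO2", [84, 84, 84, 91, 91, 91, 91, 84, 84, 84])
        runs = detect_runs(g, "SPO2", "below", 85)
        assert [(r.start, r.end, r.true_minutes) for r in runs] == [(0, 2, 3), (7, 9, 3)]

    def test_all_missing_grid_is_empty(self):
        g = make_grid("SPO2", [np.nan] * 20)
        assert detect_runs(g, "SPO2", "below", 92) == []

    def test_missing_minutes_terminate_runs(self):
        g = make_grid("SPO2", [84, np.nan, 84])
        runs = detect_runs(g, "SPO2", "below", 85)
        assert [(r.start, r.end) for r in runs] == [(0, 0), (2, 2)]

    def test_strict_inequality(self):
        g = make_grid("HR", [110.0, 110.0])
        assert detect_runs(g, "HR", "above", 110) == []
        g = make_grid("SPO2", [92.0, 92.0])
        assert detect_runs(g, "SPO2", "below", 92) == []


class TestMergeRuns:
    def test_runs_four_minutes_apart_merge(self):
        runs = [Run("SPO2", 0, 2, 3), Run("SPO2", 7, 9, 3)]
        merged = merge_runs(runs, 5)
        assert merged == [Run("SPO2", 0, 9, 6)]  # gap minutes do not count

    def test_exactly_five_minutes_apart_stay_separate(self):
        runs = [Run("SPO2", 0, 2, 3), Run("SPO2", 8, 10, 3)]
        assert merge_runs(runs, 5) == runs

    def test_single_run_unchanged(self):
        runs = [Run("SPO2", 3, 8, 6)]
        assert merge_runs(runs, 5) == runs

    def test_idempotent_and_never_grows(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            cond = rng.uniform(size=120) < 0.35
            g = make_grid("SPO2", np.where(cond, 80.0, 95.0))
            runs = detect_runs(g, "SPO2", "below", 85)
            once = merge_runs(runs, 5)
            assert merge_runs(once, 5) == once
            assert len(once) <= len(runs)
            # pairwise separations respect the merge gap
            for a, b in zip(once, once[1:]):
                assert b.start - a.end - 1 >= 5


class TestClassify:
    def test_six_minutes_below_85_qualifies(self):
        eps = classify_episodes([Run("SPO2", 0, 5, 6)], tier("SPO2", "below", 85, 5))
        assert len(eps) == 1 and eps[0].duration == 6

    def test_59_minutes_of_tachycardia_fails_the_hour_tier(self):
        eps = classify_episodes([Run("HR", 0, 58, 59)],
                                tier("HR", "above", 110, 60))
        assert eps == []

    def test_bp_tier_refused(self):
        bp = ThresholdTier(channel="SBP", direction="below", threshold=90,
                           min_consecutive=2)
        with pytest.raises(ValueError, match="detect_bp_episodes"):
            classify_episodes([], bp)

    def test_more_severe_threshold_detects_nothing_in_milder_data(self):
        g = make_grid("SPO2", [84.0] * 6)
        assert detect_runs(g, "SPO2", "below", 80) == []


class TestBpEpisodes:
    bp90 = ThresholdTier(channel="SBP", direction="below", threshold=90,
                         min_consecutive=2)

    def test_two_in_a_row_is_one_episode(self):
        s = make_series("SBP", [0, 1800, 3600, 5400], [88, 85, 110, 87])
        eps = detect_bp_episodes(s, self.bp90)
        assert len(eps) == 1
        assert (eps[0].start, eps[0].end) == (0, 1)
        assert eps[0].duration == 30.0  # span between the two measurements

    def test_alternating_never_qualifies(self):
        s = make_series("SBP", [0, 1800, 3600, 5400], [88, 95, 88, 95])
        assert detect_bp_episodes(s, self.bp90) == []

    def test_three_in_a_row_is_still_one_episode(self):
        s = make_series("SBP", [0, 1800, 3600], [85, 85, 85])
        eps = detect_bp_episodes(s, self.bp90)
        assert len(eps) == 1 and eps[0].n_merged == 3

    def test_continuous_tier_refused(self):
        with pytest.raises(ValueError):
            detect_bp_episodes(make_series("SBP", [0], [85]), tier())


class TestCumulativeDuration:
    def test_scattered_minutes_counted(self):
        rng = np.random.default_rng(5)
        values = np.full(500, 95.0)
        idx = rng.choice(500, size=141, replace=False)
        values[idx] = 90.0
        g = make_grid("SPO2", values)
        assert cumulative_duration(g, "SPO2", "below", 92) == 141

    def test_nothing_below_threshold(self):
        g = make_grid("SPO2", [95.0] * 100)
        assert cumulative_duration(g, "SPO2", "below", 92) == 0

    def test_day_night_additivity(self):
        rng = np.random.default_rng(6)
        values = np.where(rng.uniform(size=300) < 0.3, 85.0, 95.0)
        g = make_grid("SPO2", values)
        mask = rng.uniform(size=300) < 0.5
        total = cumulative_duration(g, "SPO2", "below", 92)
        day = cumulative_duration(g, "SPO2", "below", 92, minute_mask=mask)
        night = cumulative_duration(g, "SPO2", "below", 92, minute_mask=~mask)
        assert day + night == total


def random_grid(rng, n):
    """Grid with missing stretches and values hovering around 85."""
    values = 85.0 + rng.normal(0, 4, size=n)
    missing = rng.uniform(size=n) < 0.15
    values[missing] = np.nan
    return make_grid("SPO2", values)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_grids(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(40):
            n = int(rng.integers(1, 301))
            g = random_grid(rng, n)
            persist = int(rng.choice([1, 5, 10, 30, 60]))
            t = tier("SPO2", "below", 85, persist)
            got = detect_channel_episodes(g, t, merge_gap=5)
            expected = brute_force_episodes(g.values.tolist(), "below", 85, 5, persist)
            assert [(e.start, e.end, e.duration) for e in got] == \
                   [(s, e, float(tm)) for s, e, tm in expected]

    def test_nested_severity_is_subset_in_time(self):
        rng = np.random.default_rng(99)
        values = 86 + rng.normal(0, 5, size=400)
        g = make_grid("SPO2", values)
        mild = g.values < 88
        severe = g.values < 85
        assert not (severe & ~mild).any()
        for e in detect_channel_episodes(g, tier("SPO2", "below", 85, 5), 5):
            assert severe[e.start] and severe[e.end]

    def test_episode_durations_bounded_by_cumulative(self):
        rng = np.random.default_rng(123)
        for _ in range(20):
            g = random_grid(rng, 300)
            t = tier("SPO2", "below", 85, 5)
            eps = detect_channel_episodes(g, t, 5)
            cum = cumulative_duration(g, "SPO2", "below", 85)
            assert sum(e.duration for e in eps) <= cum <= len(g)

    def test_inserting_missing_minute_never_creates_episodes(self):
        g = make_grid("SPO2", [84.0] * 12)
        t = tier("SPO2", "below", 85, 5)
        base = detect_channel_episodes(g, t, 5)
        broken = g.values.copy()
        broken[6] = np.nan
        g2 = make_grid("SPO2", broken)
        assert len(detect_channel_episodes(g2, t, 5)) <= len(base)


def test_premerge_persistence_mode_is_stricter():
    # two 3-min runs 2 min apart: merged-time mode qualifies (6 >= 5),
    # pre-merge mode does not (each run alone is below persistence)
    values = [84, 84, 84, 95, 95, 84, 84, 84]
    g = make_grid("SPO2", values)
    t = tier("SPO2", "below", 85, 5)
    assert len(detect_channel_episodes(g, t, 5, "merged")) == 1
    assert len(detect_channel_episodes(g, t, 5, "premerge")) == 0
    # span mode counts the gap minutes toward persistence
    assert len(detect_channel_episodes(g, t, 5, "span")) == 1
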