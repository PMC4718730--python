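"""Sleep-bout calling, hourly summaries, cohort scoring, and permutation tests."""

from itertools import combinations

import numpy as np
import pytest

from hcrtkit.simulate import PhaseParams, SleepSimConfig, simulate_activity_cohort
from hcrtkit.sleep import (
    ActivityTrace,
    call_sleep_bouts,
    compare_genotypes,
    permutation_diff_test,
    rebound_analysis,
    score_cohort,
    summarize_sleep,
)


def trace_of(activity, **kwargs) -> ActivityTrace:
    kwargs.setdefault("larva_id", "L1")
    kwargs.setdefault("genotype", "wt")
    return ActivityTrace(activity=np.asarray(activity, dtype=float), **kwargs)


class TestCallSleepBouts:
    def test_hand_worked_trace(self):
        # (0,0,0,5,0): bouts (start 0, len 3) and (start 4, len 1), sleep 4 min
        bouts = call_sleep_bouts(trace_of([0, 0, 0, 5, 0]))
        assert [(b.start_minute, b.length_min) for b in bouts] == [(0, 3), (4, 1)]
        assert sum(b.length_min for b in bouts) == 4

    def test_fully_active_trace_has_no_bouts(self):
        assert call_sleep_bouts(trace_of([3, 1, 2, 9])) == []

    def test_sixty_zero_minutes_form_one_bout(self):
        bouts = call_sleep_bouts(trace_of([0] * 60))
        assert [(b.start_minute, b.length_min) for b in bouts] == [(0, 60)]

    def test_empty_trace(self):
        assert call_sleep_bouts(trace_of([])) == []

    def test_epsilon_controls_immobility(self):
        trace = trace_of([0.4, 0.4, 2.0])
        assert call_sleep_bouts(trace, immobility_epsilon=0.0) == []
        bouts = call_sleep_bouts(trace, immobility_epsilon=0.5)
        assert [(b.start_minute, b.length_min) for b in bouts] == [(0, 2)]

    def test_total_sleep_equals_sum_of_bout_lengths(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            activity = rng.choice([0.0, 1.0], size=500, p=[0.3, 0.7])
            trace = trace_of(activity)
            bouts = call_sleep_bouts(trace)
            assert sum(b.length_min for b in bouts) == (activity == 0).sum()

    def test_leading_wake_minute_only_shifts_offsets(self):
        base = [0, 0, 5, 0]
        b1 = call_sleep_bouts(trace_of(base))
        b2 = call_sleep_bouts(trace_of([7] + base))
        assert [(b.start_minute - 1, b.length_min) for b in b2] == [
            (b.start_minute, b.length_min) for b in b1
        ]


class TestSummarizeSleep:
    def test_all_zero_day_is_one_long_bout(self):
        trace = trace_of([0] * (24 * 60))
        bouts = call_sleep_bouts(trace)
        s = summarize_sleep(bouts, trace)
        assert (s.hourly["sleep_min"] == 60).all()
        assert s.hourly["n_transitions"].iloc[0] == 1
        assert (s.hourly["n_transitions"].iloc[1:] == 0).all()

    def test_one_minute_alternation(self):
        # wake/sleep alternating for one hour: 30 sleep minutes, 30 onsets,
        # every bout 1 minute long
        activity = [1.0, 0.0] * 30
        trace = trace_of(activity)
        bouts = call_sleep_bouts(trace)
        s = summarize_sleep(bouts, trace)
        row = s.hourly.iloc[0]
        assert row["sleep_min"] == 30
        assert row["n_transitions"] == 30
        assert row["mean_bout_len"] == pytest.approx(1.0)

    def test_transitions_sum_to_bout_count(self):
        rng = np.random.default_rng(1)
        activity = rng.choice([0.0, 2.0], size=24 * 60, p=[0.25, 0.75])
        trace = trace_of(activity)
        bouts = call_sleep_bouts(trace)
        s = summarize_sleep(bouts, trace)
        assert s.hourly["n_transitions"].sum() == len(bouts)

    def test_phase_attribution_follows_photoperiod(self):
        trace = trace_of([1.0] * (24 * 60))
        s = summarize_sleep([], trace)
        phases = s.hourly["phase"].tolist()
        assert phases[:14] == ["light"] * 14
        assert phases[14:] == ["dark"] * 10

    def test_boundary_spanning_bout_belongs_to_onset_hour(self):
        activity = np.ones(180)
        activity[55:70] = 0.0  # bout starts in hour 0, ends in hour 1
        trace = trace_of(activity)
        bouts = call_sleep_bouts(trace)
        s = summarize_sleep(bouts, trace)
        assert s.hourly["n_transitions"].tolist() == [1, 0, 0]
        assert s.hourly.loc[0, "mean_bout_len"] == pytest.approx(15.0)


class TestCohortRecovery:
    def test_scored_cohort_matches_generator_parameters(self):
        config = SleepSimConfig(
            n_larvae_per_genotype=200,
            genotype_params={
                "wt": {"day": PhaseParams(15.0, 10.0), "night": PhaseParams(15.0, 10.0)}
            },
            seed=17,
        )
        traces, truth = simulate_activity_cohort(config)
        cohort = score_cohort(traces)
        mean_bout = cohort["night_bout_len"].mean()
        mean_sleep = cohort["night_sleep_min_per_h"].mean()
        assert mean_bout == pytest.approx(10.0, rel=0.10)
        assert mean_sleep == pytest.approx(15.0, rel=0.05)

    def test_zero_sleep_parameter_gives_fully_active_traces(self):
        config = SleepSimConfig(
            n_larvae_per_genotype=20,
            genotype_params={
                "wt": {"day": PhaseParams(0.0, 1.0), "night": PhaseParams(0.0, 1.0)}
            },
            seed=3,
        )
        traces, _ = simulate_activity_cohort(config)
        for t in traces:
            assert (t.activity > 0).all()

    def test_determinism_under_fixed_seed(self):
        config = SleepSimConfig(n_larvae_per_genotype=5, seed=9)
        t1, _ = simulate_activity_cohort(config)
        t2, _ = simulate_activity_cohort(config)
        for a, b in zip(t1, t2):
            assert np.array_equal(a.activity, b.activity)
        t3, _ = simulate_activity_cohort(SleepSimConfig(n_larvae_per_genotype=5, seed=10))
        assert not all(np.array_equal(a.activity, b.activity) for a, b in zip(t1, t3))


class TestCompareGenotypes:
    def test_identical_groups_yield_null_result(self):
        config = SleepSimConfig(n_larvae_per_genotype=12, seed=2)
        traces, _ = simulate_activity_cohort(config)
        cohort = score_cohort(traces)
        sub = cohort[cohort["genotype"] == "wt"].copy()
        mirrored = sub.copy()
        mirrored["genotype"] = "wt2"
        both = __import__("pandas").concat([sub, mirrored])
        eff, p = compare_genotypes(both, "wt", "wt2", "night", "sleep_min_per_h", seed=0)
        assert eff == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_group_of_one_is_an_error(self):
        import pandas as pd

        cohort = pd.DataFrame(
            {"genotype": ["a", "b", "b"], "night_sleep_min_per_h": [1.0, 2.0, 3.0]}
        )
        with pytest.raises(ValueError, match="at least 2"):
            compare_genotypes(cohort, "a", "b")

    def test_night_difference_detected_day_not(self):
        config = SleepSimConfig(n_larvae_per_genotype=90, seed=31)
        traces, _ = simulate_activity_cohort(config)
        cohort = score_cohort(traces)
        _, p_night = compare_genotypes(
            cohort, "hom", "wt", "night", "sleep_min_per_h", n_permutations=2000, seed=0
        )
        _, p_day = compare_genotypes(
            cohort, "hom", "wt", "day", "sleep_min_per_h", n_permutations=2000, seed=0
        )
        assert p_night < 0.01
        assert p_day > p_night


class TestPermutationExactness:
    def test_agrees_with_exhaustive_enumeration_for_4_plus_4(self):
        rng = np.random.default_rng(5)
        a = rng.normal(1.0, 1.0, 4)
        b = rng.normal(0.0, 1.0, 4)
        eff, p = permutation_diff_test(a, b, seed=0)
        # independent oracle: enumerate all C(8,4) label assignments
        pooled = np.concatenate([a, b])
        obs = a.mean() - b.mean()
        count = total = 0
        for idx in combinations(range(8), 4):
            mask = np.zeros(8, dtype=bool)
            mask[list(idx)] = True
            stat = pooled[mask].mean() - pooled[~mask].mean()
            if abs(stat) >= abs(obs) - 1e-12:
                count += 1
            total += 1
        assert eff == pytest.approx(obs)
        assert p == pytest.approx(count / total)

    def test_monte_carlo_path_is_seeded(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0.5, 1.0, 30)
        b = rng.normal(0.0, 1.0, 30)
        _, p1 = permutation_diff_test(a, b, n_permutations=500, seed=4, max_exact=10)
        _, p2 = permutation_diff_test(a, b, n_permutations=500, seed=4, max_exact=10)
        assert p1 == p2


class TestReboundAnalysis:
    def test_identical_groups_have_zero_difference(self):
        values = [50.0, 55.0, 60.0, 52.0]
        eff, p = rebound_analysis(values, list(values), seed=0)
        assert eff == pytest.approx(0.0)

    def test_window_mismatch_is_an_error(self):
        with pytest.raises(ValueError, match="window"):
            rebound_analysis([1, 2, 3], [1, 2, 3], 540, 480)

    def test_elevated_post_deprivation_sleep_detected_at_study_size(self):
        # n = 13 per treatment; deprived larvae sleep more afterwards
        dep_cfg = SleepSimConfig(
            n_larvae_per_genotype=13,
            genotype_params={"wt": {"day": PhaseParams(3.0, 1.3),
                                    "night": PhaseParams(22.0, 3.0)}},
            seed=41,
        )
        ctrl_cfg = SleepSimConfig(
            n_larvae_per_genotype=13,
            genotype_params={"wt": {"day": PhaseParams(3.0, 1.3),
                                    "night": PhaseParams(15.5, 2.4)}},
            seed=42,
        )
        dep_traces, _ = simulate_activity_cohort(dep_cfg)
        ctrl_traces, _ = simulate_activity_cohort(ctrl_cfg)
        # post-deprivation window: the night phase of the recovery recording
        dep = score_cohort(dep_traces)["night_sleep_min_per_h"] * 10
        ctrl = score_cohort(ctrl_traces)["night_sleep_min_per_h"] * 10
        eff, p = rebound_analysis(dep.tolist(), ctrl.tolist(), 600, 600, seed=0)
        assert eff > 0
        assert p < 0.05
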