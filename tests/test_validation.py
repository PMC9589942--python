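"""Ground-truth subsampling pipeline: filtering, reference fits, ranking, windows."""

import numpy as np
import pandas as pd
import pytest

from crfdk import (
    CohortSpec,
    GroundTruthRecording,
    InfeasiblePatternError,
    NRParams,
    Pattern,
    build_ground_truth,
    consensus_patterns,
    dynamic_window_errors,
    generate_cohort,
    rank_patterns,
    recordings_from_table,
    subsample_pattern_errors,
    unit_inclusion_filter,
)
from crfdk.validation import PatternScore


def make_recording(rates_by_direction, contrasts, n_trials=5, trial_length=2.0, seed=0):
    """Deterministic-rate recording: regular spike trains at the given rates."""
    directions = sorted(rates_by_direction)
    trains = []
    for d in directions:
        rates = rates_by_direction[d]
        trains.append(
            [
                [np.arange(int(round(r * trial_length))) * (trial_length / max(r * trial_length, 1)) * 0.999
                 for _ in range(n_trials)]
                for r in rates
            ]
        )
    return GroundTruthRecording(
        unit_id=0,
        directions=np.array(directions, dtype=float),
        contrasts=np.asarray(contrasts, dtype=float),
        n_trials=n_trials,
        trial_length=trial_length,
        trains=trains,
    )


class TestInclusionFilter:
    @pytest.mark.parametrize("rate,included", [(2.9, False), (3.0, True), (0.0, False)])
    def test_threshold_at_max_contrast(self, rate, included):
        # 10 s trials make fractional rates exactly representable as counts
        rec = make_recording({0.0: [1.0, 2.0, rate]}, [0.0, 50.0, 100.0], trial_length=10.0)
        assert unit_inclusion_filter(rec) is included

    def test_uses_best_direction(self):
        rec = make_recording(
            {0.0: [0.0, 0.0, 1.0], 90.0: [0.0, 2.0, 8.0]}, [0.0, 50.0, 100.0]
        )
        assert unit_inclusion_filter(rec)


class TestBuildGroundTruth:
    def test_recovers_sampled_truth(self, small_cohort):
        """Full-data fits land near the generating parameters at 50 reps x 4 s."""
        rel_errors = []
        for unit in small_cohort:
            gt = build_ground_truth(unit.recording, n_restarts=30, seed=1)
            assert gt.direction == unit.preferred_direction
            rel_errors.append(abs(gt.params.r_max - unit.truth.r_max) / unit.truth.r_max)
        assert np.median(rel_errors) < 0.10

    def test_single_direction_returned(self):
        rec = make_recording({30.0: [1.0, 5.0, 9.0, 12.0]}, [0.0, 30.0, 60.0, 100.0])
        gt = build_ground_truth(rec, n_restarts=10, seed=2)
        assert gt.direction == 30.0

    def test_direction_tie_broken_low(self):
        rates = [1.0, 5.0, 9.0, 12.0]
        rec = make_recording({0.0: rates, 90.0: rates, 180.0: rates}, [0.0, 30.0, 60.0, 100.0])
        assert rec.preferred_direction == 0.0


class TestSubsampling:
    def test_full_pattern_reproduces_reference(self, small_cohort):
        unit = small_cohort[0]
        gt = build_ground_truth(unit.recording, n_restarts=30, seed=3)
        score = subsample_pattern_errors(
            unit.recording,
            gt.params,
            Pattern(24, 50, 4.0),
            scale_id=None,
            n_iterations=2,
            seed=4,
            n_restarts=30,
        )
        assert score.mean.rms_points < 1e-2
        assert score.mean.rms_allpoints < 1e-2

    def test_richer_pattern_scores_better(self, small_cohort):
        unit = small_cohort[0]
        gt = build_ground_truth(unit.recording, n_restarts=30, seed=5)
        rich = subsample_pattern_errors(
            unit.recording, gt.params, Pattern(6, 16, 2.0), 1,
            n_iterations=30, seed=6, n_restarts=5,
        )
        poor = subsample_pattern_errors(
            unit.recording, gt.params, Pattern(4, 8, 1.0), 1,
            n_iterations=30, seed=6, n_restarts=5,
        )
        assert rich.mean.rms_points < poor.mean.rms_points

    @pytest.mark.parametrize(
        "pattern,dimension",
        [
            (Pattern(25, 10, 2.0), "n_points"),
            (Pattern(6, 51, 2.0), "n_trials"),
            (Pattern(6, 10, 5.0), "trial_length"),
        ],
    )
    def test_infeasible_pattern_names_dimension(self, small_cohort, pattern, dimension):
        unit = small_cohort[0]
        with pytest.raises(InfeasiblePatternError, match=dimension):
            subsample_pattern_errors(
                unit.recording, unit.truth, pattern, 1, n_iterations=1, seed=0
            )

    def test_deterministic_under_seed(self, small_cohort):
        unit = small_cohort[0]
        kw = dict(n_iterations=5, seed=11, n_restarts=5)
        a = subsample_pattern_errors(unit.recording, unit.truth, Pattern(6, 8, 2.0), 2, **kw)
        b = subsample_pattern_errors(unit.recording, unit.truth, Pattern(6, 8, 2.0), 2, **kw)
        pd.testing.assert_frame_equal(a.errors, b.errors)


def _fake_score(pattern, err, unit_id=0, scale_id=1):
    errors = pd.DataFrame(
        {
            "err_rms_points": [err],
            "err_rms_allpoints": [err],
            "err_angle_rad": [err],
        }
    )
    return PatternScore(pattern=pattern, scale_id=scale_id, unit_id=unit_id,
                        errors=errors, n_iterations=1)


class TestRanking:
    def test_bottom_ten_are_smallest_errors(self):
        pats = [Pattern(4 + 2 * (i % 3), 1 + i, 1.0) for i in range(20)]
        scores = [_fake_score(p, float(i + 1)) for i, p in enumerate(pats)]
        ranking, best = rank_patterns(scores, "rms_points")
        assert list(ranking["mean_error"])[:3] == [20.0, 19.0, 18.0]
        assert best == pats[:10]

    def test_all_equal_scores_prefer_short_recordings(self):
        pats = [Pattern(4, t, 1.0) for t in range(1, 21)]
        scores = [_fake_score(p, 1.0) for p in reversed(pats)]
        _, best = rank_patterns(scores, "rms_points")
        assert best == pats[:10]  # shortest recording times win ties

    def test_rerun_is_identical(self):
        pats = [Pattern(4, t, 2.0) for t in range(1, 15)]
        scores = [_fake_score(p, float(t % 5)) for t, p in enumerate(pats)]
        a = rank_patterns(scores, "angle")
        b = rank_patterns(scores, "angle")
        pd.testing.assert_frame_equal(a[0], b[0])
        assert a[1] == b[1]


class TestConsensus:
    def test_pattern_topping_all_errors_ranks_first(self):
        star = Pattern(6, 16, 2.0)
        other = Pattern(4, 8, 1.0)
        lists = {
            "rms_points": [[star, other], [star]],
            "rms_allpoints": [[star], [star, other]],
            "angle": [[star, Pattern(8, 8, 3.0)]],
        }
        report = consensus_patterns(lists)
        assert report.tier1[0][0] == star
        assert report.tier1[0][1] == 5

    def test_disjoint_lists_give_empty_tier1(self):
        lists = {
            "rms_points": [[Pattern(4, 1, 1.0)]],
            "rms_allpoints": [[Pattern(6, 1, 1.0)]],
            "angle": [[Pattern(8, 1, 1.0)]],
        }
        report = consensus_patterns(lists)
        assert report.tier1 == []
        assert report.tier2 == []  # each pattern appears in one error kind only

    def test_two_kind_patterns_fall_in_tier2(self):
        p = Pattern(6, 30, 1.0)
        lists = {
            "rms_points": [[p]],
            "rms_allpoints": [[p]],
            "angle": [[Pattern(8, 1, 1.0)]],
        }
        report = consensus_patterns(lists)
        assert report.tier1 == []
        assert report.tier2[0][0] == p

    def test_report_serializes(self):
        p = Pattern(6, 16, 2.0)
        report = consensus_patterns({k: [[p]] for k in ("rms_points", "rms_allpoints", "angle")})
        d = report.to_dict()
        assert d["tier1"][0]["pattern"] == [6, 16, 2.0]
        assert d["tier1"][0]["recording_time_s"] == 192.0


class TestDynamicWindows:
    def test_full_window_variation_near_zero_and_ci_collapses(self, small_cohort):
        unit = small_cohort[0]
        gt = build_ground_truth(unit.recording, n_restarts=30, seed=8)
        df = dynamic_window_errors(
            unit.recording, gt.params, [4.0], n_bootstrap=50, seed=9, n_restarts=30
        )
        assert (df["pct_variation_mean"].abs() < 1.0).all()
        np.testing.assert_allclose(df["pct_variation_lo"], df["pct_variation_mean"])
        np.testing.assert_allclose(df["pct_variation_hi"], df["pct_variation_mean"])

    def test_window_outside_recording_rejected(self, small_cohort):
        unit = small_cohort[0]
        with pytest.raises(ValueError):
            dynamic_window_errors(unit.recording, unit.truth, [5.0], seed=0)


class TestSpikeTableRoundTrip:
    def test_recordings_from_table(self, small_cohort):
        unit = small_cohort[1]
        table = unit.recording.to_table()
        back = recordings_from_table(
            table,
            trial_length=4.0,
            n_trials=50,
            contrasts=unit.recording.contrasts,
            directions=unit.recording.directions,
        )
        assert len(back) == 1
        rec = back[0]
        np.testing.assert_array_equal(
            rec.counts(rec.directions[0]), unit.recording.counts(unit.recording.directions[0])
        )

    def test_missing_columns_named(self):
        with pytest.raises(ValueError, match="spike_time_s"):
            recordings_from_table(pd.DataFrame({"unit_id": [1]}), trial_length=4.0)

    def test_feasibility_closure_with_reference_dimensions(self, small_cohort):
        """Every pattern within {<=24, <=50, <=4 s} is accepted on the fixture."""
        unit = small_cohort[0]
        for pat in (Pattern(24, 50, 4.0), Pattern(4, 1, 1.0), Pattern(20, 32, 2.0)):
            score = subsample_pattern_errors(
                unit.recording, unit.truth, pat, 1, n_iterations=1, seed=0, n_restarts=2
            )
            assert score.n_iterations == 1
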