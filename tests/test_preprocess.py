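import numpy as np
import pandas as pd
import pytest

from wmbias import (
    DoGParams,
    SimConfig,
    between_trial_datapoints,
    datapoints_circular_mean,
    exclude_flat_observers,
    expand_to_datapoints,
    flag_first_last_similarity,
    orientation_diff,
    read_trials,
    remove_large_errors,
    simulate_trials,
    write_trials,
)
from wmbias.preprocess import trial_errors

from conftest import make_trials


class TestReadWrite:
    def test_round_trip_is_lossless(self, tmp_path, plain_cohort):
        path = tmp_path / "trials.csv"
        write_trials(plain_cohort, path)
        back, report = read_trials(path)
        assert report.ok and report.n_valid == len(plain_cohort)
        for col in ("ori_1", "ori_2", "ori_3", "ori_4", "response"):
            np.testing.assert_allclose(back[col], plain_cohort[col], atol=1e-9)
        assert back["target_position"].equals(plain_cohort["target_position"].astype(int))
        assert back["observer_id"].equals(plain_cohort["observer_id"])

    def test_invalid_rows_collected_not_dropped_silently(self, tmp_path, plain_cohort):
        df = plain_cohort.copy()
        df.loc[3, "target_position"] = 5
        df.loc[7, "ori_2"] = 200.0
        path = tmp_path / "bad.csv"
        write_trials(df, path)
        trials, report = read_trials(path)
        assert len(trials) == len(df) - 2
        reasons = dict(report.errors)
        assert "target_position" in reasons[3]
        assert "orientation" in reasons[7]

    def test_missing_column_is_schema_error(self, tmp_path, plain_cohort):
        path = tmp_path / "short.csv"
        plain_cohort.drop(columns=["response"]).to_csv(path, index=False)
        with pytest.raises(ValueError, match="missing required columns"):
            read_trials(path)

    def test_unsupported_schema_version(self, tmp_path):
        with pytest.raises(ValueError, match="schema version"):
            read_trials(tmp_path / "x.csv", schema_version="99")


class TestExclusion:
    def test_guessing_observer_excluded_real_observer_retained(self):
        guesser = simulate_trials(
            SimConfig(n_observers=1, trials_per_observer=100, p_guess=1.0, seed=1)
        )
        genuine = simulate_trials(
            SimConfig(n_observers=1, trials_per_observer=100,
                      kappa_by_position=(4.0,) * 4, p_guess=0.1, seed=2)
        ).assign(observer_id="obs_real")
        trials = pd.concat([guesser, genuine], ignore_index=True)
        report = exclude_flat_observers(trials)
        assert report.table.loc["obs001", "status"] == "excluded_flat"
        assert report.table.loc["obs_real", "status"] == "retained"
        assert set(report.retained_ids) == {"obs_real"}

    def test_false_exclusion_rate_low_for_genuine_observers(self):
        """κ=4 observers with 100 trials are almost never excluded."""
        trials = simulate_trials(
            SimConfig(n_observers=100, trials_per_observer=100,
                      kappa_by_position=(4.0,) * 4, p_guess=0.1, seed=3)
        )
        report = exclude_flat_observers(trials)
        rate = (report.table["status"] == "excluded_flat").mean()
        assert rate < 0.05

    def test_few_trials_flagged_insufficient_and_retained(self):
        trials = simulate_trials(
            SimConfig(n_observers=1, trials_per_observer=10, seed=4)
        )
        report = exclude_flat_observers(trials)
        assert report.table.loc["obs001", "status"] == "insufficient"
        assert report.retained_ids == ["obs001"]

    def test_empty_set_gives_empty_report(self):
        trials = simulate_trials(SimConfig(n_observers=1, trials_per_observer=30, seed=5))
        report = exclude_flat_observers(trials.iloc[0:0])
        assert len(report.table) == 0
        assert report.retained_ids == []

    def test_statuses_partition_and_rerun_is_noop(self, plain_cohort):
        report = exclude_flat_observers(plain_cohort)
        assert sorted(report.table.index) == sorted(plain_cohort["observer_id"].unique())
        retained = report.retained(plain_cohort)
        report2 = exclude_flat_observers(retained)
        assert (report2.table["status"] != "excluded_flat").all()
        pd.testing.assert_frame_equal(report2.retained(retained), retained)


class TestFirstLastSimilarity:
    def test_equal_precision_generators_flagged_often(self):
        trials = simulate_trials(
            SimConfig(n_observers=20, trials_per_observer=200,
                      kappa_by_position=(4.0,) * 4, seed=6)
        )
        flags = flag_first_last_similarity(trials, tolerance=5.0)
        assert flags["flagged"].mean() > 0.5

    def test_recency_gradient_rarely_flagged(self):
        trials = simulate_trials(
            SimConfig(n_observers=20, trials_per_observer=200,
                      kappa_by_position=(2.0, 3.0, 3.5, 8.0), seed=7)
        )
        flags = flag_first_last_similarity(trials, tolerance=5.0)
        assert flags["flagged"].mean() < 0.3

    def test_zero_tolerance_flags_only_exact_ties(self, plain_cohort):
        flags = flag_first_last_similarity(plain_cohort, tolerance=0.0)
        assert flags.loc[flags["flagged"], "abs_diff"].eq(0.0).all()

    def test_report_status_update(self, plain_cohort):
        report = exclude_flat_observers(plain_cohort)
        flag_first_last_similarity(plain_cohort, tolerance=50.0, report=report)
        statuses = set(report.table["status"])
        assert statuses <= {"retained", "excluded_flat", "flagged_similarity", "insufficient"}
        assert "flagged_similarity" in statuses  # tolerance 50 flags everyone
        # flagged observers are still retained
        assert set(report.retained_ids) == set(report.table.index[
            report.table["status"] != "excluded_flat"])


class TestRemoveLargeErrors:
    def test_hand_case_threshold_45(self):
        # target 0 deg at position 1; responses chosen to give errors 10, −50, 44, 46
        ori = np.zeros((4, 4))
        ori[:, 1:] = 77.0  # arbitrary distractors
        trials = make_trials(ori, [1, 1, 1, 1], [10.0, 130.0, 44.0, 46.0])
        np.testing.assert_allclose(trial_errors(trials), [10, -50, 44, 46])
        kept = remove_large_errors(trials, 45.0)
        np.testing.assert_allclose(trial_errors(kept), [10, 44])

    def test_threshold_90_is_identity(self, plain_cohort):
        pd.testing.assert_frame_equal(
            remove_large_errors(plain_cohort, 90.0).reset_index(drop=True),
            plain_cohort.reset_index(drop=True),
        )

    def test_idempotent(self, plain_cohort):
        once = remove_large_errors(plain_cohort, 45.0)
        twice = remove_large_errors(once, 45.0)
        pd.testing.assert_frame_equal(once, twice)

    def test_invalid_threshold(self, plain_cohort):
        for bad in (0.0, -5.0, 91.0):
            with pytest.raises(ValueError):
                remove_large_errors(plain_cohort, bad)

    def test_surviving_deltas_unchanged(self, plain_cohort):
        before = expand_to_datapoints(plain_cohort)
        after = expand_to_datapoints(remove_large_errors(plain_cohort, 45.0))
        key = ["observer_id", "trial_index", "distractor_position"]
        merged = after.merge(before, on=key, suffixes=("_a", "_b"))
        assert len(merged) == len(after)
        np.testing.assert_allclose(merged["delta_a"], merged["delta_b"])


class TestExpansion:
    def test_three_points_per_trial(self, plain_cohort):
        pts = expand_to_datapoints(plain_cohort)
        assert len(pts) == 3 * len(plain_cohort)
        counts = pts.groupby(["observer_id", "trial_index"]).size()
        assert (counts == 3).all()

    def test_first_position_target_all_backward(self):
        rng = np.random.default_rng(0)
        trials = make_trials(rng.uniform(0, 180, (6, 4)), [1] * 6, rng.uniform(0, 180, 6))
        pts = expand_to_datapoints(trials)
        assert (pts["direction"] == "backward").all()
        per_trial = pts.groupby("trial_index")["temporal_distance"].apply(sorted)
        assert all(ds == [1, 2, 3] for ds in per_trial)

    def test_direction_and_distance_match_positions_brute_force(self, plain_cohort):
        pts = expand_to_datapoints(plain_cohort.head(200))
        for _, row in pts.iterrows():
            assert row["temporal_distance"] == abs(
                row["distractor_position"] - row["target_position"]
            )
            expected = "forward" if row["distractor_position"] < row["target_position"] else "backward"
            assert row["direction"] == expected

    def test_hand_trial_sign_convention(self, hand_trial):
        """Distractor 170 vs target 10: delta −20 (counter-clockwise)."""
        pts = expand_to_datapoints(hand_trial)
        assert len(pts) == 3
        d1 = pts[pts["distractor_position"] == 1].iloc[0]
        assert d1["delta"] == pytest.approx(-20.0)
        assert d1["error"] == pytest.approx(0.0)
        assert d1["direction"] == "forward"
        d4 = pts[pts["distractor_position"] == 4].iloc[0]
        assert d4["delta"] == pytest.approx(80.0)
        assert d4["temporal_distance"] == 2

    def test_expansion_deltas_match_orientation_diff_oracle(self, plain_cohort):
        sub = plain_cohort.head(50)
        pts = expand_to_datapoints(sub)
        ori = sub[["ori_1", "ori_2", "ori_3", "ori_4"]].to_numpy()
        for _, row in pts.iterrows():
            i = sub.index[(sub["trial_index"] == row["trial_index"])
                          & (sub["observer_id"] == row["observer_id"])][0]
            expected = orientation_diff(
                ori[i, row["distractor_position"] - 1], ori[i, row["target_position"] - 1]
            )
            assert row["delta"] == pytest.approx(expected)


class TestCircularMeanPoints:
    def test_identical_distractors_reduce_to_single_delta(self):
        ori = np.array([[30.0, 100.0, 30.0, 30.0]])
        trials = make_trials(ori, [2], [100.0])
        pts = datapoints_circular_mean(trials)
        assert len(pts) == 1
        assert pts.iloc[0]["delta"] == pytest.approx(orientation_diff(30.0, 100.0))

    def test_one_point_per_trial(self, plain_cohort):
        pts = datapoints_circular_mean(plain_cohort)
        assert len(pts) + pts.attrs["n_degenerate_skipped"] == len(plain_cohort)

    def test_hand_case_mean_of_neighbouring_orientations(self):
        # distractors 10, 20, 30 around target 0: axial mean 20 -> delta 20
        ori = np.array([[0.0, 10.0, 20.0, 30.0]])
        trials = make_trials(ori, [1], [0.0])
        pts = datapoints_circular_mean(trials)
        assert pts.iloc[0]["delta"] == pytest.approx(20.0, abs=1e-6)

    def test_degenerate_mean_skipped_and_counted(self):
        # distractors 0, 60, 120 are balanced on the doubled circle
        ori = np.array([[0.0, 60.0, 120.0, 45.0]])
        trials = make_trials(ori, [4], [45.0])
        pts = datapoints_circular_mean(trials)
        assert len(pts) == 0
        assert pts.attrs["n_degenerate_skipped"] == 1


class TestBetweenTrial:
    def test_single_trial_observer_contributes_nothing(self):
        trials = make_trials(np.full((1, 4), 10.0), [1], [12.0])
        prev_resp, prev_targ = between_trial_datapoints(trials)
        assert len(prev_resp) == 0 and len(prev_targ) == 0

    def test_k_trials_give_k_minus_one_points(self, plain_cohort):
        prev_resp, prev_targ = between_trial_datapoints(plain_cohort)
        n_obs = plain_cohort["observer_id"].nunique()
        assert len(prev_resp) == len(plain_cohort) - n_obs
        assert len(prev_targ) == len(prev_resp)

    def test_observer_boundaries_not_crossed(self):
        a = make_trials(np.full((3, 4), 10.0), [1, 1, 1], [12.0, 14.0, 16.0], "obsA")
        b = make_trials(np.full((2, 4), 90.0), [1, 1], [95.0, 85.0], "obsB")
        prev_resp, _ = between_trial_datapoints(pd.concat([a, b], ignore_index=True))
        assert len(prev_resp) == 3  # 2 from obsA + 1 from obsB
        assert prev_resp.groupby("observer_id").size().to_dict() == {"obsA": 2, "obsB": 1}

    def test_order_sensitivity(self, plain_cohort):
        shuffled = plain_cohort.sample(frac=1.0, random_state=0)
        # same content, but trial_index ordering restores the original pairs
        prev_a, _ = between_trial_datapoints(plain_cohort)
        prev_b, _ = between_trial_datapoints(shuffled)
        pd.testing.assert_frame_equal(prev_a, prev_b)
        # genuinely reindexing trials changes the pairings
        relabelled = plain_cohort.copy()
        rng = np.random.default_rng(1)
        relabelled["trial_index"] = rng.permutation(len(relabelled))
        prev_c, _ = between_trial_datapoints(relabelled)
        assert not np.allclose(
            np.sort(prev_a["delta"].to_numpy()), np.sort(prev_c["delta"].to_numpy())
        )

    def test_prev_target_delta_uses_displayed_orientation(self):
        ori = np.array([[10.0, 50.0, 70.0, 120.0], [30.0, 80.0, 110.0, 160.0]])
        trials = make_trials(ori, [1, 2], [15.0, 85.0])
        prev_resp, prev_targ = between_trial_datapoints(trials)
        # current target is ori_2 of trial 1 = 80; prev response 15; prev target 10
        assert prev_resp.iloc[0]["delta"] == pytest.approx(orientation_diff(15.0, 80.0))
        assert prev_targ.iloc[0]["delta"] == pytest.approx(orientation_diff(10.0, 80.0))
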