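import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rsindex.datamodel import OutcomeRecord
from rsindex.evaluation import (
    auroc,
    bootstrap_ci,
    calibration_report,
    compare_systems,
    label_observations,
    trigger_burden,
)

H = 60  # minutes per hour


def _obs_frame(times_h, admission_id="a1"):
    return pd.DataFrame({"admission_id": admission_id,
                         "obs_time": [int(t * H) for t in times_h]})


class TestLabelling:
    def test_window_labels_match_hand_examples(self):
        obs = _obs_frame([10, 10, 30])
        outcomes = [OutcomeRecord("a1", "death", 20 * H, 20 * H)]
        lab24 = label_observations(obs.iloc[[0]], outcomes, 24.0)
        assert lab24["label"].tolist() == [1]
        outcomes_far = [OutcomeRecord("a1", "death", 40 * H, 40 * H)]
        lab_far = label_observations(obs.iloc[[1]], outcomes_far, 24.0)
        assert lab_far["label"].tolist() == [0]
        lab_post = label_observations(obs.iloc[[2]], outcomes, 24.0)
        assert lab_post["censored"].tolist() == [True]

    def test_event_exactly_at_window_edge_is_positive(self):
        obs = _obs_frame([0])
        outcomes = [OutcomeRecord("a1", "readmission", 24 * H, None)]
        lab = label_observations(obs, outcomes, 24.0)
        assert lab["label"].tolist() == [1]

    def test_endpoint_specific_labelling_censors_other_event(self):
        obs = _obs_frame([1])
        outcomes = [OutcomeRecord("a1", "readmission", 10 * H, None)]
        lab = label_observations(obs, outcomes, 24.0, endpoint="death")
        assert lab["label"].tolist() == [0]
        lab_r = label_observations(obs, outcomes, 24.0,
                                   endpoint="readmission")
        assert lab_r["label"].tolist() == [1]

    def test_partition_into_pos_neg_censored_is_exact(self, small_cohort):
        cohort, _ = small_cohort
        obs = cohort.observations_frame()
        for n in (12.0, 24.0, 72.0):
            lab = label_observations(obs, cohort.outcomes, n)
            pos = int((lab["label"] == 1).sum())
            cens = int(lab["censored"].sum())
            neg = int(((lab["label"] == 0) & ~lab["censored"]).sum())
            assert pos + neg + cens == len(obs)

    def test_positive_sets_nest_across_widening_windows(self, small_cohort):
        cohort, _ = small_cohort
        obs = cohort.observations_frame().reset_index(drop=True)
        previous = None
        for n in (12.0, 24.0, 36.0, 48.0, 72.0):
            lab = label_observations(obs, cohort.outcomes, n)
            current = set(np.flatnonzero(lab["label"].to_numpy()))
            if previous is not None:
                assert previous <= current
            previous = current

    def test_near_discharge_censoring_flag(self):
        obs = _obs_frame([10, 100])
        outcomes = [OutcomeRecord("a1", "none", None, 120 * H)]
        default = label_observations(obs, outcomes, 24.0)
        assert not default["censored"].any()
        flagged = label_observations(obs, outcomes, 24.0,
                                     censor_near_discharge=True)
        assert flagged["censored"].tolist() == [False, True]

    def test_nonpositive_window_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            label_observations(_obs_frame([1]), [], 0.0)


class TestAuroc:
    def test_hand_computed_example(self):
        assert auroc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    def test_perfect_separation_and_all_ties(self):
        assert auroc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0
        assert auroc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            auroc([1, 2], [1, 1])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 20), st.integers(0, 1)),
                    min_size=2, max_size=50))
    def test_equals_pairwise_probability(self, pairs):
        scores = np.array([p[0] for p in pairs], dtype=float)
        labels = np.array([p[1] for p in pairs])
        if labels.min() == labels.max():
            return
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        brute = wins / (len(pos) * len(neg))
        assert auroc(scores, labels) == pytest.approx(brute, abs=1e-12)


class TestBootstrap:
    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"admission_id": np.repeat(range(30), 4),
                           "x": rng.normal(size=120)})
        metric = lambda d: d["x"].mean()
        a = bootstrap_ci(metric, df, b_resamples=200, seed=9)
        b = bootstrap_ci(metric, df, b_resamples=200, seed=9)
        assert a == b

    def test_identical_admissions_give_zero_width(self):
        df = pd.DataFrame({"admission_id": np.repeat(range(10), 2),
                           "x": np.tile([1.0, 3.0], 10)})
        lo, hi = bootstrap_ci(lambda d: d["x"].mean(), df,
                              b_resamples=100, seed=0)
        assert lo == hi == 2.0

    def test_width_shrinks_with_cohort_size(self):
        rng = np.random.default_rng(5)

        def width(n_adm, seed):
            df = pd.DataFrame({"admission_id": np.repeat(range(n_adm), 3),
                               "x": rng.normal(size=3 * n_adm)})
            lo, hi = bootstrap_ci(lambda d: d["x"].mean(), df,
                                  b_resamples=200, seed=seed)
            return hi - lo

        assert width(400, 1) < width(25, 2)

    def test_gaussian_mean_coverage_near_nominal(self):
        """~95% of percentile CIs should cover the true mean."""
        rng = np.random.default_rng(17)
        covered = 0
        outer = 200
        for rep in range(outer):
            df = pd.DataFrame({
                "admission_id": np.arange(100),
                "x": rng.normal(1.0, 1.0, size=100)})
            lo, hi = bootstrap_ci(lambda d: d["x"].mean(), df,
                                  b_resamples=500, seed=rep)
            covered += lo <= 1.0 <= hi
        assert 0.90 <= covered / outer <= 0.99

    def test_mostly_undefined_metric_is_an_error(self):
        df = pd.DataFrame({"admission_id": range(10), "x": range(10)})

        def bad(d):
            raise ValueError("undefined")

        with pytest.raises(ValueError, match="undefined on"):
            bootstrap_ci(bad, df, b_resamples=20, seed=0)


class TestCalibration:
    def test_constant_half_on_balanced_labels_scores_quarter_brier(self):
        y = np.tile([0, 1], 500)
        rep = calibration_report(np.full(1000, 0.5), y)
        assert rep["brier"] == pytest.approx(0.25)

    def test_perfect_predictions_have_tiny_brier(self):
        y = np.tile([0, 1], 50)
        p = np.where(y == 1, 0.999, 0.001)
        rep = calibration_report(p, y)
        assert rep["brier"] < 1e-4

    def test_group_rate_probabilities_give_identity_cox_line(self):
        # probabilities set to the empirical rate of their risk group
        # make alpha=0, beta=1 the exact maximum-likelihood solution
        rng = np.random.default_rng(0)
        true_levels = np.linspace(0.03, 0.6, 10)
        p_parts, y_parts = [], []
        for level in true_levels:
            y_g = (rng.random(1000) < level).astype(int)
            y_parts.append(y_g)
            p_parts.append(np.full(1000, y_g.mean()))
        p, y = np.concatenate(p_parts), np.concatenate(y_parts)
        rep = calibration_report(p, y)
        assert abs(rep["cox_alpha"]) < 0.05
        assert abs(rep["cox_beta"] - 1.0) < 0.05
        assert rep["hosmer_lemeshow_c"] < 1.0

    def test_overconfident_probabilities_flatten_cox_slope(self):
        rng = np.random.default_rng(1)
        n = 8000
        p_true = rng.uniform(0.05, 0.5, size=n)
        y = (rng.random(n) < p_true).astype(int)
        from scipy.special import expit, logit
        p_over = expit(3.0 * logit(p_true))
        rep = calibration_report(p_over, y)
        assert rep["cox_beta"] < 0.7

    def test_zero_event_group_merged_with_warning(self):
        p = np.r_[np.full(50, 1e-7), np.full(50, 0.5)]
        y = np.r_[np.zeros(50, int), (np.arange(50) % 2)]
        with pytest.warns(UserWarning, match="merging"):
            rep = calibration_report(p, y, n_groups=4)
        assert np.isfinite(rep["hosmer_lemeshow_c"])


class TestTriggerBurden:
    def test_hand_computed_six_observation_example(self):
        scores = [0.9, 0.8, 0.6, 0.4, 0.2, 0.1]
        labels = [1, 0, 1, 0, 0, 0]
        curve = trigger_burden(scores, labels, thresholds=[0.0, 0.5, 0.95])
        low, mid, high = curve.itertuples(index=False)
        assert (low.triggers, low.true_positive_triggers) == (6, 2)
        assert low.burden == 3.0
        assert (mid.triggers, mid.true_positive_triggers) == (3, 2)
        assert mid.burden == 1.5
        assert high.triggers == 0 and high.undefined
        assert np.isinf(high.burden)


class TestCompareSystems:
    def test_shape_and_shared_labels_across_systems(self, small_cohort):
        cohort, _ = small_cohort
        obs = cohort.observations_frame()
        rng = np.random.default_rng(0)
        scored = obs[["admission_id", "obs_time"]].copy()
        scored["s1"] = rng.random(len(obs))
        scored["s2"] = rng.random(len(obs))
        table = compare_systems(
            scored, cohort.outcomes, {"A": "s1", "B": "s2"},
            horizons=(24.0, 72.0), endpoints=("compound",),
            with_ci=False)
        assert len(table) == 2 * 2
        for horizon, sub in table.groupby("horizon"):
            assert sub["label_checksum"].nunique() == 1
            assert sub["n_pos"].nunique() == 1
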