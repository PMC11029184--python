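import numpy as np
import pandas as pd
import pytest

from rsindex.datamodel import CohortTables, VITAL_CHANNELS
from rsindex.novelty import (
    VitalSignNoveltyDetector,
    novelty_value,
    rs2_score,
    select_normality_training_set,
    silverman_bandwidths,
)

from conftest import make_obs


def brute_force_novelty(model, probes):
    """Direct double-loop product-Gaussian KDE; the independent oracle."""
    Z = model.normalise(probes)
    h = model.bandwidths_
    d = h.size
    out = []
    for z in Z:
        total = 0.0
        for t in model.train_:
            q = np.sum(((z - t) / h) ** 2)
            total += np.exp(-0.5 * q)
        dens = total / (model.train_.shape[0]
                        * np.prod(h) * (2 * np.pi) ** (d / 2))
        out.append(-np.log(dens))
    return np.array(out)


class TestTrainingSelection:
    def test_only_discharge_day_survivor_sets_selected(self, small_cohort):
        cohort, truth = small_cohort
        training = select_normality_training_set(cohort)
        outcomes = {o.admission_id: o for o in cohort.outcomes}
        day_min = 24 * 60
        for row in training.itertuples(index=False):
            out = outcomes[row.admission_id]
            assert out.event_type == "none"
            assert (row.obs_time // day_min
                    == out.hospital_discharge_time // day_min)

    def test_event_admissions_contribute_nothing(self, small_cohort):
        cohort, truth = small_cohort
        training = select_normality_training_set(cohort)
        event_ids = set(
            truth.admissions.loc[truth.admissions["event_type"] != "none",
                                 "admission_id"])
        assert not (set(training["admission_id"]) & event_ids)

    def test_no_survivors_is_an_error(self, small_cohort):
        cohort, _ = small_cohort
        empty = CohortTables(cohort.admissions, cohort.observations, [])
        with pytest.raises(ValueError, match="larger cohort"):
            select_normality_training_set(empty)


class TestFit:
    def test_too_few_complete_vectors_rejected(self, normal_cloud):
        with pytest.raises(ValueError, match=">=50"):
            VitalSignNoveltyDetector().fit(normal_cloud.iloc[:30])

    def test_incomplete_rows_dropped_from_training(self, normal_cloud):
        X = normal_cloud.copy()
        X.iloc[:100, 0] = np.nan
        model = VitalSignNoveltyDetector().fit(X)
        assert model.train_.shape[0] == len(X) - 100

    def test_zero_variance_channel_rejected(self, normal_cloud):
        X = normal_cloud.copy()
        X["spo2"] = 97.0
        with pytest.raises(ValueError, match="zero-variance"):
            VitalSignNoveltyDetector().fit(X)

    def test_refit_same_data_is_bit_identical(self, normal_cloud):
        a = VitalSignNoveltyDetector(seed=5).fit(normal_cloud)
        b = VitalSignNoveltyDetector(seed=5).fit(normal_cloud)
        assert a.to_json() == b.to_json()

    def test_subsampling_cap_respected(self, normal_cloud):
        big = pd.concat([normal_cloud] * 3, ignore_index=True)
        model = VitalSignNoveltyDetector(max_train=500, seed=0).fit(big)
        assert model.train_.shape[0] == 500

    def test_silverman_bandwidths_positive_and_shrink_with_n(self):
        sds = np.ones(5)
        assert np.all(silverman_bandwidths(sds, 100)
                      > silverman_bandwidths(sds, 10000))
        assert np.all(silverman_bandwidths(sds, 100) > 0)


class TestNoveltyValue:
    def test_matches_double_loop_oracle(self, normal_cloud):
        model = VitalSignNoveltyDetector(seed=0).fit(normal_cloud.iloc[:200])
        rng = np.random.default_rng(7)
        probes = rng.normal(size=(50, 5)) * [9, 11, 2.2, 0.35, 1.3] \
            + [78, 121, 16, 36.9, 96.5]
        fast = model.score_samples(probes)
        slow = brute_force_novelty(model, probes)
        np.testing.assert_allclose(fast, slow, rtol=1e-10)

    def test_density_integrates_to_one(self, normal_cloud):
        """Numerical quadrature of the KDE over a wide box is ~1."""
        model = VitalSignNoveltyDetector(seed=0).fit(normal_cloud.iloc[:200])
        h = model.bandwidths_
        total = 0.0
        grids = [np.linspace(model.train_[:, j].min() - 8 * h[j],
                             model.train_[:, j].max() + 8 * h[j], 400)
                 for j in range(5)]
        # the product kernel factorises, so the 5-D integral of each
        # kernel is the product of 1-D quadratures
        for t in model.train_:
            prod = 1.0
            for j in range(5):
                g = grids[j]
                prod *= np.trapezoid(
                    np.exp(-0.5 * ((g - t[j]) / h[j]) ** 2)
                    / (h[j] * np.sqrt(2 * np.pi)), g)
            total += prod
        assert total / model.train_.shape[0] == pytest.approx(1.0, abs=0.02)

    def test_bulk_scores_below_far_tail(self, normal_cloud):
        model = VitalSignNoveltyDetector(seed=0).fit(normal_cloud)
        centre = model.mean_[None, :].copy()
        far = centre + 3.0 * model.sd_[None, :]
        assert model.score_samples(centre)[0] <= model.score_samples(far)[0]

    def test_duplicating_training_points_leaves_values_unchanged(
            self, normal_cloud):
        # the 1/n normalisation absorbs multiplicity; hold the
        # bandwidth rule fixed so only the normalisation is probed
        fixed = lambda sds, n: 0.4 * sds
        X = normal_cloud.iloc[:100]
        m1 = VitalSignNoveltyDetector(bandwidth_rule=fixed, seed=0).fit(X)
        m2 = VitalSignNoveltyDetector(bandwidth_rule=fixed, seed=0).fit(
            pd.concat([X, X], ignore_index=True))
        probes = normal_cloud.iloc[100:140]
        np.testing.assert_allclose(m1.score_samples(probes),
                                   m2.score_samples(probes), rtol=1e-12)

    def test_channel_order_does_not_matter(self, normal_cloud):
        model = VitalSignNoveltyDetector(seed=0).fit(normal_cloud)
        probes = normal_cloud.iloc[:20]
        shuffled = probes[list(reversed(VITAL_CHANNELS))]
        np.testing.assert_allclose(model.score_samples(probes),
                                   model.score_samples(shuffled))

    def test_marginalised_value_is_marginal_density(self, normal_cloud):
        model = VitalSignNoveltyDetector(seed=0).fit(normal_cloud.iloc[:150])
        probe = np.array([[80.0, 120.0, np.nan, 37.0, 96.0]])
        got = model.score_samples(probe)[0]
        # oracle: rebuild a 4-channel model over the observed dimensions
        z = model.normalise(np.nan_to_num(probe, nan=0.0))[0]
        dims = [0, 1, 3, 4]
        h = model.bandwidths_[dims]
        total = sum(np.exp(-0.5 * np.sum(
            ((z[dims] - t[dims]) / h) ** 2)) for t in model.train_)
        dens = total / (model.train_.shape[0] * np.prod(h)
                        * (2 * np.pi) ** 2)
        assert got == pytest.approx(-np.log(dens), rel=1e-10)

    def test_all_missing_rejected(self, normal_cloud):
        model = VitalSignNoveltyDetector(seed=0).fit(normal_cloud)
        with pytest.raises(ValueError, match="all vital channels missing"):
            model.score_samples(np.full((1, 5), np.nan))

    def test_strict_policy_rejects_missing(self, normal_cloud):
        model = VitalSignNoveltyDetector(
            seed=0, missing_policy="strict").fit(normal_cloud)
        with pytest.raises(ValueError, match="strict"):
            model.score_samples(np.array([[80, 120, np.nan, 37, 96.0]]))


class TestCalibratedScore:
    def test_rs2_monotone_in_novelty(self, normal_cloud):
        model = VitalSignNoveltyDetector(seed=0).fit(normal_cloud)
        rng = np.random.default_rng(3)
        probes = rng.normal(size=(200, 5)) * [20, 25, 6, 1.0, 3.0] \
            + [85, 115, 18, 37, 95]
        probes[:, 4] = np.clip(probes[:, 4], 50, 100)
        nov = model.score_samples(probes)
        rs2 = model.rs2_from_novelty(nov)
        order = np.argsort(nov)
        assert np.all(np.diff(rs2[order]) >= 0)
        assert np.all((rs2 >= 0) & (rs2 <= 1))

    def test_typical_observation_scores_near_zero(self, normal_cloud):
        model = VitalSignNoveltyDetector(seed=0).fit(normal_cloud)
        most_typical = model.train_[
            np.argmin(model.score_samples(
                model.train_ * model.sd_ + model.mean_))]
        raw = most_typical * model.sd_ + model.mean_
        assert model.transform(raw[None, :])[0] <= 0.01

    def test_gross_outlier_scores_above_099(self, normal_cloud):
        model = VitalSignNoveltyDetector(seed=0).fit(normal_cloud)
        assert rs2_score(model, make_obs(
            heart_rate=170, resp_rate=38, systolic_bp=75,
            temperature=36.9, spo2=96)) > 0.99

    def test_median_training_point_scores_near_half(self, normal_cloud):
        model = VitalSignNoveltyDetector(seed=0).fit(normal_cloud)
        nov = model.score_samples(
            model.train_ * model.sd_ + model.mean_)
        median_idx = np.argsort(nov)[len(nov) // 2]
        raw = model.train_[median_idx] * model.sd_ + model.mean_
        assert model.transform(raw[None, :])[0] == pytest.approx(0.5,
                                                                 abs=0.02)

    def test_json_round_trip(self, normal_cloud):
        model = VitalSignNoveltyDetector(seed=0).fit(normal_cloud.iloc[:80])
        back = VitalSignNoveltyDetector.from_json(model.to_json())
        probes = normal_cloud.iloc[80:100]
        np.testing.assert_allclose(model.transform(probes),
                                   back.transform(probes))

    def test_functional_wrappers_agree_with_methods(self, normal_cloud):
        model = VitalSignNoveltyDetector(seed=0).fit(normal_cloud)
        obs = make_obs()
        assert novelty_value(model, obs) == pytest.approx(
            model.score_samples(np.array([[70, 120, 16, 37, 98.0]]))[0])
        assert 0.0 <= rs2_score(model, obs) <= 1.0
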