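import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ibp.outcome import (
    OutcomeLogit,
    auc_comparison_test,
    calibration_and_rank,
    fit_logistic,
    loo_predict,
    roc_auc,
    sens_spec_products,
)
from ibp.synthetic import CohortSpec, simulate_cohort


@pytest.fixture(scope="module")
def cohort_data():
    c = simulate_cohort(CohortSpec(n_patients=135, seed=21))
    data = c.design.copy()
    data["success"] = c.clinical["success"].to_numpy()
    data["ilae_class"] = c.clinical["ilae_class"].to_numpy()
    return c, data


class TestFit:
    def test_or_equals_exp_beta_to_machine_precision(self, cohort_data):
        _, data = cohort_data
        res = OutcomeLogit.from_dataframe(data, covariates=list(data.columns[:10])).fit()
        np.testing.assert_array_equal(
            res.odds_ratios()["OR"].to_numpy(), np.exp(res.params.to_numpy())
        )

    def test_recovers_known_coefficients_on_large_sample(self):
        rng = np.random.default_rng(0)
        n = 4000
        x = rng.standard_normal(n)
        lin = 1.0 * x - 0.5
        y = (rng.random(n) < 1 / (1 + np.exp(-lin))).astype(int)
        res = fit_logistic(pd.DataFrame({"x": x}), y)
        assert res.params["x"] == pytest.approx(1.0, abs=0.15)
        assert res.params["const"] == pytest.approx(-0.5, abs=0.15)

    def test_perfect_separation_is_flagged_not_fatal(self):
        x = np.array([0, 1, 2, 3, 10, 11, 12, 13], dtype=float)
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        res = fit_logistic(pd.DataFrame({"x": x}), y)
        assert res.separation
        ci = res.conf_int()
        assert np.isinf(ci.to_numpy()).any()  # unbounded where separated

    def test_one_class_outcome_rejected(self):
        with pytest.raises(ValueError):
            OutcomeLogit(np.ones(10, dtype=int), pd.DataFrame({"x": np.arange(10.0)}))

    def test_pseudo_r2_ordering(self, cohort_data):
        _, data = cohort_data
        res = OutcomeLogit.from_dataframe(data, covariates=list(data.columns[:10])).fit()
        assert 0 < res.r2_cox_snell < res.r2_nagelkerke < 1


class TestROC:
    def test_perfect_separation_auc_one(self):
        _, auc = roc_auc(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0]))
        assert auc == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(1)
        scores = rng.random(1000)
        labels = rng.integers(0, 2, 1000)
        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(0.5, abs=0.05)

    @pytest.mark.parametrize("seed", range(5))
    def test_auc_equals_mann_whitney_u_exactly(self, seed):
        rng = np.random.default_rng(seed)
        n = 80
        scores = np.round(rng.random(n), 2)  # ties included on purpose
        labels = rng.integers(0, 2, n)
        if labels.sum() in (0, n):
            labels[0] = 1 - labels[0]
        _, auc = roc_auc(scores, labels)
        u = stats.mannwhitneyu(scores[labels == 1], scores[labels == 0]).statistic
        assert auc == pytest.approx(u / (labels.sum() * (n - labels.sum())), abs=1e-12)

    def test_one_class_labels_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([0.1, 0.9]), np.array([1, 1]))


class TestComparisonTest:
    def test_identical_curves_give_null_result(self):
        rng = np.random.default_rng(2)
        scores = rng.random(50)
        labels = rng.integers(0, 2, 50)
        t, p = auc_comparison_test(scores, labels, scores)
        assert (t, p) == (0.0, 1.0)

    def test_products_grid_has_n_minus_one_points(self):
        scores = np.linspace(0, 1, 135)
        labels = (scores > 0.5).astype(int)
        assert sens_spec_products(scores, labels).size == 134

    def test_perfect_model_beats_chance(self):
        scores = np.linspace(0, 1, 135)
        labels = (scores > 0.3).astype(int)
        _, p = auc_comparison_test(scores, labels)
        assert p < 0.001

    def test_bonferroni_multiplies_and_caps(self):
        rng = np.random.default_rng(3)
        scores = rng.random(60)
        labels = rng.integers(0, 2, 60)
        _, p1 = auc_comparison_test(scores, labels)
        _, p5 = auc_comparison_test(scores, labels, bonferroni=5)
        assert p5 == min(1.0, 5 * p1)


class TestLOO:
    def test_deterministic_and_out_of_sample(self, cohort_data):
        _, data = cohort_data
        X = data[list(data.columns[:10])]
        y = data["success"].to_numpy()
        p1, auc1 = loo_predict(X, y)
        p2, auc2 = loo_predict(X, y)
        np.testing.assert_array_equal(p1, p2)
        assert p1.shape == (135,)
        assert not np.isnan(p1).any()
        assert 0 <= auc1 <= 1

    def test_small_cohort_rejected(self):
        with pytest.raises(ValueError):
            loo_predict(pd.DataFrame({"x": np.arange(5.0)}), np.array([0, 1, 0, 1, 0]))

    def test_one_class_fold_yields_na(self):
        # a single positive: its own fold trains on one class only
        rng = np.random.default_rng(4)
        X = pd.DataFrame({"x": rng.standard_normal(20)})
        y = np.zeros(20, dtype=int)
        y[3] = 1
        probs, _ = loo_predict(X, y)
        assert np.isnan(probs[3])
        assert np.isfinite(probs[np.arange(20) != 3]).all()


class TestCalibration:
    def test_confident_correct_predictions_fill_top_bin(self):
        rep = calibration_and_rank(np.full(30, 0.99), np.ones(30, dtype=int))
        assert rep.bins.iloc[-1]["observed_success"] == 1.0
        assert rep.high_confidence == (30, 30)

    def test_anticalibrated_fixture_has_decreasing_bins(self):
        rng = np.random.default_rng(5)
        truth = rng.integers(0, 2, 2000)
        probs = np.clip(1.0 - truth + rng.normal(0, 0.1, 2000), 0, 1)
        rep = calibration_and_rank(probs, np.where(truth == 1, 1, 3))
        freq = rep.bins["observed_success"].dropna().to_numpy()
        assert (np.diff(freq) <= 0).all()

    def test_spearman_sign_is_negative_for_concordant_model(self):
        # better (lower) ILAE class goes with higher predicted probability
        probs = np.array([0.9, 0.8, 0.6, 0.4, 0.2, 0.1])
        ilae = np.array([1, 1, 2, 3, 4, 5])
        rep = calibration_and_rank(probs, ilae)
        assert rep.spearman_rho < -0.9

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            calibration_and_rank(np.array([0.5, 1.2]), np.array([1, 2]))
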