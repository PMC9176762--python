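import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gcsrasch.outcomes import (
    PredictionResult,
    brier,
    build_features,
    fit_logistic,
    fit_predict_forest,
    fit_predict_logistic,
    make_cv_folds,
    risk_difference_analysis,
    wilcoxon_signed_rank,
)
from gcsrasch.registry import RecordSet


def pred_result(p, y, model="m", features="f"):
    frame = pd.DataFrame({"id": np.arange(len(p)), "fold": 0, "p_hat": p, "y": y})
    return PredictionResult(frame=frame, model=model, features=features)


class TestFolds:
    def test_even_split(self):
        assert np.bincount(make_cv_folds(10, 5, 0)).tolist() == [2] * 5

    def test_near_even_split(self):
        assert sorted(np.bincount(make_cv_folds(11, 5, 0)).tolist()) == [2, 2, 2, 2, 3]

    def test_deterministic_and_guarded(self):
        assert np.array_equal(make_cv_folds(20, 4, 7), make_cv_folds(20, 4, 7))
        with pytest.raises(ValueError):
            make_cv_folds(3, 5, 0)


class TestLogistic:
    def test_contingency_table_closed_form(self):
        x = np.r_[np.ones(100), np.zeros(100)][:, None]
        y = np.r_[np.ones(20), np.zeros(80), np.ones(5), np.zeros(95)]
        coefs, _, fallback = fit_logistic(x, y)
        assert not fallback
        assert np.exp(coefs[0]) == pytest.approx((20 * 95) / (80 * 5), rel=1e-4)

    def test_constant_outcome_predicts_near_zero(self):
        x = np.random.default_rng(0).normal(size=(50, 2))
        pred = fit_predict_logistic(x, np.zeros(50, dtype=int))
        assert (pred.frame["p_hat"] <= 1e-3).all()

    def test_coefficient_recovery(self):
        rng = np.random.default_rng(4)
        n = 50000
        X = rng.normal(size=(n, 2))
        beta = np.array([0.8, -0.5])
        p = 1 / (1 + np.exp(-(X @ beta - 1.0)))
        y = (rng.uniform(size=n) < p).astype(int)
        coefs, intercept, fallback = fit_logistic(X, y)
        assert not fallback
        # asymptotic SE is ~0.012 here; 3 SE tolerance
        assert np.abs(coefs - beta).max() < 0.04
        assert intercept == pytest.approx(-1.0, abs=0.04)

    def test_out_of_fold_coverage(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 2))
        y = rng.integers(0, 2, 200)
        folds = make_cv_folds(200, 5, 3)
        pred = fit_predict_logistic(X, y, folds)
        assert len(pred.frame) == 200
        assert not pred.frame["id"].duplicated().any()
        assert set(pred.frame["fold"]) == set(range(5))


class TestForest:
    def test_pure_noise_no_better_than_base_rate(self):
        rng = np.random.default_rng(2)
        n = 600
        X = rng.normal(size=(n, 3))
        y = (rng.uniform(size=n) < 0.3).astype(int)
        folds = make_cv_folds(n, 5, 1)
        pred = fit_predict_forest(X, y, folds, tree_grid=(50,), seed=9)
        base = y.mean() * (1 - y.mean())
        assert brier(pred).brier >= base - 0.005

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(120, 2))
        y = (X[:, 0] + rng.normal(size=120) > 0).astype(int)
        folds = make_cv_folds(120, 3, 0)
        a = fit_predict_forest(X, y, folds, tree_grid=(20, 40), seed=5)
        b = fit_predict_forest(X, y, folds, tree_grid=(20, 40), seed=5)
        pd.testing.assert_frame_equal(a.frame, b.frame)


class TestBrier:
    def test_perfect_and_constant(self):
        assert brier(pred_result([1.0, 0.0], [1, 0])).brier == 0.0
        assert brier(pred_result([0.5] * 4, [1, 0, 1, 0])).brier == 0.25

    def test_arithmetic_example(self):
        s = brier(pred_result([0.8, 0.3], [1, 0]))
        assert s.brier == pytest.approx(0.065)

    def test_base_rate_closed_form(self):
        rng = np.random.default_rng(0)
        y = (rng.uniform(size=5000) < 0.27).astype(int)
        s = brier(pred_result(np.full(5000, y.mean()), y))
        assert s.brier == pytest.approx(y.mean() * (1 - y.mean()), rel=1e-12)

    def test_logloss_clipping(self):
        s = brier(pred_result([1.0, 0.0], [0, 1]))
        assert np.isfinite(s.logloss)


class TestWilcoxon:
    def test_exact_all_positive_n5(self):
        assert wilcoxon_signed_rank([1.0, 2.0, 3.0, 4.0, 5.0]) == pytest.approx(2 / 32)

    def test_antisymmetric_p_one(self):
        with pytest.warns(UserWarning, match="fewer than 5"):
            assert wilcoxon_signed_rank([-2.0, -1.0, 1.0, 2.0]) == pytest.approx(1.0)

    def test_all_zero_warns_p_one(self):
        with pytest.warns(UserWarning):
            assert wilcoxon_signed_rank([0.0, 0.0]) == 1.0

    @pytest.mark.parametrize("n", [6, 8, 10])
    def test_matches_brute_force_enumeration(self, n):
        rng = np.random.default_rng(n)
        d = rng.normal(size=n)
        ranks = stats.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        # enumerate all 2^n sign patterns of the null distribution
        stats_null = [
            ranks[np.array(signs, dtype=bool)].sum()
            for signs in itertools.product([0, 1], repeat=n)
        ]
        stats_null = np.array(stats_null)
        mean = ranks.sum() / 2
        p_exact = np.mean(np.abs(stats_null - mean) >= abs(w_obs - mean) - 1e-12)
        assert wilcoxon_signed_rank(d) == pytest.approx(p_exact, rel=1e-10)


class TestRiskDifference:
    def test_identical_predictions_zero_counts(self):
        a = pred_result([0.1, 0.2, 0.3], [0, 0, 1])
        out = risk_difference_analysis(a, a)
        assert all(v["count"] == 0 for v in out["thresholds"].values())

    def test_uniform_shift(self):
        a = pred_result(np.full(10, 0.2), np.zeros(10, dtype=int))
        b = pred_result(np.full(10, 0.23), np.zeros(10, dtype=int))
        out = risk_difference_analysis(a, b)
        assert out["thresholds"][0.025]["count"] == 10
        assert out["thresholds"][0.05]["count"] == 0
        assert out["mean_delta"] == pytest.approx(0.03)

    def test_percentages_hand_computed(self):
        delta = np.array([0.0, 0.03, -0.06, 0.12, 0.0, 0.01, -0.03, 0.2, 0.0, 0.04])
        a = pred_result(np.full(10, 0.3), np.zeros(10, dtype=int))
        b = pred_result(0.3 + delta, np.zeros(10, dtype=int))
        out = risk_difference_analysis(a, b)
        assert out["thresholds"][0.025]["count"] == 6
        assert out["thresholds"][0.025]["percent"] == pytest.approx(60.0)
        assert out["thresholds"][0.05]["count"] == 3
        assert out["thresholds"][0.10]["count"] == 2

    def test_case_set_mismatch(self):
        a = pred_result([0.1], [0])
        b = pred_result([0.1, 0.2], [0, 1])
        with pytest.raises(ValueError, match="case sets"):
            risk_difference_analysis(a, b)


class TestBuildFeatures:
    def test_indicators_and_total(self):
        df = pd.DataFrame(
            {
                "id": ["a", "b"],
                "age": [40.0, 50.0],
                "sex": ["male", "female"],
                "iss": pd.array([9, 17], dtype="int64"),
                "region": ["Head", "Chest"],
                "eye": pd.array([4, 1], dtype="Int64"),
                "verbal": pd.array([5, 1], dtype="Int64"),
                "motor": pd.array([6, 1], dtype="Int64"),
                "outcome": ["alive", "dead"],
            }
        )
        X, y, ids = build_features(RecordSet(df), ancillary=True)
        assert y.tolist() == [0, 1]
        assert X.loc[0, "eye_3"] == 1 and X.loc[1, "eye_3"] == 0
        assert X.loc[0, "total"] == 12 and X.loc[1, "total"] == 0
        assert X.loc[0, "male"] == 1 and X.loc[0, "region_Head"] == 1

    def test_missing_outcome_rejected(self):
        df = pd.DataFrame(
            {
                "id": ["a"], "age": [40.0], "sex": ["male"],
                "iss": pd.array([9], dtype="int64"), "region": ["Head"],
                "eye": pd.array([4], dtype="Int64"), "verbal": pd.array([5], dtype="Int64"),
                "motor": pd.array([6], dtype="Int64"), "outcome": ["missing"],
            }
        )
        with pytest.raises(ValueError, match="missing outcomes"):
            build_features(RecordSet(df))
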