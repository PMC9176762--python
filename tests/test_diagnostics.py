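import numpy as np
import pytest
from scipy import stats

from gcsrasch.diagnostics import (
    category_probability_curves,
    compute_fit_report,
    cronbach_alpha,
    item_fit_residual,
    item_trait_chi_square,
    never_modal_categories,
    person_fit_residual,
    psi,
    run_sample_design,
    standardized_residuals,
    threshold_order_report,
)
from gcsrasch.pcm import (
    PcmItemParams,
    PersonEstimate,
    ResponseMatrix,
    fit_items_cml,
    estimate_persons,
)
from gcsrasch.synthetic import PcmSimConfig, simulate_pcm


def person(theta, raw, extreme=False):
    return PersonEstimate(theta=theta, se=1.0, raw_score=raw, extreme=extreme)


class TestStandardizedResiduals:
    def test_dichotomous_bernoulli_arithmetic(self):
        params = PcmItemParams(thresholds=(np.array([0.0]), np.array([0.0])))
        m = ResponseMatrix(np.array([[1, 0]]), (1, 1))
        z = standardized_residuals(m, params, [person(0.0, 1)])
        assert z[0, 0] == pytest.approx(1.0)
        assert z[0, 1] == pytest.approx(-1.0)

    def test_simulation_oracle_mean_zero_var_one(self, gcs_like_thresholds):
        # known locations, known parameters: exact standardization
        cfg = PcmSimConfig(item_thresholds=gcs_like_thresholds, person_sd=1.5,
                           n_persons=20000, seed=42)
        m = simulate_pcm(cfg)
        theta = np.random.default_rng(42).normal(0, 1.5, 20000)
        params = PcmItemParams(thresholds=gcs_like_thresholds)
        persons = [person(t, int(r)) for t, r in zip(theta, m.totals)]
        z = standardized_residuals(m, params, persons)
        assert z.mean() == pytest.approx(0.0, abs=0.02)
        assert z.var() == pytest.approx(1.0, abs=0.03)


class TestFitResiduals:
    def test_chi_square_mean_maps_near_zero(self):
        assert abs(item_fit_residual(np.ones(1000), 1000)) < 0.1

    def test_underdispersion_is_negative(self):
        z = np.full(500, 0.3)
        assert item_fit_residual(z, 500) < -5

    def test_wilson_hilferty_normality(self):
        # distributional oracle: chi-square(100) draws -> approx standard normal
        rng = np.random.default_rng(0)
        y = rng.chisquare(100, size=2000)
        vals = [item_fit_residual(np.sqrt(np.full(100, yi / 100)), 100) for yi in y]
        assert stats.kstest(vals, "norm").pvalue > 0.01

    def test_person_variant_same_transform(self):
        z = np.array([0.5, -1.2, 0.8])
        assert person_fit_residual(z, 3) == item_fit_residual(z, 3)

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            item_fit_residual(np.array([1.0]), 1)


class TestItemTraitChiSquare:
    def test_df_for_six_intervals_three_items(self, gcs_like_thresholds):
        cfg = PcmSimConfig(item_thresholds=gcs_like_thresholds, n_persons=600, seed=0)
        m = simulate_pcm(cfg).drop_extremes()
        params = fit_items_cml(m)
        persons = [p for p in estimate_persons(m, params)]
        _, df, p = item_trait_chi_square(m, persons, params, 6)
        assert df == 15
        assert 0 <= p <= 1

    def test_perfect_fit_gives_zero(self):
        # two persons whose responses equal their expected scores exactly
        params = PcmItemParams(thresholds=(np.array([0.0]), np.array([0.0]), np.array([0.0])))
        m = ResponseMatrix(np.array([[1, 0, 1], [0, 1, 0]] * 6), (1, 1, 1))
        # at theta 0 expected score is 0.5 per item; per-interval sums of
        # observed equal sums of expected by construction
        persons = [person(0.0, int(r)) for r in m.totals]
        chi2, df, p = item_trait_chi_square(m, persons, params, 2)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_more_intervals_than_persons(self, gcs_like_thresholds):
        params = PcmItemParams(thresholds=gcs_like_thresholds)
        m = ResponseMatrix(np.array([[1, 1, 1], [0, 1, 2]]), (2, 3, 3))
        persons = [person(0.0, 3), person(0.1, 3)]
        with pytest.raises(ValueError):
            item_trait_chi_square(m, persons, params, 6)


class TestReliability:
    def test_psi_trivial_cases(self):
        # all SE = 0 -> 1; mean SE^2 = Var -> 0; formula arithmetic -> -1
        thetas = [-1.0, 0.0, 1.0]
        assert psi([PersonEstimate(t, 1e-12, 0, False) for t in thetas]) == pytest.approx(1.0)
        var = np.var(thetas, ddof=1)
        assert psi([PersonEstimate(t, np.sqrt(var), 0, False) for t in thetas]) == pytest.approx(0.0, abs=1e-12)
        se = np.sqrt(2 * var)
        assert psi([PersonEstimate(t, se, 0, False) for t in thetas]) == pytest.approx(-1.0)

    def test_psi_extreme_flag_filters(self):
        ps = [PersonEstimate(0.0, 0.1, 0, True), PersonEstimate(1.0, 0.1, 5, False),
              PersonEstimate(-1.0, 0.1, 3, False)]
        assert psi(ps, include_extremes=False) != psi(ps, include_extremes=True)

    def test_alpha_identical_items(self):
        col = np.array([0, 1, 2, 1, 0, 2])
        m = ResponseMatrix(np.column_stack([col, col, col]), (2, 2, 2))
        assert cronbach_alpha(m) == pytest.approx(1.0)

    def test_alpha_zero_covariance_toy(self):
        m = ResponseMatrix(np.array([[0, 1], [1, 1], [0, 0], [1, 0]]), (1, 1))
        assert cronbach_alpha(m) == pytest.approx(0.0, abs=1e-12)

    def test_alpha_independent_items_near_zero(self):
        rng = np.random.default_rng(1)
        m = ResponseMatrix(rng.integers(0, 3, size=(20000, 3)), (2, 2, 2))
        assert cronbach_alpha(m) == pytest.approx(0.0, abs=0.03)


class TestThresholdOrder:
    def test_ordered_and_disordered_flags(self):
        params = PcmItemParams(thresholds=(np.array([-1.0, 0.0, 1.0]), np.array([0.5, -0.5])))
        r = threshold_order_report(params)
        assert r.disordered[0] == (False, False)
        assert r.disordered[1] == (True,)
        assert r.any_disordered

    def test_detection_power_on_designed_disorder(self):
        # never-modal middle category: thresholds (1, -1)
        truth = (np.array([1.0, -1.0]), np.array([-1.5, 0.0, 1.5]), np.array([-0.8, 0.15, 0.85]))
        hits = 0
        for rep in range(40):
            m = simulate_pcm(PcmSimConfig(item_thresholds=truth, n_persons=2000, seed=5000 + rep))
            r = threshold_order_report(fit_items_cml(m))
            hits += any(r.disordered[0])
        assert hits >= 38  # >= 95% power


class TestCurves:
    def test_dichotomous_curves_cross_at_threshold(self):
        params = PcmItemParams(thresholds=(np.array([0.4]),))
        curves = category_probability_curves(params, [0.4])
        p = curves.pivot_table(index="category", values="probability")
        assert p.loc[0, "probability"] == pytest.approx(p.loc[1, "probability"])

    def test_ordered_thresholds_every_category_modal(self):
        params = PcmItemParams(thresholds=(np.array([-1.0, 0.0, 1.0]),))
        assert never_modal_categories(params, np.linspace(-6, 6, 500)) == [[]]

    def test_disordered_toy_middle_never_modal(self):
        params = PcmItemParams(thresholds=(np.array([1.0, -1.0]),))
        assert never_modal_categories(params, np.linspace(-6, 6, 500)) == [[1]]


class TestSampleDesign:
    def test_counts_and_structure_on_fixture(self, cohort_matrix):
        reports = run_sample_design(cohort_matrix, seed=3)
        assert reports["sample1"].n_valid == 48417
        assert reports["sample1"].n_extreme == 0
        assert reports["sample2"].n_valid + reports["sample2"].n_extreme == 500
        n3 = reports["sample3"].n_valid + reports["sample3"].n_extreme
        assert n3 == cohort_matrix.n_persons // 10
        # sample 4 targets approx. 500 valid cases
        assert abs(reports["sample4"].n_valid - 500) < 60

    def test_deterministic_given_seed(self, cohort_matrix):
        a = run_sample_design(cohort_matrix, seed=5)
        b = run_sample_design(cohort_matrix, seed=5)
        assert a["sample2"] == b["sample2"]

    def test_extreme_signature_on_fixture(self, cohort_matrix):
        # extreme-dominated samples depress PSI and inflate alpha
        rep = compute_fit_report(cohort_matrix, label="full")
        assert rep.psi_with_extremes < rep.psi_no_extremes
        assert rep.alpha_with_extremes > rep.alpha_no_extremes
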