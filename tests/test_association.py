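"""Logistic screening, RCAL/SIMEX corrections, BH and group assignment."""

import numpy as np
import pandas as pd
import pytest

from peptivar.association import (
    AssociationError,
    ConvergenceWarning,
    MeasurementErrorLogit,
    _quadratic_extrapolate,
    assign_groups,
    bh_adjust,
    fit_logistic,
    multivariate_fit,
    rcal,
    simex,
    univariate_screen,
)
from peptivar.feature_table import FeatureTable
from peptivar.synthetic_data import CaseControlDesign, generate_case_control_study


def two_by_two(a, b, c, d):
    """x=1 exposed: a cases / b controls; x=0: c cases / d controls."""
    x = np.r_[np.ones(a + b), np.zeros(c + d)]
    y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
    return x, y


class TestFitLogistic:
    def test_no_association_beta_zero(self):
        x, y = two_by_two(10, 10, 10, 10)
        assert fit_logistic(x, y).beta == pytest.approx(0.0, abs=1e-8)

    def test_contingency_closed_form_odds_ratio(self):
        x, y = two_by_two(20, 10, 10, 20)
        fit = fit_logistic(x, y)
        assert fit.beta == pytest.approx(np.log(4.0), abs=1e-6)
        # closed-form Wald SE of a log odds ratio: sqrt(sum of 1/cell)
        assert fit.beta_se == pytest.approx(
            np.sqrt(1 / 20 + 1 / 10 + 1 / 10 + 1 / 20), abs=1e-6)

    def test_perfect_separation_flagged(self):
        x = np.r_[np.full(10, -1.0), np.full(10, 1.0)]
        y = np.r_[np.zeros(10), np.ones(10)]
        with pytest.warns(ConvergenceWarning):
            fit = fit_logistic(x, y)
        assert fit.separated

    def test_matches_statsmodels_oracle(self, rng):
        import statsmodels.api as sm

        x = rng.standard_normal((200, 2))
        y = (rng.random(200) < 1 / (1 + np.exp(-(0.5 + x @ [1.0, -0.7])))).astype(float)
        ours = fit_logistic(x, y)
        ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        np.testing.assert_allclose(ours.params, ref.params, rtol=1e-6)
        np.testing.assert_allclose(ours.se, ref.bse, rtol=1e-5)
        np.testing.assert_allclose(ours.wald_p, ref.pvalues, rtol=1e-4, atol=1e-12)

    def test_constant_predictor_rejected(self):
        with pytest.raises(AssociationError, match="constant"):
            fit_logistic(np.ones(10), np.r_[np.ones(5), np.zeros(5)])

    def test_one_class_rejected(self):
        with pytest.raises(AssociationError, match="classes"):
            fit_logistic(np.arange(6.0), np.ones(6))


class TestRcal:
    def test_worked_example_urine_feature(self):
        """beta 0.435 / ICC 0.459 -> 0.948 (prints as 0.947 from rounded inputs)."""
        fit = fit_logistic(*two_by_two(20, 10, 10, 20))
        fit.params[1] = 0.435  # set the slope to the published value
        corrected = rcal(fit, 0.459)
        assert corrected.beta_star == pytest.approx(0.435 / 0.459, abs=1e-12)
        assert corrected.beta_star == pytest.approx(0.948, abs=5e-4)
        assert corrected.or_star == pytest.approx(np.exp(corrected.beta_star))

    def test_worked_example_serum_feature(self):
        fit = fit_logistic(*two_by_two(20, 10, 10, 20))
        fit.params[1] = -1.66
        assert rcal(fit, 0.616).beta_star == pytest.approx(-2.69, abs=5e-3)

    def test_icc_one_is_identity(self):
        fit = fit_logistic(*two_by_two(20, 10, 10, 20))
        corrected = rcal(fit, 1.0)
        assert corrected.beta_star == pytest.approx(fit.beta)
        assert corrected.ci_star == pytest.approx(fit.conf_int())

    def test_correction_never_shrinks(self):
        fit = fit_logistic(*two_by_two(20, 10, 10, 20))
        for icc in (0.2, 0.5, 0.9):
            assert abs(rcal(fit, icc).beta_star) >= abs(fit.beta)

    def test_invalid_icc_rejected(self):
        fit = fit_logistic(*two_by_two(20, 10, 10, 20))
        for icc in (0.0, -0.3, 1.5):
            with pytest.raises(AssociationError):
                rcal(fit, icc)

    def test_rosner_interval_reproduces_published_ci(self):
        """Naive Wald CI from beta=0.435, p=0.012, divided by ICC 0.459."""
        from scipy import stats

        beta, p, icc = 0.435, 0.012, 0.459
        se = beta / stats.norm.ppf(1 - p / 2)
        fit = fit_logistic(*two_by_two(20, 10, 10, 20))
        fit.params[1], fit.se[1] = beta, se
        lo, hi = rcal(fit, icc).ci_star
        assert lo == pytest.approx(0.21, abs=5e-3)
        assert hi == pytest.approx(1.69, abs=5e-3)


class TestSimex:
    def test_zero_error_variance_returns_naive(self):
        x, y = two_by_two(20, 10, 10, 20)
        fit = fit_logistic(x, y)
        corrected = simex(x, y, 0.0)
        assert corrected.beta_star == pytest.approx(fit.beta)

    def test_quadratic_identity_extrapolation(self):
        # means lying exactly on q(lambda) = 1 + lambda + lambda^2 -> q(-1) = 1
        lams = [0.0, 0.5, 1.0, 1.5, 2.0]
        vals = [1 + l + l**2 for l in lams]
        assert _quadratic_extrapolate(lams, vals) == pytest.approx(1.0, abs=1e-10)

    def test_too_few_lambda_points(self):
        with pytest.raises(AssociationError):
            _quadratic_extrapolate([0.0, 1.0], [1.0, 2.0])

    def test_corrects_toward_truth_on_attenuated_data(self, rng):
        beta_true, sigma_w2 = 1.0, 2.0 / 3.0  # ICC = 0.6
        n = 2000
        x = rng.standard_normal(n)
        w = x + np.sqrt(sigma_w2) * rng.standard_normal(n)
        y = (rng.random(n) < 1 / (1 + np.exp(-beta_true * x))).astype(float)
        naive = fit_logistic(w, y)
        corrected = simex(w, y, sigma_w2, B=100, seed=1)
        assert naive.beta == pytest.approx(0.6, abs=0.12)
        # SIMEX moves at least half of the attenuation gap back toward truth
        assert corrected.beta_star > naive.beta + 0.4 * (beta_true - naive.beta)
        assert corrected.ci_star[0] < corrected.beta_star < corrected.ci_star[1]

    def test_deterministic_for_fixed_seed(self, rng):
        x, y = two_by_two(30, 20, 20, 30)
        a = simex(x + 0.01 * np.arange(len(x)), y, 0.3, B=20, seed=5)
        b = simex(x + 0.01 * np.arange(len(x)), y, 0.3, B=20, seed=5)
        assert a.beta_star == b.beta_star

    def test_bad_lambda_grid_rejected(self):
        x, y = two_by_two(20, 10, 10, 20)
        with pytest.raises(AssociationError):
            simex(x, y, 0.5, lambdas=(-0.5, 1.0))


class TestBhAdjust:
    def test_hand_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.04, 0.04, 0.04]),
                                   [0.04, 0.04, 0.04])

    def test_monotone_and_capped(self, rng):
        p = rng.uniform(0, 1, size=50)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert np.all(adj <= 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(AssociationError):
            bh_adjust([0.5, 1.2])


class TestAssignGroups:
    def labels_from_counts(self, counts):
        return np.repeat([k for k in counts], [counts[k] for k in counts])

    def test_cohort_arithmetic_two_group(self):
        counts = {"no alteration": 57, "BPH": 7, "inflammation": 12, "AAH": 2,
                  "ASAP": 11, "HGPIN": 4, "PCa": 55}
        ga = assign_groups(self.labels_from_counts(counts))
        assert ga.n_reference == 76
        assert ga.n_cases == 70
        assert ga.excluded.sum() == 2

    def test_four_group_counts(self):
        counts = {"no alteration": 57, "BPH": 7, "inflammation": 12, "AAH": 2,
                  "ASAP": 11, "HGPIN": 4, "PCa": 55}
        ga = assign_groups(self.labels_from_counts(counts), scheme="four-group")
        kept = ga.outcome[~ga.excluded]
        assert dict(zip(*np.unique(kept, return_counts=True))) == {
            "A": 57, "B": 19, "C": 15, "D": 55}

    def test_all_pca_all_cases(self):
        ga = assign_groups(["PCa"] * 5)
        assert np.all(ga.outcome == 1)

    def test_unknown_label_rejected(self):
        with pytest.raises(AssociationError, match="carcinoma"):
            assign_groups(["PCa", "carcinoma"])


class TestScreensAndModels:
    def make_screen_inputs(self, seed=0):
        design = CaseControlDesign(n_cases=80, n_controls=80, n_features=4,
                                   beta_true=[0.8, 0.0, 0.0, 0.0],
                                   sigma_b2=1.0, sigma_w2=0.5, seed=seed)
        table, pheno = generate_case_control_study(design)
        log2 = FeatureTable(np.log2(table.values), table.mz, table.meta,
                            table.below_lod, state="log2")
        return log2, pheno["outcome"].to_numpy()

    def test_single_feature_screen_reduces_to_fit_plus_rcal(self):
        log2, y = self.make_screen_inputs()
        single = FeatureTable(log2.values[:, :1], log2.mz[:1], log2.meta,
                              log2.below_lod[:, :1], state="log2")
        frame = univariate_screen(single, y, icc_per_feature=[0.6],
                                  methods=("rcal",))
        fit = fit_logistic(single.values[:, 0], y)
        assert frame.loc[0, "beta"] == pytest.approx(fit.beta)
        assert frame.loc[0, "beta_star_rcal"] == pytest.approx(fit.beta / 0.6)
        assert frame.loc[0, "bh_p"] == pytest.approx(fit.p)

    def test_screen_uses_median_icc_for_missing_error_structures(self):
        log2, y = self.make_screen_inputs()
        icc = [0.5, np.nan, 0.7, np.nan]  # median of finite = 0.6
        frame = univariate_screen(log2, y, icc_per_feature=icc, methods=("rcal",))
        assert frame.loc[1, "icc_used"] == pytest.approx(0.6)
        assert frame.loc[3, "icc_used"] == pytest.approx(0.6)

    def test_screen_requires_log2_state(self):
        design = CaseControlDesign(n_cases=30, n_controls=30, n_features=2, seed=1)
        table, pheno = generate_case_control_study(design)
        with pytest.raises(AssociationError, match="log2"):
            univariate_screen(table, pheno["outcome"].to_numpy())

    def test_model_object_round_trip(self):
        log2, y = self.make_screen_inputs()
        model = MeasurementErrorLogit(y, log2.values[:, 0], icc=0.6,
                                      sigma_w2=0.5, name="mz1000")
        res = model.fit(method="rcal")
        assert res.corrected.beta_star == pytest.approx(res.naive.beta / 0.6)
        assert "mz1000" in res.summary()

    def test_multivariate_orthogonal_matches_univariate(self, rng):
        n = 4000
        x = rng.standard_normal((n, 2))
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.5 * x[:, 0] - 0.5 * x[:, 1])))
             ).astype(float)
        joint = multivariate_fit(x, y)
        for j in range(2):
            solo = fit_logistic(x[:, j], y)
            assert joint.params[j + 1] == pytest.approx(solo.beta, abs=0.08)

    def test_duplicated_feature_collinearity_error(self, rng):
        x = rng.standard_normal(50)
        X = np.column_stack([x, x])
        y = (x > 0).astype(float)
        with pytest.raises(AssociationError, match="collinear"):
            multivariate_fit(X, y, names=("f1", "f2"))

    def test_empty_selection_rejected(self):
        with pytest.raises(AssociationError):
            multivariate_fit(np.empty((10, 0)), np.r_[np.ones(5), np.zeros(5)])
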