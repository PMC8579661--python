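"""Outcome model: logistic fits, stepwise elimination, fit indices, ROC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from connfp import (
    SeizureOutcomeModel,
    backward_stepwise,
    classification_table,
    fit_indices,
    fit_logistic,
    hosmer_lemeshow,
    roc_auc,
)


def _table_from_2x2(n11, n10, n01, n00):
    """Feature table with one binary predictor: (predictor=1 & y=1) = n11 etc."""
    rows = []
    for x, y, n in ((1, 1, n11), (1, 0, n10), (0, 1, n01), (0, 0, n00)):
        rows += [{"id": f"s{len(rows) + k}", "x_ind": x, "outcome": y}
                 for k in range(n)]
    return pd.DataFrame(rows)


class TestFitLogistic:
    def test_2x2_slope_equals_log_odds_ratio(self):
        # increased/not x SF/non-SF cell counts (6,8;1,15): the MLE slope of
        # a saturated single-binary-predictor logistic model is the log OR
        table = _table_from_2x2(6, 1, 8, 15)
        res = fit_logistic(table, ["x_ind"])
        assert res.params["x_ind"] == pytest.approx(np.log(11.25), abs=1e-4)

    def test_balanced_cells_give_zero_slope(self):
        table = _table_from_2x2(5, 5, 5, 5)
        res = fit_logistic(table, ["x_ind"])
        assert res.params["x_ind"] == pytest.approx(0.0, abs=1e-6)

    def test_intercept_only_fits_bernoulli_mean(self):
        table = _table_from_2x2(0, 0, 14, 16)  # 14/16 split, constant predictor
        model = SeizureOutcomeModel.from_feature_table(table, predictors=["x_ind"])
        res = model.fit_backward()
        assert res.predictors == []
        assert np.allclose(res.fittedvalues, 14 / 30)

    def test_constant_outcome_raises(self):
        table = _table_from_2x2(5, 0, 5, 0)
        with pytest.raises(ValueError, match="constant"):
            SeizureOutcomeModel.from_feature_table(table, predictors=["x_ind"])

    def test_separation_flagged_not_raised(self):
        table = _table_from_2x2(10, 0, 0, 10)  # perfect separation
        res = fit_logistic(table, ["x_ind"])
        assert res.separation

    def test_too_few_observations_raises(self, rng):
        table = pd.DataFrame({
            "a_ind": [0, 1, 0], "b_ind": [1, 0, 1], "c_ind": [1, 1, 0],
            "outcome": [0, 1, 1],
        })
        with pytest.raises(ValueError, match="too small"):
            fit_logistic(table, ["a_ind", "b_ind", "c_ind"])


class TestBackwardStepwise:
    def test_permuted_copy_removed_before_planted_predictor(self, rng):
        n = 500
        x1 = rng.integers(0, 2, n)
        eta = -0.5 + 2.0 * x1
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        table = pd.DataFrame({
            "planted_ind": x1,
            "permuted_ind": rng.permutation(x1),
            "outcome": y,
        })
        res = backward_stepwise(table)
        removed = [e["predictor"] for e in res.removal_log
                   if e["action"] == "removed"]
        assert removed and removed[0] == "permuted_ind"
        assert "planted_ind" in res.predictors

    def test_single_strong_predictor_is_fixed_point(self, rng):
        n = 200
        x = rng.integers(0, 2, n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(2.0 * x - 1)))).astype(int)
        table = pd.DataFrame({"x_ind": x, "outcome": y})
        stepwise = backward_stepwise(table)
        direct = fit_logistic(table, ["x_ind"])
        assert stepwise.predictors == ["x_ind"]
        pd.testing.assert_series_equal(stepwise.params, direct.params)

    def test_pure_noise_predictors_mostly_eliminated(self, rng):
        n = 800
        table = pd.DataFrame({
            f"n{j}_ind": rng.integers(0, 2, n) for j in range(6)
        })
        table["outcome"] = rng.integers(0, 2, n)
        res = backward_stepwise(table)
        # the procedure has type-I inflation, so do not demand exactly zero
        assert len(res.predictors) <= 2

    def test_constant_column_dropped_upfront(self, rng):
        n = 60
        x = rng.integers(0, 2, n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(2.0 * x - 1)))).astype(int)
        table = pd.DataFrame({"x_ind": x, "flat_ind": np.ones(n, dtype=int),
                              "outcome": y})
        res = backward_stepwise(table)
        dropped = [e["predictor"] for e in res.removal_log
                   if "constant" in e["action"]]
        assert dropped == ["flat_ind"]


class TestFitIndices:
    def test_printed_model_chi_square_recovers_cox_snell(self):
        # LL1 chosen so that X2 = 15.19 with n = 30
        ll0 = 14 * np.log(14 / 30) + 16 * np.log(16 / 30)
        ll1 = ll0 + 15.19 / 2
        x2, cs, nk = fit_indices(ll0, ll1, 30)
        assert x2 == pytest.approx(15.19, abs=1e-12)
        assert cs == pytest.approx(0.3973, abs=5e-4)
        assert nk == pytest.approx(0.5305, abs=5e-4)

    def test_equal_likelihoods_give_zero(self):
        x2, cs, nk = fit_indices(-20.0, -20.0, 30)
        assert x2 == cs == nk == 0.0

    @given(
        ll0=st.floats(-200.0, -1.0),
        gain=st.floats(0.0, 50.0),
        n=st.integers(5, 500),
    )
    @settings(max_examples=100, deadline=None)
    def test_cox_snell_never_exceeds_nagelkerke(self, ll0, gain, n):
        _, cs, nk = fit_indices(ll0, ll0 + gain, n)
        assert 0.0 <= cs <= nk + 1e-12


class TestHosmerLemeshow:
    def test_perfect_calibration_gives_zero(self):
        p = np.array([0.25] * 8 + [0.75] * 8)
        y = np.array([1, 1, 0, 0, 0, 0, 0, 0] + [1, 1, 1, 1, 1, 1, 0, 0])
        with pytest.warns(UserWarning, match="effective groups"):
            c, pval, g = hosmer_lemeshow(p, y)
        assert c == pytest.approx(0.0, abs=1e-12)
        assert g == 2 and np.isnan(pval)

    def test_two_group_arithmetic_oracle(self):
        p = np.array([0.2] * 5 + [0.8] * 5)
        y = np.array([1, 0, 0, 0, 0] + [1, 1, 1, 0, 0])
        with pytest.warns(UserWarning):
            c, _, _ = hosmer_lemeshow(p, y)
        # group 1: e1=1, o1=1 -> 0; group 2: e1=4, o1=3 ->
        # (3-4)^2/4 + (2-1)^2/1 = 0.25 + 1
        assert c == pytest.approx(1.25, abs=1e-12)

    def test_well_specified_model_chi_square_mean(self, rng):
        # C ~ chi-square(groups - 2) for a well-specified model: the mean
        # over replicates should sit near 8 for 10 groups
        import statsmodels.api as sm

        n, reps = 400, 300
        cs = []
        for _ in range(reps):
            x = rng.standard_normal(n)
            y = (rng.random(n) < 1 / (1 + np.exp(-x))).astype(float)
            res = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
            c, _, g = hosmer_lemeshow(res.predict(), y, 10)
            assert g == 10
            cs.append(c)
        assert abs(np.mean(cs) - 8.0) < 0.1 * 8.0

    def test_boundary_probabilities_rejected(self):
        with pytest.raises(ValueError):
            hosmer_lemeshow(np.array([0.0, 0.5]), np.array([0, 1]))


class TestClassificationTable:
    def test_perfect_probabilities(self):
        y = np.array([0, 1, 1, 0])
        p = np.array([0.01, 0.99, 0.98, 0.02])
        ct = classification_table(p, y)
        assert ct["overall_pct"] == ct["positive_pct"] == ct["negative_pct"] == 100.0

    def test_all_predicted_negative(self):
        y = np.array([0, 0, 0, 1, 1])
        p = np.full(5, 0.4)
        ct = classification_table(p, y)
        assert ct["overall_pct"] == pytest.approx(60.0)
        assert ct["negative_pct"] == 100.0
        assert ct["positive_pct"] == 0.0

    def test_matches_counting_oracle(self, rng):
        y = rng.integers(0, 2, 50)
        p = rng.random(50)
        ct = classification_table(p, y, cutoff=0.5)
        pred = (p >= 0.5).astype(int)
        assert ct["overall_pct"] == pytest.approx(100 * (pred == y).mean())


class TestROC:
    def test_perfect_separation_auc_one(self):
        y = np.array([0, 0, 1, 1])
        assert roc_auc(np.array([0.1, 0.2, 0.8, 0.9]), y).auc == 1.0

    def test_all_ties_auc_half(self):
        y = np.array([0, 1, 0, 1])
        assert roc_auc(np.full(4, 0.5), y).auc == 0.5

    def test_matches_all_pairs_oracle(self, rng):
        for seed in range(3):
            r = np.random.default_rng(seed)
            y = np.r_[np.zeros(10), np.ones(10)].astype(int)
            p = np.round(r.random(20), 1)  # force some ties
            auc = roc_auc(p, y).auc
            pos, neg = p[y == 1], p[y == 0]
            wins = sum((pp > nn) + 0.5 * (pp == nn) for pp in pos for nn in neg)
            assert auc == pytest.approx(wins / 100, abs=1e-12)

    def test_trapezoid_equals_mann_whitney(self, rng):
        res = roc_auc(rng.random(40), rng.integers(0, 2, 40))
        fpr = 1 - res.specificity
        trap = np.trapezoid(res.sensitivity, fpr)
        assert trap == pytest.approx(res.auc, abs=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([0.2, 0.8]), np.array([1, 1]))


class TestResultsObject:
    def test_summary_reports_core_fields(self, rng):
        n = 80
        x = rng.integers(0, 2, n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(1.5 * x - 0.5)))).astype(int)
        table = pd.DataFrame({"mesial_ipsilateral_ind": x, "outcome": y})
        res = backward_stepwise(table)
        text = res.summary()
        for token in ("seizure-free", "Nagelkerke", "ROC AUC", "classification"):
            assert token in text

    def test_lr_statistic_consistency(self, rng):
        n = 100
        x = rng.integers(0, 2, n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(2.0 * x - 1)))).astype(int)
        res = fit_logistic(pd.DataFrame({"x_ind": x, "outcome": y}), ["x_ind"])
        assert res.llf >= res.llnull
        assert res.lr_stat == pytest.approx(-2 * (res.llnull - res.llf))
        assert res.lr_pvalue == pytest.approx(stats.chi2.sf(res.lr_stat, 1))
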