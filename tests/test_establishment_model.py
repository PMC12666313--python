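import itertools
import math

import numpy as np
import pandas as pd
import pytest

from odrs.errors import DomainError
from odrs.establishment_model import (
    CANDIDATE_TERMS,
    VIF_INF,
    _fit_terms,
    backward_aic,
    biopsy_periods,
    fit_establishment_model,
    fit_logistic,
    model_performance,
    prepare_cohort,
    vif,
)
from odrs.synthetic_data import DEFAULT_PERIOD_KNOTS, generate_establishment_cohort


class TestFitLogistic:
    def test_intercept_only_recovers_log_odds(self):
        y = np.array([1] * 30 + [0] * 70)
        design = pd.DataFrame({"const": np.ones(100)})
        fit = fit_logistic(design, y)
        assert fit.params["const"] == pytest.approx(math.log(30 / 70), abs=1e-6)
        # AIC = 2k - 2l
        assert fit.aic == pytest.approx(2 * 1 - 2 * fit.loglik)

    def test_recovers_known_coefficients_within_three_se(self):
        rng = np.random.default_rng(8)
        n = 5000
        x1 = rng.normal(size=n)
        x2 = rng.binomial(1, 0.4, size=n).astype(float)
        eta = -0.5 + 0.8 * x1 - 1.2 * x2
        y = rng.random(n) < 1 / (1 + np.exp(-eta))
        design = pd.DataFrame({"const": 1.0, "x1": x1, "x2": x2})
        fit = fit_logistic(design, y.astype(int))
        se = fit.result.bse
        for name, true in (("const", -0.5), ("x1", 0.8), ("x2", -1.2)):
            assert abs(fit.params[name] - true) < 3 * se[name]

    def test_single_class_outcome_rejected(self):
        with pytest.raises(DomainError):
            fit_logistic(pd.DataFrame({"const": np.ones(10)}), np.ones(10))

    def test_separation_is_flagged_not_fatal(self):
        x = np.linspace(-3, 3, 30)
        y = (x > 0).astype(int)
        fit = fit_logistic(pd.DataFrame({"const": 1.0, "x": x}), y)
        assert fit.separation_flag


def _cohort(n=500, coefficients=None, seed=0):
    df = generate_establishment_cohort(n, coefficients=coefficients, seed=seed)
    return prepare_cohort(df, knots=DEFAULT_PERIOD_KNOTS)


class TestBackwardAic:
    def test_pure_noise_predictors_are_mostly_dropped(self):
        # AIC keeps a 1-df noise term iff its chi-square improvement exceeds
        # 2, i.e. with probability P(chi2_1 > 2) ~ 0.157 per term; the null
        # expectation over 4 candidates is ~0.6 retained terms per cohort
        retained = []
        for seed in range(20):
            data = _cohort(400, coefficients={"intercept": 0.0}, seed=seed)
            selected, _ = backward_aic(data, ["age", "sex", "mutation", "location"])
            retained.append(len(selected))
        assert np.mean(retained) < 1.5
        assert any(r == 0 for r in retained)

    def test_strong_predictor_retained(self):
        data = _cohort(500, coefficients={"intercept": -0.7, "ldh_elevated": 1.5}, seed=4)
        selected, _ = backward_aic(data, ["age", "sex", "ldh_elevated", "mutation"])
        assert "ldh_elevated" in selected

    def test_empty_candidate_set_gives_intercept_only(self):
        data = _cohort(200, seed=5)
        selected, res = backward_aic(data, [])
        assert selected == () and len(res.params) == 1

    def test_matches_exhaustive_best_aic_subset_search(self):
        terms = ["age", "sex", "ldh_elevated", "hospital", "mutation"]
        for seed in (11, 12, 13):
            data = _cohort(
                400,
                coefficients={"intercept": -0.5, "ldh_elevated": 1.2, "academic": 0.9},
                seed=seed,
            )
            selected, _ = backward_aic(data, terms)
            best_aic, best_subset = np.inf, None
            for r in range(len(terms) + 1):
                for subset in itertools.combinations(terms, r):
                    aic = _fit_terms(data, list(subset)).aic
                    if aic < best_aic:
                        best_aic, best_subset = aic, set(subset)
            assert set(selected) == best_subset


class TestVif:
    def test_orthogonal_columns_are_one(self):
        rng = np.random.default_rng(2)
        raw = rng.normal(size=(100, 3))
        q, _ = np.linalg.qr(np.column_stack([np.ones(100), raw]))
        design = pd.DataFrame(q[:, 1:], columns=["a", "b", "c"])
        out = vif(design)
        for v in out.values():
            assert v == pytest.approx(1.0, abs=1e-9)

    def test_duplicated_column_hits_the_sentinel(self):
        x = np.random.default_rng(3).normal(size=50)
        out = vif(pd.DataFrame({"a": x, "b": x, "c": np.arange(50.0)}))
        assert out["a"] == VIF_INF and out["b"] == VIF_INF

    def test_correlation_0p9_gives_closed_form(self):
        # build columns with exact sample correlation 0.9
        rng = np.random.default_rng(4)
        base = rng.normal(size=(200, 2))
        base -= base.mean(axis=0)
        q, _ = np.linalg.qr(base)
        z1, z2 = q[:, 0], q[:, 1]
        x2 = 0.9 * z1 + math.sqrt(1 - 0.81) * z2
        out = vif(pd.DataFrame({"x1": z1, "x2": x2}))
        assert out["x1"] == pytest.approx(1 / (1 - 0.81), rel=1e-9)

    def test_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=80)
        b = 0.6 * a + rng.normal(size=80)
        before = vif(pd.DataFrame({"a": a, "b": b}))
        after = vif(pd.DataFrame({"a": 100 * a - 7, "b": b}))
        assert before["b"] == pytest.approx(after["b"], rel=1e-9)


class _Stub:
    def __init__(self, prob):
        self._p = np.asarray(prob, dtype=float)

    def predict(self, data):
        return self._p


class TestModelPerformance:
    def test_predictions_equal_outcomes_is_perfect(self):
        y = np.array([0, 1, 0, 1, 1, 0, 1, 0, 1, 0])
        data = pd.DataFrame({"success": y})
        out = model_performance(_Stub(y.astype(float)), data)
        assert out["auroc"] == 1.0

    def test_constant_predictions_are_chance(self):
        y = np.array([0, 1] * 10)
        out = model_performance(_Stub(np.full(20, 0.5)), pd.DataFrame({"success": y}))
        assert out["auroc"] == 0.5

    def test_large_sample_auroc_matches_analytic_value(self):
        # success generated from a logistic model; the analytic AUROC is the
        # probability a success's linear predictor exceeds a failure's
        rng = np.random.default_rng(6)
        n = 1000
        eta = rng.normal(0.0, 1.2, size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        prob = 1 / (1 + np.exp(-eta))
        out = model_performance(_Stub(prob), pd.DataFrame({"success": y}))
        pos, neg = eta[y == 1], eta[y == 0]
        analytic = np.mean(pos[:, None] > neg[None, :])
        assert out["auroc"] == pytest.approx(analytic, abs=0.03)

    def test_calibration_bins_cover_all_subjects(self):
        rng = np.random.default_rng(7)
        y = rng.integers(0, 2, 100)
        out = model_performance(_Stub(rng.random(100)), pd.DataFrame({"success": y}))
        assert out["calibration"]["n"].sum() == 100
        assert out["prob_summary"]["min"] <= out["prob_summary"]["q25"]


class TestFullModel:
    def test_end_to_end_fit_on_synthetic_cohort(self):
        df = generate_establishment_cohort(600, seed=9)
        fit = fit_establishment_model(df, knots=DEFAULT_PERIOD_KNOTS)
        # generator's true drivers should be found at this sample size
        assert {"sex", "ldh_elevated", "hospital", "biopsy_period"} <= set(fit.selected_terms)
        assert 0.6 < fit.auroc <= 1.0
        assert all(v >= 1.0 for v in fit.vif.values())
        # selected-model AIC is no worse than the full model's
        full = _fit_terms(prepare_cohort(df, DEFAULT_PERIOD_KNOTS), list(CANDIDATE_TERMS))
        assert fit.aic <= full.aic + 1e-9

    def test_biopsy_period_default_knots_are_terciles(self):
        days = np.arange(90.0)
        labels = biopsy_periods(days)
        assert list(np.unique(labels)) == ["P1", "P2", "P3"]
        assert (labels == "P1").sum() == 30
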