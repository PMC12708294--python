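import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from asymstroke.predictor import (
    auc_mann_whitney,
    decision_curve,
    delong_ci,
    lasso_fit,
    roc_analysis,
    select_predictors,
    soft_threshold,
)


def orthonormal_design(n, p, seed=0):
    """Exactly centered, unit-variance, mutually orthogonal columns."""
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(np.column_stack([np.ones(n), rng.normal(size=(n, p))]))
    return q[:, 1:] * np.sqrt(n)


class TestLassoFit:
    def test_soft_threshold_closed_form_single_predictor(self):
        # single standardized predictor with OLS coefficient 2: at lambda = 1
        # the solution is exactly 1
        x = orthonormal_design(100, 1, seed=3)
        y = x[:, 0] * 2.0
        fit = lasso_fit(x, y, cv_folds=4, seed=0)
        i = int(np.argmin(np.abs(fit.lambdas - 1.0)))
        lam = fit.lambdas[i]
        assert fit.coef_path[i, 0] == pytest.approx(2.0 - lam, abs=1e-8)

    def test_orthonormal_equals_soft_threshold_along_path(self):
        x = orthonormal_design(200, 5, seed=1)
        beta = np.array([2.0, -1.5, 0.5, 0.0, 3.0])
        y = x @ beta
        fit = lasso_fit(x, y, cv_folds=5, seed=0)
        bols = x.T @ (y - y.mean()) / len(y)
        for i, lam in enumerate(fit.lambdas):
            expect = np.sign(bols) * np.maximum(np.abs(bols) - lam, 0.0)
            assert np.max(np.abs(fit.coef_path[i] - expect)) < 1e-8

    def test_lambda_max_zeroes_everything(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(80, 6))
        y = rng.normal(size=80) + x[:, 0]
        fit = lasso_fit(x, y, cv_folds=4, seed=0)
        assert np.all(fit.coef_path[0] == 0.0)

    def test_null_selection_is_sparse(self):
        counts = []
        for seed in range(15):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=(200, 20))
            y = rng.normal(size=200)
            fit = lasso_fit(x, y, cv_folds=5, seed=seed)
            counts.append(len(select_predictors(fit)))
        assert np.median(counts) <= 3

    def test_constant_column_dropped_constant_y_rejected(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(50, 3))
        x[:, 1] = 7.0
        with pytest.warns(UserWarning, match="constant"):
            fit = lasso_fit(x, x[:, 0] + rng.normal(size=50), cv_folds=5, seed=0)
        assert fit.dropped == ["x1"]
        with pytest.raises(ValueError, match="constant"):
            lasso_fit(x[:, :1], np.ones(50), cv_folds=5, seed=0)

    def test_binomial_family_runs_and_separates(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(150, 4))
        y = (x[:, 0] + 0.5 * rng.normal(size=150) > 0).astype(float)
        fit = lasso_fit(x, y, family="binomial", cv_folds=5, seed=1)
        assert "x0" in select_predictors(fit)

    def test_missing_values_rejected(self):
        x = np.ones((10, 2))
        x[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            lasso_fit(x, np.arange(10.0), cv_folds=2, seed=0)


class TestSelectPredictors:
    def test_ordering_and_bounds(self):
        x = orthonormal_design(300, 4, seed=5)
        y = x @ np.array([0.1, 3.0, -1.0, 0.0])
        fit = lasso_fit(x, y, cv_folds=5, seed=0)
        sel = select_predictors(fit)
        assert len(sel) <= 4
        assert sel[0] == "x1"  # largest |coefficient| first

    def test_recovery_of_generating_variables(self):
        from asymstroke.cohort import SimulationParams, simulate_cohort

        hits = 0
        for seed in range(10):
            t = simulate_cohort(SimulationParams(
                seed=seed, outcome_coefs={"gcs": 0.6, "adl": 0.6,
                                          "mrs_discharge": 0.6},
                outcome_noise_sd=1.0))
            df = t.data
            cols = ["gcs", "adl", "mrs_discharge", "age", "infarct_volume_ml",
                    "crp", "hba1c", "ldh", "glucose", "chloride"]
            fit = lasso_fit(df[cols].astype(float), df.lang.to_numpy(float),
                            cv_folds=5, seed=seed)
            sel = select_predictors(fit)
            hits += all(v in sel for v in ("gcs", "adl", "mrs_discharge"))
        assert hits >= 9

    def test_all_zero_path_gives_empty_list(self):
        from asymstroke.predictor import LassoFit

        fit = LassoFit(["a", "b"], np.array([1.0]), np.zeros((1, 2)),
                       np.zeros(1), np.zeros(1), 0, np.zeros(4, int),
                       "gaussian", 0)
        assert select_predictors(fit) == []


class TestRoc:
    def test_perfect_separation(self):
        r = roc_analysis([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert r.auc == 1.0 and r.ci_high == 1.0
        assert r.sensitivity == 1.0 and r.specificity == 1.0

    def test_rank_statistic_enumeration(self):
        assert auc_mann_whitney([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0
        assert auc_mann_whitney([1, 1, 2, 2], [0, 1, 0, 1]) == 0.5

    def test_auc_equals_pairwise_oracle(self):
        rng = np.random.default_rng(0)
        for trial in range(20):
            n = int(rng.integers(10, 200))
            scores = np.round(rng.normal(size=n), 1)  # force ties
            labels = (rng.random(n) < 0.4).astype(int)
            if labels.sum() in (0, n):
                continue
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            oracle = np.mean([1.0 if a > b else 0.5 if a == b else 0.0
                              for a in pos for b in neg])
            assert auc_mann_whitney(scores, labels) == pytest.approx(oracle)

    def test_confusion_metrics_match_counts(self):
        scores = np.r_[np.full(35, 0.9), np.full(10, 0.1),
                       np.full(37, 0.9), np.full(82, 0.1)]
        labels = np.r_[np.ones(45), np.zeros(119)].astype(int)
        r = roc_analysis(scores, labels)
        assert (r.tp, r.fn, r.tn, r.fp) == (35, 10, 82, 37)
        assert r.sensitivity == pytest.approx(0.778, abs=5e-4)
        assert r.specificity == pytest.approx(0.689, abs=5e-4)

    def test_delong_ci_contains_auc(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=100)
        labels = (rng.random(100) < 0.3).astype(int)
        auc, lo, hi = delong_ci(scores, labels)
        assert lo <= auc <= hi

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis([0.1, 0.2], [1, 1])


class TestDecisionCurve:
    def test_threshold_zero_identity(self):
        rng = np.random.default_rng(0)
        scores = rng.random(40)
        labels = (rng.random(40) < 0.35).astype(int)
        d = decision_curve(scores, labels, thresholds=np.linspace(0, 0.9, 19),
                           n_boot=20, seed=0)
        assert d.nb_model[0] == pytest.approx(labels.mean())
        assert d.nb_all[0] == pytest.approx(labels.mean())
        assert np.all(d.nb_none == 0.0)

    def test_hand_evaluated_net_benefit(self):
        # n = 10 with 4 positives; at p_t = 0.5 the classifier catches
        # TP = 3, FP = 1 -> NB = (3 - 1*1)/10 = 0.2
        scores = np.array([0.6, 0.7, 0.8, 0.3, 0.55, 0.2, 0.1, 0.2, 0.3, 0.4])
        labels = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        d = decision_curve(scores, labels, thresholds=np.array([0.5]),
                           n_boot=10, seed=0)
        assert d.nb_model[0] == pytest.approx(0.2)

    def test_treat_all_crosses_zero_at_prevalence(self):
        labels = np.r_[np.ones(30), np.zeros(70)].astype(int)
        prev = labels.mean()
        scores = np.clip(labels * 0.6 + 0.2, 0, 1)
        d = decision_curve(scores, labels,
                           thresholds=np.array([prev - 1e-9, prev, prev + 1e-9]),
                           n_boot=5, seed=0)
        assert d.nb_all[0] > 0 >= d.nb_all[2]
        assert d.nb_all[1] == pytest.approx(0.0, abs=1e-12)

    def test_invalid_thresholds_and_scores(self):
        with pytest.raises(ValueError, match="< 1"):
            decision_curve([0.5], [1], thresholds=np.array([1.0]))
        with pytest.raises(ValueError, match="probabilities"):
            decision_curve([1.5], [1], thresholds=np.array([0.2]))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_identities_hold_for_random_inputs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 60))
        scores = rng.random(n)
        labels = (rng.random(n) < 0.5).astype(int)
        d = decision_curve(scores, labels, thresholds=np.linspace(0, 0.95, 10),
                           n_boot=5, seed=0)
        assert np.all(d.nb_none == 0.0)
        assert d.nb_model[0] == pytest.approx(labels.mean())


def test_soft_threshold_values():
    assert soft_threshold(2.0, 1.0) == 1.0
    assert soft_threshold(-2.0, 1.0) == -1.0
    assert soft_threshold(0.5, 1.0) == 0.0
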