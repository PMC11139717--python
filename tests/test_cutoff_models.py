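import numpy as np
import pandas as pd
import pytest

from noduletex.cutoff_models import (CutoffRule, binarize, roc_auc,
                                     stepwise_logistic, univariate_logistic,
                                     youden_cutoff)
from .oracles import auc_oracle, youden_oracle


class TestYoudenCutoff:
    def test_perfect_separation_midpoint(self):
        values = [5, 6, 7, 1, 2, 3]
        labels = [1, 1, 1, 0, 0, 0]
        rule = youden_cutoff(values, labels)
        assert rule.threshold == pytest.approx(4.0)
        assert rule.direction == "greater"
        assert rule.youden_j == pytest.approx(1.0)

    def test_coincident_distributions_j_zero(self):
        values = [1, 2, 1, 2]
        labels = [0, 0, 1, 1]
        assert youden_cutoff(values, labels).youden_j == pytest.approx(0.0)

    def test_negated_feature_flips_direction_same_j(self):
        values = np.array([5.0, 6, 7, 1, 2, 3])
        labels = np.array([1, 1, 1, 0, 0, 0])
        pos_rule = youden_cutoff(values, labels)
        neg_rule = youden_cutoff(-values, labels)
        assert neg_rule.direction == "less-or-equal"
        assert neg_rule.youden_j == pytest.approx(pos_rule.youden_j)

    def test_constant_feature_rejected(self):
        with pytest.raises(ValueError, match="no discriminating cutoff"):
            youden_cutoff([2.0, 2.0, 2.0], [1, 0, 1])

    def test_matches_exhaustive_oracle_random_sweep(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(6, 25))
            values = rng.integers(0, 8, n).astype(float)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max() or np.unique(values).size < 2:
                continue
            rule = youden_cutoff(values, labels)
            j_oracle, _, _ = youden_oracle(values, labels)
            assert rule.youden_j == pytest.approx(j_oracle)

    def test_binarize_reproduces_j_exactly(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            values = rng.normal(size=20)
            labels = rng.integers(0, 2, 20)
            if labels.min() == labels.max():
                continue
            rule = youden_cutoff(values, labels)
            pred = binarize(values, rule)
            sens = pred[labels == 1].mean()
            spec = 1 - pred[labels == 0].mean()
            assert sens + spec - 1 == pytest.approx(rule.youden_j)


class TestBinarize:
    def test_greater_is_strict_at_threshold(self):
        rule = CutoffRule("f", 4.0, "greater", 0.5, 0.8, 0.7)
        out = binarize([4.0, 4.01], rule)
        assert list(out) == [0, 1]

    def test_less_or_equal_is_inclusive(self):
        rule = CutoffRule("cov", -1.13, "less-or-equal", 0.5, 0.8, 0.7)
        assert binarize([-1.13], rule)[0] == 1

    def test_constant_output_warns(self):
        rule = CutoffRule("f", 0.0, "greater", 0.5, 0.8, 0.7)
        with pytest.warns(UserWarning, match="constant"):
            binarize([1.0, 2.0, 3.0], rule)

    def test_missing_value_rejected(self):
        rule = CutoffRule("f", 0.0, "greater", 0.5, 0.8, 0.7)
        with pytest.raises(ValueError, match="missing"):
            binarize([1.0, np.nan], rule)


class TestUnivariateLogistic:
    def test_or_equals_cross_product_ratio(self):
        # TP=10, FP=5, FN=5, TN=10 -> OR = 100/25 = 4
        x = np.array([1] * 10 + [1] * 5 + [0] * 5 + [0] * 10)
        y = np.array([1] * 10 + [0] * 5 + [1] * 5 + [0] * 10)
        fit = univariate_logistic(x, y, name="f")
        assert fit.terms.loc["f", "odds_ratio"] == pytest.approx(4.0, rel=1e-5)
        assert fit.terms.loc["f", "ci_low"] < 4.0 < fit.terms.loc["f", "ci_high"]

    def test_null_predictor_or_near_one(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 2, 2000)
        y = rng.integers(0, 2, 2000)
        fit = univariate_logistic(x, y)
        assert fit.terms.iloc[0]["odds_ratio"] == pytest.approx(1.0, abs=0.2)

    def test_zero_cell_raises_separation_flag(self):
        x = np.array([1] * 10 + [0] * 10)
        y = np.array([1] * 10 + [0] * 10)
        fit = univariate_logistic(x, y)
        assert "separation" in fit.flags
        assert fit.method == "wald-haldane"

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            univariate_logistic([1, 1, 1], [0, 1, 0])


class TestStepwiseLogistic:
    def _sim(self, seed=0, n=300):
        rng = np.random.default_rng(seed)
        true = rng.integers(0, 2, n)
        noise = rng.integers(0, 2, n)
        # outcome driven by `true` with OR ~ 10
        logit = -1.5 + np.log(10) * true
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
        return pd.DataFrame({"true": true, "noise": noise}), y

    def test_recovers_true_predictor_only(self):
        X, y = self._sim(seed=4)
        fit = stepwise_logistic(X, y)
        assert fit.included == ["true"]

    def test_all_null_gives_intercept_only(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"a": rng.integers(0, 2, 200),
                          "b": rng.integers(0, 2, 200)})
        y = rng.integers(0, 2, 200)
        fit = stepwise_logistic(X, y)
        assert fit.included == []
        assert "intercept-only" in fit.flags

    def test_duplicate_predictor_enters_once(self):
        X, y = self._sim(seed=5)
        X["copy"] = X["true"]
        fit = stepwise_logistic(X, y)
        assert len([c for c in fit.included if c in ("true", "copy")]) == 1

    def test_deterministic(self):
        X, y = self._sim(seed=6)
        a = stepwise_logistic(X, y)
        b = stepwise_logistic(X, y)
        assert a.included == b.included
        assert a.terms.equals(b.terms)


class TestRocAuc:
    def test_perfect_separation(self):
        auc, ci = roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert auc == 1.0
        assert ci[1] == 1.0

    def test_binary_prediction_auc_is_mean_of_sens_spec(self):
        # sens 1.0, spec 0.396 on 16/48 -> AUC 0.698
        from noduletex.reader_eval import predictions_from_rates

        truth, pred = predictions_from_rates(1.0, 0.396, 16, 48)
        auc, ci = roc_auc(pred, truth)
        assert round(auc, 3) == 0.698
        sens = pred[truth == 1].mean()
        spec = 1 - pred[truth == 0].mean()
        assert auc == pytest.approx((sens + spec) / 2)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.random(4000)
        labels = rng.integers(0, 2, 4000)
        auc, _ = roc_auc(scores, labels)
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, 50)
        a, _ = roc_auc(scores, labels)
        b, _ = roc_auc(np.exp(scores), labels)
        assert a == pytest.approx(b)

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            scores = rng.integers(0, 5, 30).astype(float)
            labels = rng.integers(0, 2, 30)
            if labels.min() == labels.max():
                continue
            auc, _ = roc_auc(scores, labels)
            assert auc == pytest.approx(auc_oracle(scores, labels))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([0.1, 0.2], [1, 1])

    def test_hanley_method_available(self):
        auc, ci = roc_auc([3, 2, 4, 1, 5, 0], [1, 0, 1, 0, 1, 0],
                          method="hanley")
        assert 0 <= ci[0] <= auc <= ci[1] <= 1
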