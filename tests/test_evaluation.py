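import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from poaf_twin.evaluation import (
    UndefinedMetricError,
    brier_score,
    bootstrap_ci,
    calibration_slope,
    confusion_metrics,
    hosmer_lemeshow,
    metrics_report,
    roc_auc,
    youden_threshold,
)


def _pair_count_auc(scores, labels):
    """O(n^2) concordant-pair oracle (ties 1/2)."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pos = s[y == 1]
    neg = s[y == 0]
    total = conc = 0.0
    for a in pos:
        for b in neg:
            total += 1
            if a > b:
                conc += 1
            elif a == b:
                conc += 0.5
    return conc / total


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=4000)
        y = rng.integers(0, 2, 4000)
        # SE of AUC under the null is ~ 1/sqrt(12 * n_pos n_neg / n)
        assert abs(roc_auc(s, y) - 0.5) < 3 * np.sqrt(1 / (12 * 1000))

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(3)
        for n in (10, 25, 50):
            for _ in range(5):
                s = rng.integers(0, 6, n).astype(float)  # forces ties
                y = rng.integers(0, 2, n)
                if y.min() == y.max():
                    continue
                assert roc_auc(s, y) == pytest.approx(
                    _pair_count_auc(s, y), abs=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(5)
        s = rng.normal(size=300)
        y = (s + rng.normal(size=300) > 0).astype(int)
        assert roc_auc(s, y) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            roc_auc([1, 2, 3], [1, 1, 1])

    def test_bootstrap_ci_brackets_auc(self):
        rng = np.random.default_rng(1)
        s = rng.normal(size=400)
        y = (s + rng.normal(size=400) > 0).astype(int)
        auc = roc_auc(s, y)
        lo, hi = bootstrap_ci(s, y, n_boot=500, seed=2)
        assert lo < auc < hi
        assert hi - lo < 0.25


class TestYoudenThreshold:
    def test_separable_gives_max_j(self):
        s = np.array([1, 2, 3, 10, 11, 12])
        y = np.array([0, 0, 0, 1, 1, 1])
        t = youden_threshold(s, y)
        cm = confusion_metrics(s, y, t)
        assert cm["sensitivity"] + cm["specificity"] - 1 == pytest.approx(1.0)

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(7)
        s = rng.normal(size=30)
        y = (s + rng.normal(size=30) > 0).astype(int)
        t = youden_threshold(s, y)
        js = []
        for cand in np.unique(s):
            cm = confusion_metrics(s, y, cand)
            js.append(cm["sensitivity"] + cm["specificity"] - 1)
        cm_t = confusion_metrics(s, y, t)
        assert (cm_t["sensitivity"] + cm_t["specificity"] - 1
                == pytest.approx(max(js), abs=1e-12))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(9)
        s = rng.normal(size=50)
        y = (s + rng.normal(size=50) > 0).astype(int)
        t_lin = youden_threshold(s, y)
        t_exp = youden_threshold(np.exp(s), y)
        assert t_exp == pytest.approx(np.exp(t_lin), rel=1e-9)


class TestConfusionMetrics:
    def test_perfect_classification(self):
        s = np.array([0.1, 0.2, 0.8, 0.9])
        y = np.array([0, 0, 1, 1])
        cm = confusion_metrics(s, y, 0.5)
        for k in ("sensitivity", "specificity", "ppv", "npv"):
            assert cm[k] == 1.0

    def test_two_by_two_table_ratios(self):
        """TP=87 FN=13 FP=18 TN=82 -> sensitivity 87.0%, specificity 82.0%."""
        s = np.concatenate([np.ones(87), np.zeros(13), np.ones(18),
                            np.zeros(82)])
        y = np.concatenate([np.ones(100), np.zeros(100)]).astype(int)
        cm = confusion_metrics(s, y, 0.5)
        assert cm["sensitivity"] == pytest.approx(0.87)
        assert cm["specificity"] == pytest.approx(0.82)
        assert cm["ppv"] == pytest.approx(87 / 105)
        assert cm["npv"] == pytest.approx(82 / 95)

    def test_matches_manual_count(self):
        s = np.array([0.9, 0.8, 0.7, 0.65, 0.6, 0.55, 0.4, 0.35, 0.3,
                      0.2, 0.15, 0.1])
        y = np.array([1, 1, 0, 1, 0, 1, 1, 0, 0, 1, 0, 0])
        cm = confusion_metrics(s, y, 0.5)
        # manual: predictions >= 0.5 are the first six scores
        assert (cm["tp"], cm["fp"], cm["fn"], cm["tn"]) == (4, 2, 2, 4)

    def test_empty_positive_set_flagged(self):
        s = np.array([0.1, 0.2, 0.3, 0.4])
        y = np.array([0, 1, 0, 1])
        cm = confusion_metrics(s, y, 0.9)
        assert np.isnan(cm["ppv"])
        assert cm["flags"]


class TestHosmerLemeshow:
    def test_perfectly_calibrated_groups_zero(self):
        # within each group, predictions equal the group event rate
        p = np.repeat([0.2, 0.5, 0.8], 10)
        y = np.concatenate([
            [1, 1, 0, 0, 0, 0, 0, 0, 0, 0],
            [1, 1, 1, 1, 1, 0, 0, 0, 0, 0],
            [1, 1, 1, 1, 1, 1, 1, 1, 0, 0],
        ])
        chi2, p_val = hosmer_lemeshow(p, y, n_groups=3)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p_val == pytest.approx(1.0)

    def test_matches_hand_summed_two_group_toy(self):
        p = np.array([0.2, 0.2, 0.2, 0.8, 0.8, 0.8])
        y = np.array([0, 0, 1, 1, 1, 0])
        chi2, _ = hosmer_lemeshow(p, y, n_groups=2)
        exp1, exp2 = 0.6, 2.4
        hand = ((1 - exp1) ** 2 / (exp1 * (1 - exp1 / 3))
                + (2 - exp2) ** 2 / (exp2 * (1 - exp2 / 3)))
        assert chi2 == pytest.approx(hand, rel=1e-12)

    def test_p_uniform_under_correct_calibration(self):
        """p-values are uniform over replicates when the tested
        probabilities come from a correctly specified logistic fit (the
        setting in which the n_groups - 2 degrees of freedom apply)."""
        import statsmodels.api as sm
        from scipy.stats import kstest

        rng = np.random.default_rng(11)
        pvals = []
        for _ in range(200):
            x = rng.normal(size=1000)
            p_true = 1 / (1 + np.exp(-(-1.0 + 1.2 * x)))
            y = (rng.random(1000) < p_true).astype(int)
            fit = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
            pvals.append(hosmer_lemeshow(fit.predict(), y)[1])
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestCalibrationSlope:
    def test_self_calibration_near_one(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.05, 0.9, 10_000)
        y = rng.random(10_000) < p
        assert 0.9 <= calibration_slope(p, y) <= 1.1

    def test_doubled_logits_halve_slope(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0.1, 0.9, 10_000)
        y = rng.random(10_000) < p
        logit = np.log(p / (1 - p))
        p_over = 1 / (1 + np.exp(-2 * logit))
        assert calibration_slope(p_over, y) == pytest.approx(0.5, abs=0.1)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(0.1, 0.9, 500)
        y = (rng.random(500) < p).astype(int)
        perm = rng.permutation(500)
        assert calibration_slope(p, y) == pytest.approx(
            calibration_slope(p[perm], y[perm]), rel=1e-8)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        p = rng.uniform(0.1, 0.9, 800)
        y = (rng.random(800) < p).astype(int)
        x = np.log(p / (1 - p))
        ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0).params[1]
        assert calibration_slope(p, y) == pytest.approx(ref, rel=1e-6)


class TestBrierScore:
    def test_perfect_predictions(self):
        assert brier_score([1.0, 0.0, 1.0], [1, 0, 1]) == 0.0

    def test_constant_half(self):
        assert brier_score([0.5] * 4, [0, 1, 0, 1]) == 0.25

    def test_hand_computed_five_pairs(self):
        p = [0.9, 0.3, 0.5, 0.8, 0.1]
        y = [1, 0, 1, 0, 0]
        hand = (0.01 + 0.09 + 0.25 + 0.64 + 0.01) / 5
        assert brier_score(p, y) == pytest.approx(hand)

    def test_calibrated_constant_predictor_decomposition(self):
        """Brier of a constant predictor at the true event rate p
        approaches p(1-p)."""
        rng = np.random.default_rng(10)
        p = 0.3
        y = rng.random(20_000) < p
        assert brier_score(np.full(20_000, p), y) == pytest.approx(
            p * (1 - p), abs=0.01)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_bounded_unit_interval(self, probs):
        y = [1] * len(probs)
        assert 0.0 <= brier_score(probs, y) <= 1.0


class TestMetricsReport:
    def test_full_panel_on_informative_score(self):
        rng = np.random.default_rng(13)
        n = 800
        p = rng.uniform(0.05, 0.9, n)
        y = (rng.random(n) < p).astype(int)
        rep = metrics_report(p, y, n_boot=200, seed=1)
        assert 0.5 < rep.auc <= 1.0
        assert rep.auc_ci[0] < rep.auc < rep.auc_ci[1]
        assert rep.brier is not None and rep.brier < 0.25
        assert rep.calibration_slope == pytest.approx(1.0, abs=0.2)

    def test_ordinal_score_skips_calibration(self):
        rng = np.random.default_rng(14)
        s = rng.integers(0, 9, 200).astype(float)
        y = (s + rng.normal(0, 3, 200) > 4).astype(int)
        rep = metrics_report(s, y, n_boot=100, seed=1)
        assert rep.brier is None
        assert rep.hosmer_lemeshow_chi2 is None
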