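"""ROC/Youden/DeLong, LOOCV, McNemar, group tests and regression."""

import numpy as np
import pytest
from scipy import stats as sps

from adc_texture.stats import (
    compare_aucs,
    confusion_metrics,
    group_tests,
    loocv_accuracy,
    mcnemar_test,
    pearson_regression,
    roc_analysis,
    youden_cutoff,
)


def auc_by_pair_counting(scores, labels):
    """Oracle: concordant pairs get 1, ties 0.5, discordant 0."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, bool)
    pos, neg = s[y], s[~y]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (pos.size * neg.size)


def youden_by_exhaustive_sweep(scores, labels, direction):
    """Oracle: evaluate every achievable threshold, return the best J."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, bool)
    best = -np.inf
    for t in np.concatenate([[s.min() - 1], np.unique(s)]):
        pred = s > t if direction == "higher" else s <= t
        sens = (pred & y).sum() / y.sum()
        spec = (~pred & ~y).sum() / (~y).sum()
        best = max(best, sens + spec - 1)
    return best


class TestROC:
    def test_perfect_separation(self):
        roc = roc_analysis([1, 2, 3, 4], [0, 0, 1, 1])
        assert roc.auc == 1.0
        assert roc.direction == "higher"

    def test_all_tied_scores(self):
        roc = roc_analysis([5, 5, 5, 5], [0, 1, 0, 1])
        assert roc.auc == 0.5

    def test_three_of_four_pairs_concordant(self):
        roc = roc_analysis([1, 3, 2, 4], [0, 0, 1, 1])
        assert roc.auc == 0.75

    def test_lower_direction_auto_detected(self):
        roc = roc_analysis([4, 3, 2, 1], [0, 0, 1, 1])
        assert roc.direction == "lower"
        assert roc.auc == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis([1, 2, 3], [1, 1, 1])

    @pytest.mark.parametrize("seed", range(6))
    def test_auc_equals_mann_whitney_pair_count(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 50))
        scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
        labels = rng.random(n) > 0.4
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        roc = roc_analysis(scores, labels, direction="higher")
        assert roc.auc == pytest.approx(auc_by_pair_counting(scores, labels), abs=1e-12)

    def test_ci_contains_auc_and_stays_in_unit_interval(self, rng):
        scores = rng.normal(size=30)
        labels = rng.random(30) > 0.5
        labels[:2] = [False, True]
        roc = roc_analysis(scores, labels)
        lo, hi = roc.auc_ci
        assert 0.0 <= lo <= roc.auc <= hi <= 1.0


class TestYouden:
    def test_perfect_separation_metrics(self):
        ev = youden_cutoff(roc_analysis([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1]))
        assert ev.sensitivity == 100.0
        assert ev.specificity == 100.0
        assert ev.youden == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_optimal_versus_exhaustive_search(self, seed):
        rng = np.random.default_rng(100 + seed)
        scores = np.round(rng.normal(size=25), 1)
        labels = rng.random(25) > 0.5
        labels[:2] = [False, True]
        roc = roc_analysis(scores, labels)
        ev = youden_cutoff(roc)
        assert ev.youden == pytest.approx(
            youden_by_exhaustive_sweep(scores, labels, roc.direction), abs=1e-12
        )

    def test_counts_consistent_with_metrics(self):
        ev = youden_cutoff(roc_analysis([1, 3, 2, 4, 2, 5], [0, 0, 0, 1, 1, 1]))
        sens, spec, acc = confusion_metrics(ev.tp, ev.fn, ev.tn, ev.fp)
        assert (ev.sensitivity, ev.specificity, ev.accuracy) == (sens, spec, acc)
        assert ev.tp + ev.fn == 3
        assert ev.tn + ev.fp == 3


class TestConfusionMetrics:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((25, 7, 7, 1), (78.1, 87.5, 80.0)),
            ((19, 13, 7, 1), (59.4, 87.5, 65.0)),
            ((18, 4, 9, 1), (81.8, 90.0, 84.4)),
            ((10, 0, 10, 0), (100.0, 100.0, 100.0)),
        ],
    )
    def test_rounded_percent_triplets(self, counts, expected):
        sens, spec, acc = confusion_metrics(*counts)
        assert round(sens, 1) == expected[0]
        assert round(spec, 1) == expected[1]
        assert round(acc, 1) == expected[2]

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(0, 0, 5, 5)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(-1, 2, 3, 4)


class TestCompareAUCs:
    def test_identical_scores_give_p_one(self):
        s = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        y = [0, 0, 0, 1, 1, 1]
        assert compare_aucs(s, s, y) == 1.0

    def test_p_in_unit_interval(self, rng):
        for _ in range(20):
            y = rng.random(15) > 0.5
            if y.all() or not y.any():
                continue
            p = compare_aucs(rng.normal(size=15), rng.normal(size=15), y)
            assert 0.0 <= p <= 1.0

    def test_agrees_with_paired_bootstrap_oracle(self):
        rng = np.random.default_rng(12345)
        n = 12
        y = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 1, 1], bool)
        a = np.array([1.0, 2.1, 0.7, 3.0, 1.5, 2.8, 3.4, 1.9, 4.0, 2.2, 3.7, 2.9])
        b = np.array([0.9, 1.2, 2.0, 1.1, 2.4, 2.6, 1.0, 3.1, 2.2, 3.3, 1.8, 2.7])
        d_obs = auc_by_pair_counting(a, y) - auc_by_pair_counting(b, y)
        diffs = []
        while len(diffs) < 10_000:
            idx = rng.integers(0, n, n)
            yy = y[idx]
            if yy.all() or not yy.any():
                continue
            diffs.append(auc_by_pair_counting(a[idx], yy) - auc_by_pair_counting(b[idx], yy))
        se = np.std(diffs, ddof=1)
        p_boot = 2 * sps.norm.sf(abs(d_obs) / se)
        p_delong = compare_aucs(a, b, y)
        assert p_delong == pytest.approx(p_boot, abs=0.05)

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(ValueError):
            compare_aucs([1, 2, 3], [1, 2], [0, 1, 1])


class TestLOOCV:
    def test_perfect_feature_fully_correct(self):
        res = loocv_accuracy([1, 2, 3, 10, 11, 12, 13], [0, 0, 0, 1, 1, 1, 1])
        assert res.accuracy == 100.0
        assert res.correct.all()

    def test_one_prediction_per_case(self, rng):
        x = rng.normal(size=17)
        y = rng.random(17) > 0.5
        y[:2] = [False, True]
        res = loocv_accuracy(x, y)
        assert res.predicted.shape == (17,)
        assert res.fold_cutoffs.shape == (17,)
        assert res.accuracy == pytest.approx(100.0 * res.correct.mean())

    def test_null_feature_accuracy_matches_simulated_chance(self):
        # A label-independent feature: LOOCV accuracy of the Youden-cutoff
        # classifier settles near the 50% balanced level, well below the 80%
        # majority rate of the 8/32 design (the Youden criterion optimizes
        # sensitivity+specificity, not raw accuracy).
        rng = np.random.default_rng(99)
        y = np.array([0] * 8 + [1] * 32, bool)
        accs = [loocv_accuracy(rng.normal(size=40), y).accuracy for _ in range(200)]
        mean = np.mean(accs)
        se = np.std(accs, ddof=1) / np.sqrt(len(accs))
        assert mean < 80.0 - 3 * se
        assert abs(mean - 52.0) < 6.0

    def test_degenerate_fold_predicts_majority(self):
        # removing the single negative leaves a one-class training fold
        res = loocv_accuracy([5.0, 1.0, 2.0, 3.0], [0, 1, 1, 1])
        assert res.degenerate_folds == 1
        assert res.predicted[0]  # majority class of the fold is positive


class TestMcNemar:
    def test_no_discordant_pairs(self):
        assert mcnemar_test([True, False, True], [True, False, True]) == 1.0

    def test_ten_zero_split_closed_form(self):
        a = [True] * 10 + [True] * 5
        b = [False] * 10 + [True] * 5
        assert mcnemar_test(a, b) == pytest.approx(2 * 0.5**10, rel=1e-9)

    def test_balanced_discordance_is_symmetric(self):
        a = [True, False] * 4
        b = [False, True] * 4
        assert mcnemar_test(a, b) == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mcnemar_test([True], [True, False])


class TestGroupTests:
    def test_identical_groups_give_t_zero(self):
        x = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        g = np.array(["low"] * 3 + ["high"] * 3)
        res = group_tests(x, g, low_classes=("low",))
        assert res.t_stat == pytest.approx(0.0, abs=1e-12)
        assert res.t_pvalue == pytest.approx(1.0)

    def test_two_group_anova_f_equals_t_squared(self, rng):
        x = rng.normal(size=14)
        g = np.array(["low"] * 6 + ["high"] * 8)
        res = group_tests(x, g, low_classes=("low",))
        assert res.f_stat == pytest.approx(res.t_stat**2, rel=1e-10)
        assert res.anova_pvalue == pytest.approx(res.t_pvalue, rel=1e-10)

    def test_three_group_f_matches_hand_sums_of_squares(self):
        groups = {"II": [1.0, 2.0, 3.0], "III": [2.0, 4.0, 6.0], "IV": [5.0, 7.0, 9.0]}
        x = np.concatenate(list(groups.values()))
        g = np.repeat(list(groups), 3)
        grand = x.mean()
        ssb = sum(3 * (np.mean(v) - grand) ** 2 for v in groups.values())
        ssw = sum(((np.asarray(v) - np.mean(v)) ** 2).sum() for v in groups.values())
        f_hand = (ssb / 2) / (ssw / 6)
        res = group_tests(x, g, low_classes=("II",))
        assert res.f_stat == pytest.approx(f_hand, rel=1e-12)

    def test_posthoc_gated_on_overall_anova(self):
        # clearly separated -> Tukey performed; pure noise w/ equal means -> not
        rng = np.random.default_rng(8)
        g = np.repeat(["II", "III", "IV"], 10)
        strong = np.concatenate([rng.normal(0, 1, 10), rng.normal(5, 1, 10),
                                 rng.normal(10, 1, 10)])
        res = group_tests(strong, g, low_classes=("II",))
        assert res.posthoc_performed
        assert set(res.posthoc_pvalues) == {("II", "III"), ("II", "IV"), ("III", "IV")}
        assert all(0 <= p <= 1 for p in res.posthoc_pvalues.values())
        x = np.tile([1.0, 2.0, 3.0, 2.0, 1.5, 2.5, 1.8, 2.2, 2.0, 1.9], 3)
        res_null = group_tests(x, g, low_classes=("II",))
        assert not res_null.posthoc_performed
        assert res_null.posthoc_pvalues is None

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValueError):
            group_tests([1.0, 2.0, 3.0], ["low", "low", "high"], low_classes=("low",))

    def test_welch_variant_differs_under_variance_heterogeneity(self, rng):
        x = np.concatenate([rng.normal(0, 0.5, 5), rng.normal(1, 5.0, 25)])
        g = np.array(["low"] * 5 + ["high"] * 25)
        pooled = group_tests(x, g, low_classes=("low",))
        welch = group_tests(x, g, low_classes=("low",), welch=True)
        assert pooled.t_pvalue != pytest.approx(welch.t_pvalue, rel=1e-6)


class TestPearsonRegression:
    def test_exact_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        res = pearson_regression(x, 2 * x + 1)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_orthogonal_response(self):
        x = np.array([-1.0, 0.0, 1.0])
        y = np.array([1.0, -2.0, 1.0])  # symmetric in x -> zero correlation
        res = pearson_regression(x, y)
        assert res.r_squared == pytest.approx(0.0, abs=1e-12)
        assert res.slope == pytest.approx(0.0, abs=1e-12)

    def test_matches_closed_form_on_five_points(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 7.0])
        sxx = ((x - x.mean()) ** 2).sum()
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        syy = ((y - y.mean()) ** 2).sum()
        res = pearson_regression(x, y)
        assert res.slope == pytest.approx(sxy / sxx, rel=1e-12)
        assert res.intercept == pytest.approx(y.mean() - sxy / sxx * x.mean(), rel=1e-12)
        assert res.r_squared == pytest.approx(sxy**2 / (sxx * syy), rel=1e-12)
        # p-value from the exact t distribution of the correlation
        r = sxy / np.sqrt(sxx * syy)
        t = r * np.sqrt(3 / (1 - r**2))
        assert res.pvalue == pytest.approx(2 * sps.t.sf(abs(t), df=3), rel=1e-9)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            pearson_regression([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
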