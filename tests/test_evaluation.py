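import numpy as np
import pytest
from scipy import stats

from mpapredict.ct_data import ResponseLabel, Severity
from mpapredict.evaluation import (
    ConfusionMatrix,
    accuracy,
    clopper_pearson,
    confusion_matrix,
    evaluation_report,
    sensitivity,
    specificity,
    stratified_accuracy,
)
from mpapredict.published import (
    PUBLISHED_STRATUM_COUNTS,
    published_confusion_matrix,
    published_validation_triples,
)

GOOD, POOR = ResponseLabel.GOOD, ResponseLabel.POOR


def brute_force_exact_ci(successes, trials, level=0.95, tol=1e-12):
    """Independent oracle: invert the binomial tail probabilities by
    bisection, with no reference to the beta distribution."""
    alpha = 1 - level

    def bisect(f, lo, hi):
        for _ in range(100):
            mid = (lo + hi) / 2
            if f(mid) > 0:
                lo = mid
            else:
                hi = mid
            if hi - lo < tol:
                break
        return (lo + hi) / 2

    if successes == 0:
        lower = 0.0
    else:
        # largest p with P(X >= s | p) <= alpha/2
        lower = bisect(
            lambda p: alpha / 2 - stats.binom.sf(successes - 1, trials, p), 0.0, 1.0
        )
    if successes == trials:
        upper = 1.0
    else:
        # smallest p with P(X <= s | p) <= alpha/2
        upper = bisect(
            lambda p: stats.binom.cdf(successes, trials, p) - alpha / 2, 0.0, 1.0
        )
    return lower, upper


class TestConfusionMatrix:
    def test_published_label_pairs(self):
        triples = published_validation_triples()
        cm = confusion_matrix([p for p, _, _ in triples], [a for _, a, _ in triples])
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (6, 1, 1, 31)
        assert cm.total == 39

    def test_all_correct_has_zero_off_diagonal(self):
        labels = [POOR, POOR, GOOD, GOOD]
        cm = confusion_matrix(labels, labels)
        assert cm.fp == cm.fn == 0
        assert cm.tp == 2 and cm.tn == 2

    def test_single_false_positive(self):
        cm = confusion_matrix([POOR], [GOOD])
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (0, 1, 0, 0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion_matrix([POOR], [GOOD, GOOD])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(tp=-1, fp=0, fn=0, tn=0)


class TestHeadlineStatistics:
    def test_published_sensitivity_specificity_accuracy(self):
        cm = published_confusion_matrix()
        assert round(100 * sensitivity(cm), 1) == 85.7  # 6/7
        assert round(100 * specificity(cm), 1) == 96.9  # 31/32
        assert round(100 * accuracy(cm), 1) == 94.9  # 37/39

    def test_zero_denominators_raise(self):
        no_poor = ConfusionMatrix(tp=0, fp=1, fn=0, tn=3)
        no_good = ConfusionMatrix(tp=2, fp=0, fn=1, tn=0)
        with pytest.raises(ZeroDivisionError):
            sensitivity(no_poor)
        with pytest.raises(ZeroDivisionError):
            specificity(no_good)

    def test_invariant_to_patient_permutation(self, rng):
        pred = [POOR if rng.random() < 0.3 else GOOD for _ in range(50)]
        act = [POOR if rng.random() < 0.3 else GOOD for _ in range(50)]
        if POOR not in act or GOOD not in act:
            act[0], act[1] = POOR, GOOD
        cm = confusion_matrix(pred, act)
        perm = rng.permutation(50)
        cm2 = confusion_matrix([pred[i] for i in perm], [act[i] for i in perm])
        assert cm == cm2


class TestClopperPearson:
    @pytest.mark.parametrize(
        "s, n, lower, upper",
        [(6, 7, 0.421, 0.996), (31, 32, 0.838, 0.999)],
    )
    def test_published_intervals_at_three_decimals(self, s, n, lower, upper):
        ci = clopper_pearson(s, n)
        assert round(ci.lower, 3) == lower
        assert round(ci.upper, 3) == upper

    def test_boundary_cases_are_exact(self):
        assert clopper_pearson(0, 10).lower == 0.0
        assert clopper_pearson(10, 10).upper == 1.0

    def test_matches_binomial_tail_inversion_oracle(self):
        for trials in (1, 5, 12, 27):
            for s in range(trials + 1):
                ci = clopper_pearson(s, trials)
                lo, hi = brute_force_exact_ci(s, trials)
                assert ci.lower == pytest.approx(lo, abs=1e-6)
                assert ci.upper == pytest.approx(hi, abs=1e-6)

    def test_matches_statsmodels_beta_interval(self):
        from statsmodels.stats.proportion import proportion_confint

        for s, n in [(3, 10), (6, 7), (31, 32), (0, 5), (5, 5)]:
            lo, hi = proportion_confint(s, n, alpha=0.05, method="beta")
            ci = clopper_pearson(s, n)
            assert ci.lower == pytest.approx(float(lo), abs=1e-10)
            assert ci.upper == pytest.approx(float(hi), abs=1e-10)

    def test_interval_contains_point_estimate(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 60))
            s = int(rng.integers(0, n + 1))
            ci = clopper_pearson(s, n)
            assert ci.lower <= s / n <= ci.upper

    def test_width_shrinks_with_trials(self):
        widths = []
        for n in (10, 20, 40, 80):
            ci = clopper_pearson(int(0.8 * n), n)
            widths.append(ci.upper - ci.lower)
        assert widths == sorted(widths, reverse=True)

    @pytest.mark.parametrize("s, n", [(-1, 5), (6, 5), (0, 0)])
    def test_out_of_range_rejected(self, s, n):
        with pytest.raises(ValueError):
            clopper_pearson(s, n)


class TestStratifiedAccuracy:
    def test_published_table(self):
        report = stratified_accuracy(published_validation_triples())
        assert round(100 * report.stratum(Severity.MILD).accuracy, 1) == 100.0
        assert round(100 * report.stratum(Severity.SEVERE).accuracy, 1) == 94.4
        assert round(100 * report.stratum(Severity.MOST_SEVERE).accuracy, 1) == 75.0
        assert round(100 * report.overall.accuracy, 1) == 94.9
        sizes = [s.matrix.total for s in report.strata]
        assert sizes == [17, 18, 4]
        assert report.overall.matrix.total == sum(sizes)

    def test_overall_accuracy_is_size_weighted_mean(self):
        report = stratified_accuracy(published_validation_triples())
        weighted = sum(s.accuracy * s.matrix.total for s in report.strata)
        assert report.overall.accuracy == pytest.approx(
            weighted / report.overall.matrix.total
        )

    def test_single_stratum_equals_overall(self):
        triples = [(POOR, POOR, Severity.SEVERE), (GOOD, GOOD, Severity.SEVERE)]
        report = stratified_accuracy(triples)
        assert len(report.strata) == 1
        assert report.strata[0].accuracy == report.overall.accuracy

    def test_missing_severity_names_patient(self):
        triples = [(GOOD, GOOD, Severity.MILD), (GOOD, GOOD, None)]
        with pytest.raises(ValueError, match="PT2"):
            stratified_accuracy(triples, patient_ids=["PT1", "PT2"])

    def test_report_bundle(self):
        bundle = evaluation_report(stratified_accuracy(published_validation_triples()))
        overall = bundle["overall"]
        assert overall["sensitivity_pct"] == 85.7
        assert overall["specificity_pct"] == 96.9
        assert overall["accuracy_pct"] == 94.9
        assert overall["sensitivity_ci"] == [0.421, 0.996]
        assert overall["specificity_ci"] == [0.838, 0.999]
        assert bundle["strata"]["mild"]["accuracy_pct"] == 100.0
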