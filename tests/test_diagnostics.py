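"""Diagnostic accuracy: confusion tables, CIs, ROC/AUC, Youden cut-off."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, stats

from pro55.diagnostics import (
    ConfusionTable,
    accuracy_metrics,
    auc_ci,
    best_tradeoff_cutoff,
    confusion_at_cutoff,
    delong_variance,
    proportion_ci,
    roc_curve,
)
from pro55.errors import ContractError, DegenerateDataError, InvalidInputError


class TestConfusion:
    def test_degenerate_cutoff_zero(self):
        scores = np.array([0.1, 0.5, 0.9, 0.3])
        labels = np.array([True, False, True, False])
        t = confusion_at_cutoff(scores, labels, 0.0)
        assert t.fn == 0 and t.tn == 0
        assert t.tp == 2 and t.fp == 2

    def test_score_equal_to_cutoff_is_negative(self):
        t = confusion_at_cutoff([0.3, 0.30001], [True, True], 0.3)
        assert t.fn == 1 and t.tp == 1

    def test_reference_cohort_cutoff_03(self, reference_cohort):
        scores, protein = reference_cohort
        t = confusion_at_cutoff(scores, protein < 1.0, 0.3)
        assert (t.tp, t.fn, t.fp, t.tn) == (30, 27, 29, 58)
        assert t.n == 144

    def test_counts_partition(self, reference_cohort):
        scores, protein = reference_cohort
        for cut in (0.3, 0.5, 0.7):
            t = confusion_at_cutoff(scores, protein < 0.8, cut)
            assert t.n == 144
            assert t.n_positive == 25 and t.n_negative == 119

    def test_length_mismatch(self):
        with pytest.raises(ContractError):
            confusion_at_cutoff([0.1, 0.2], [True], 0.3)

    def test_score_outside_unit_interval(self):
        with pytest.raises(InvalidInputError):
            confusion_at_cutoff([1.2], [True], 0.3)


class TestAccuracyMetrics:
    def test_sensitivity_specificity_values(self):
        m = accuracy_metrics(ConfusionTable(tp=30, fp=29, fn=27, tn=58))
        assert round(100 * m["sensitivity"].estimate, 1) == 52.6
        assert round(100 * m["specificity"].estimate, 1) == 66.7
        m2 = accuracy_metrics(ConfusionTable(tp=19, fp=14, fn=38, tn=73))
        assert round(100 * m2["specificity"].estimate, 1) == 83.9

    def test_perfect_sensitivity_ci_reaches_one(self):
        m = accuracy_metrics(ConfusionTable(tp=20, fp=5, fn=0, tn=10))
        assert m["sensitivity"].estimate == 1.0
        assert m["sensitivity"].ci_high == 1.0

    def test_zero_denominator_is_undefined(self):
        m = accuracy_metrics(ConfusionTable(tp=0, fp=0, fn=5, tn=10))
        assert not m["ppv"].defined
        assert np.isnan(m["ppv"].estimate)


class TestProportionCI:
    def test_boundaries(self):
        low, high = proportion_ci(0, 10)
        assert low == 0.0
        low, high = proportion_ci(10, 10)
        assert high == 1.0

    def test_wilson_symmetry(self):
        # k <-> n-k symmetry; at k = n/2 the interval is self-symmetric
        low, high = proportion_ci(5, 10, method="wilson")
        assert low == pytest.approx(1 - high)
        low37, high37 = proportion_ci(3, 10, method="wilson")
        low73, high73 = proportion_ci(7, 10, method="wilson")
        assert low37 == pytest.approx(1 - high73)
        assert high37 == pytest.approx(1 - low73)

    def test_clopper_pearson_matches_tail_inversion(self):
        """Oracle: invert the exact binomial tails by root finding."""
        k, n, alpha = 30, 57, 0.05
        low, high = proportion_ci(k, n, method="clopper_pearson")
        f_low = lambda p: stats.binom.sf(k - 1, n, p) - alpha / 2
        f_high = lambda p: stats.binom.cdf(k, n, p) - alpha / 2
        assert low == pytest.approx(optimize.brentq(f_low, 1e-12, 1 - 1e-12), abs=1e-9)
        assert high == pytest.approx(optimize.brentq(f_high, 1e-12, 1 - 1e-12), abs=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(InvalidInputError):
            proportion_ci(5, 0)
        with pytest.raises(InvalidInputError):
            proportion_ci(11, 10)

    def test_exact_coverage_at_least_nominal(self):
        """Clopper-Pearson coverage >= 95%, computed exactly from the pmf."""
        for n in (25, 57, 119):
            ks = np.arange(n + 1)
            bounds = np.array([proportion_ci(k, n) for k in ks])
            for p in np.arange(0.1, 0.91, 0.1):
                covered = (bounds[:, 0] <= p) & (p <= bounds[:, 1])
                coverage = stats.binom.pmf(ks[covered], n, p).sum()
                assert coverage >= 0.95


class TestRoc:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([True, True, False, False])
        roc = roc_curve(scores, labels)
        assert roc.auc == pytest.approx(1.0)
        c, sens, spec = best_tradeoff_cutoff(roc)
        assert sens == 1.0 and spec == 1.0

    def test_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(5)
        scores = rng.random(60)
        labels = rng.random(60) < 0.4
        roc = roc_curve(scores, labels)
        assert (roc.fpr[0], roc.tpr[0]) == (0.0, 0.0)
        assert (roc.fpr[-1], roc.tpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(roc.tpr) >= 0) and np.all(np.diff(roc.fpr) >= 0)

    def test_null_coupling_auc_near_half(self):
        rng = np.random.default_rng(11)
        scores = rng.random(20_000)
        labels = rng.random(20_000) < 0.4
        assert roc_curve(scores, labels).auc == pytest.approx(0.5, abs=0.02)

    def test_label_inversion_symmetry(self):
        rng = np.random.default_rng(2)
        scores = rng.random(300)
        labels = rng.random(300) < scores
        a = roc_curve(scores, labels).auc
        b = roc_curve(scores, ~labels).auc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_single_class_errors(self):
        with pytest.raises(DegenerateDataError):
            roc_curve([0.1, 0.2], [True, True])

    @given(st.data())
    @settings(max_examples=120, deadline=None)
    def test_auc_equals_mann_whitney_with_ties(self, data):
        """Trapezoidal AUC == Mann-Whitney statistic (ties count half)."""
        n = data.draw(st.integers(4, 30))
        # coarse grid forces heavy ties
        scores = np.array(
            data.draw(st.lists(st.sampled_from([0.0, 0.25, 0.5, 0.75, 1.0]),
                               min_size=n, max_size=n))
        )
        labels = np.array(data.draw(st.lists(st.booleans(), min_size=n, max_size=n)))
        if labels.all() or not labels.any():
            return
        auc = roc_curve(scores, labels).auc
        u = stats.mannwhitneyu(scores[labels], scores[~labels],
                               use_continuity=False).statistic
        mw = u / (labels.sum() * (~labels).sum())
        assert auc == pytest.approx(mw, abs=1e-12)

    def test_matches_sklearn(self):
        sk = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(3)
        scores = np.round(rng.random(500), 2)
        labels = rng.random(500) < scores
        assert roc_curve(scores, labels).auc == pytest.approx(
            sk.roc_auc_score(labels, scores), abs=1e-12
        )


class TestAucCI:
    def test_delong_matches_bruteforce_placements(self):
        """Oracle: O(m*n) double-loop placement values."""
        rng = np.random.default_rng(8)
        scores = np.round(rng.random(40), 1)  # ties included
        labels = rng.random(40) < 0.45
        auc, var = delong_variance(scores, labels)
        pos, neg = scores[labels], scores[~labels]
        v10 = np.array([np.mean((x > neg) + 0.5 * (x == neg)) for x in pos])
        v01 = np.array([np.mean((pos > x) + 0.5 * (pos == x)) for x in neg])
        assert auc == pytest.approx(v10.mean(), abs=1e-12)
        expected = np.var(v10, ddof=1) / len(pos) + np.var(v01, ddof=1) / len(neg)
        assert var == pytest.approx(expected, abs=1e-12)

    def test_interval_covers_point_estimate(self):
        rng = np.random.default_rng(9)
        scores = rng.random(200)
        labels = rng.random(200) < 0.5
        low, high = auc_ci(scores, labels)
        auc = roc_curve(scores, labels).auc
        assert low <= auc <= high
        assert low <= 0.5 <= high  # independent labels: interval covers chance

    def test_duplication_narrows_interval(self):
        rng = np.random.default_rng(10)
        scores = rng.random(80)
        labels = rng.random(80) < scores
        low1, high1 = auc_ci(scores, labels)
        low2, high2 = auc_ci(np.tile(scores, 2), np.tile(labels, 2))
        assert (high2 - low2) < (high1 - low1)

    def test_hanley_mcneil_alternative_runs(self):
        rng = np.random.default_rng(12)
        scores = rng.random(100)
        labels = rng.random(100) < scores
        low, high = auc_ci(scores, labels, method="hanley_mcneil")
        assert 0.0 <= low < high <= 1.0


class TestYouden:
    def test_best_of_three_printed_cutoffs(self, reference_cohort):
        """Among the reported cut-offs 0.3/0.5/0.7, 0.3 maximises J."""
        scores, protein = reference_cohort
        labels = protein < 1.0
        js = {}
        for cut in (0.3, 0.5, 0.7):
            t = confusion_at_cutoff(scores, labels, cut)
            js[cut] = t.tp / t.n_positive + t.tn / t.n_negative - 1
        assert max(js, key=js.get) == 0.3

    def test_tie_broken_toward_lower_cutoff(self):
        # two cut-offs with identical J = 0.5: pick the more sensitive one
        scores = np.array([0.9, 0.6, 0.4, 0.1])
        labels = np.array([True, True, False, False])
        roc = roc_curve(scores, labels)
        cut, sens, spec = best_tradeoff_cutoff(roc)
        ties = [
            (c, t - f)
            for c, t, f in roc.operating_points
            if np.isfinite(c)
        ]
        best_j = max(j for _, j in ties)
        tied_cuts = [c for c, j in ties if j == pytest.approx(best_j)]
        assert cut == min(tied_cuts)
        assert sens >= spec or sens == 1.0  # lower cut-off favours sensitivity
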