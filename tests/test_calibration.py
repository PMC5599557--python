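"""Platt scaling, confusion statistics and cautious classification."""

import numpy as np
import pytest

from oncosnv.calibrate import (
    CautiousCurve,
    ConfusionCounts,
    auc,
    cautious_curve,
    compute_metrics,
    confusion_at_threshold,
    fit_platt,
    select_cautious_threshold,
)


class TestPlatt:
    def test_separated_scores_monotone_crossing_half(self):
        s = np.concatenate([np.random.default_rng(0).normal(-2, 0.3, 50),
                            np.random.default_rng(1).normal(2, 0.3, 50)])
        y = np.array([0] * 50 + [1] * 50)
        model = fit_platt(s, y)
        assert model.A < 0
        p = model(np.sort(s))
        assert np.all(np.diff(p) >= 0)
        assert model(np.array([-2]))[0] < 0.5 < model(np.array([2]))[0]

    def test_symmetric_scores_give_half_at_zero(self):
        rng = np.random.default_rng(5)
        pos = rng.normal(1, 1, 2000)
        s = np.concatenate([pos, -pos])
        y = np.array([1] * 2000 + [0] * 2000)
        model = fit_platt(s, y)
        assert abs(model(np.array([0.0]))[0] - 0.5) < 1e-6

    def test_parameter_recovery(self):
        # scores scored through a known sigmoid A*=-2, B*=0
        rng = np.random.default_rng(123)
        s = rng.normal(0, 2, 10_000)
        p_true = 1 / (1 + np.exp(-2.0 * s))  # p(s) = 1/(1+exp(A*s+B)), A=-2, B=0
        y = (rng.random(10_000) < p_true).astype(int)
        model = fit_platt(s, y)
        assert abs(model.A - (-2.0)) <= 0.1

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            fit_platt([1.0, 2.0], [1, 1])

    def test_order_preservation_and_auc_invariance(self):
        rng = np.random.default_rng(2)
        s = rng.normal(0, 1, 500)
        y = (rng.random(500) < 1 / (1 + np.exp(-s))).astype(int)
        model = fit_platt(s, y)
        p = model(s)
        assert np.array_equal(np.argsort(s, kind="stable"), np.argsort(p, kind="stable"))
        assert np.isclose(auc(s, y), auc(p, y))


class TestConfusion:
    p = np.array([0.95, 0.60, 0.05, 0.40])
    y = np.array([1, 1, 0, 0])

    def test_default_threshold(self):
        c = confusion_at_threshold(self.p, self.y, 0.5)
        assert (c.TP, c.FP, c.TN, c.FN) == (2, 0, 2, 0)
        assert c.coverage == 1.0

    def test_cautious_threshold_abstains(self):
        c = confusion_at_threshold(self.p, self.y, 0.9)
        assert (c.TP, c.FP, c.TN, c.FN) == (1, 0, 1, 0)
        assert c.coverage == 0.5

    def test_tau_one_zero_coverage(self):
        c = confusion_at_threshold(np.array([0.9, 0.1]), np.array([1, 0]), 1.0)
        assert c.n_predicted == 0 and c.coverage == 0.0

    def test_exact_half_counts_positive_at_default(self):
        c = confusion_at_threshold(np.array([0.5]), np.array([1]), 0.5)
        assert c.TP == 1


# published confusion-count rows: counts -> (sens, spec, balacc, MCC, PPV) at 2 dp.
# Note the cautious coding row's sensitivity: 3398/3522 = 0.9648 -> 0.96;
# the source table prints 0.97, inconsistent with its own counts.  The
# count-derived value is asserted here.
TABLE_ROWS = [
    ((48_079, 30_902, 36_363, 20_432), (0.70, 0.54, 0.62, 0.25, 0.61)),
    ((6_512, 1_859, 13_044, 3_544), (0.65, 0.88, 0.76, 0.54, 0.78)),
    ((10_333, 3_992, 13_297, 4_631), (0.69, 0.77, 0.73, 0.46, 0.72)),
    ((3_398, 197, 1_319, 124), (0.96, 0.87, 0.92, 0.85, 0.95)),
]


class TestMetrics:
    @pytest.mark.parametrize("counts,expected", TABLE_ROWS)
    def test_published_confusion_rows(self, counts, expected):
        m = compute_metrics(ConfusionCounts(*counts))
        got = (m.sensitivity, m.specificity, m.balanced_accuracy, m.MCC, m.PPV)
        assert tuple(round(g, 2) for g in got) == expected

    def test_cautious_coding_peak_value(self):
        m = compute_metrics(ConfusionCounts(3_398, 197, 1_319, 124))
        assert round(100 * m.balanced_accuracy, 2) == 91.74

    def test_perfect_classifier(self):
        m = compute_metrics(ConfusionCounts(10, 0, 10, 0))
        assert (m.sensitivity, m.specificity, m.balanced_accuracy, m.MCC, m.PPV) \
            == (1.0, 1.0, 1.0, 1.0, 1.0)

    def test_degenerate_denominators_flagged(self):
        m = compute_metrics(ConfusionCounts(0, 0, 5, 3))
        assert m.PPV == 0.0 and "PPV" in m.degenerate

    def test_mcc_matches_correlation_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            tp, fp, tn, fn = rng.integers(0, 30, 4)
            if min(tp + fp, tp + fn, tn + fp, tn + fn) == 0:
                continue
            truth = np.array([1] * (tp + fn) + [0] * (tn + fp))
            pred = np.array([1] * tp + [0] * fn + [0] * tn + [1] * fp)
            oracle = np.corrcoef(pred, truth)[0, 1]
            m = compute_metrics(ConfusionCounts(int(tp), int(fp), int(tn), int(fn)))
            assert np.isclose(m.MCC, oracle, atol=1e-12)


class TestAUC:
    def test_perfect_and_uninformative(self):
        assert auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0
        assert auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_pair_counting_example(self):
        assert auc([0.9, 0.7, 0.6, 0.2], [1, 0, 1, 0]) == 0.75

    def test_matches_brute_force_pairs(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = int(rng.integers(4, 15))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            p = np.round(rng.random(n), 2)  # force ties sometimes
            wins = sum((1.0 if pi > pj else 0.5 if pi == pj else 0.0)
                       for pi, yi in zip(p, y) if yi == 1
                       for pj, yj in zip(p, y) if yj == 0)
            oracle = wins / (y.sum() * (n - y.sum()))
            assert np.isclose(auc(p, y), oracle)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.9], [1, 1])


class TestCautiousCurve:
    def test_default_entry_equals_uncautious_metrics(self):
        p = np.array([0.95, 0.6, 0.05, 0.4])
        y = np.array([1, 1, 0, 0])
        curve = cautious_curve(p, y)
        c = confusion_at_threshold(p, y, 0.5)
        assert curve.balanced_accuracy[0] == compute_metrics(c).balanced_accuracy
        assert curve.coverage[0] == 1.0

    def test_coverage_non_increasing(self):
        rng = np.random.default_rng(3)
        p = rng.random(500)
        y = rng.integers(0, 2, 500)
        curve = cautious_curve(p, y)
        assert np.all(np.diff(curve.coverage) <= 1e-12)

    def test_bimodal_pscores_improve_with_caution(self):
        rng = np.random.default_rng(4)
        n = 2000
        # well-separated beta mixture with an overlapping fraction
        p_pos = np.where(rng.random(n) < 0.8, rng.beta(8, 2, n), rng.random(n))
        p_neg = np.where(rng.random(n) < 0.8, rng.beta(2, 8, n), rng.random(n))
        p = np.concatenate([p_pos, p_neg])
        y = np.array([1] * n + [0] * n)
        curve = cautious_curve(p, y)
        hi = curve.defined & (curve.tau_grid >= 0.85)
        assert np.nanmax(curve.balanced_accuracy[hi]) > curve.balanced_accuracy[0]

    def test_self_consistency_with_direct_computation(self):
        rng = np.random.default_rng(6)
        p = rng.random(200)
        y = rng.integers(0, 2, 200)
        curve = cautious_curve(p, y)
        for i in (0, 10, 25):
            if not curve.defined[i]:
                continue
            direct = compute_metrics(confusion_at_threshold(p, y, curve.tau_grid[i]))
            assert curve.balanced_accuracy[i] == direct.balanced_accuracy


class TestThresholdSelection:
    def make_curve(self, taus, accs, cov=None):
        taus = np.asarray(taus, dtype=float)
        accs = np.asarray(accs, dtype=float)
        cov = np.ones_like(taus) if cov is None else np.asarray(cov, dtype=float)
        return CautiousCurve(taus, accs, cov, np.ones_like(taus, dtype=bool))

    def test_lower_of_two_comparable_peaks(self):
        curve = self.make_curve([0.5, 0.7, 0.75, 0.81], [0.70, 0.76, 0.73, 0.762])
        assert select_cautious_threshold(curve, min_coverage=0.0) == 0.7

    def test_unimodal_argmax(self):
        curve = self.make_curve([0.5, 0.6, 0.7, 0.8], [0.6, 0.7, 0.8, 0.75])
        assert select_cautious_threshold(curve, min_coverage=0.0) == 0.7

    def test_flat_curve_returns_smallest_tau(self):
        curve = self.make_curve([0.5, 0.6, 0.7], [0.7, 0.7, 0.7])
        assert select_cautious_threshold(curve, min_coverage=0.0) == 0.5

    def test_min_coverage_excludes_entries(self):
        curve = self.make_curve([0.5, 0.7, 0.9], [0.6, 0.7, 0.99], cov=[1.0, 0.5, 0.01])
        assert select_cautious_threshold(curve, min_coverage=0.05) == 0.7

    def test_no_qualifying_entry_errors(self):
        curve = self.make_curve([0.5], [0.6], cov=[0.0])
        with pytest.raises(ValueError):
            select_cautious_threshold(curve, min_coverage=0.05)
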