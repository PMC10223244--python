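"""Metrics, exact tests, aggregation, applicability domain."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mtqsar import (
    ConfusionCounts,
    MetricsReport,
    aggregate_report,
    binomial_significance,
    confusion,
    f_metrics,
    fisher_significance,
    fit_applicability_domain,
    in_domain,
    mcc,
    roc_auc,
)


class TestConfusion:
    def test_perfect(self):
        c = confusion([1, 1, 0, 0], [1, 1, 0, 0])
        assert (c.tp, c.tn, c.fp, c.fn) == (2, 2, 0, 0)

    def test_all_positive_predictions(self):
        c = confusion([1, 1, 1, 1], [1, 0, 1, 0])
        assert (c.tp, c.fp) == (2, 2)

    def test_undefined_counted_separately(self):
        c = confusion([1, None, 0, 1, 0], [1, 1, 0, 0, 0])
        assert c.n_undefined == 1
        assert c.n_defined == 4
        assert (c.tp, c.tn, c.fp, c.fn) == (1, 2, 1, 0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion([1, 0], [1])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1)


class TestFMetrics:
    def test_perfect_imbalanced_split(self):
        c = ConfusionCounts(tp=30, tn=156)
        assert f_metrics(c) == (100.0, 100.0, 100.0)

    def test_arithmetic(self):
        f0, fa, fn = f_metrics(ConfusionCounts(tp=9, fn=1, tn=90, fp=0))
        assert (round(f0, 1), fa, fn) == (99.0, 90.0, 100.0)

    def test_empty_positive_class_is_undefined_not_zero(self):
        f0, fa, fn = f_metrics(ConfusionCounts(tn=10, fp=2))
        assert fa is None and fn is not None

    def test_f0_between_fa_and_fn(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            tp, fp, tn, fn = rng.integers(1, 50, size=4)
            f0, fa, fnn = f_metrics(ConfusionCounts(int(tp), int(fp), int(tn), int(fn)))
            assert min(fa, fnn) - 1e-9 <= f0 <= max(fa, fnn) + 1e-9


class TestRocAuc:
    def test_binary_verdicts_reduce_to_balanced_accuracy(self):
        rng = np.random.default_rng(1)
        truth = rng.integers(0, 2, size=200)
        pred = np.where(rng.random(200) < 0.8, truth, 1 - truth)
        c = confusion(list(pred), list(truth))
        _, fa, fn = f_metrics(c)
        assert roc_auc(list(pred), list(truth)) == pytest.approx((fa + fn) / 2, abs=1e-9)

    def test_pairwise_comparison_oracle(self):
        # AUC = P(score_pos > score_neg) + 0.5 P(tie), by brute force
        rng = np.random.default_rng(2)
        truth = rng.integers(0, 2, size=40)
        scores = np.round(rng.normal(truth.astype(float), 1.0), 1)  # forces ties
        pos = scores[truth == 1]
        neg = scores[truth == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        expected = 100.0 * wins / (len(pos) * len(neg))
        assert roc_auc(list(scores), list(truth)) == pytest.approx(expected, abs=1e-9)

    def test_perfect_separation(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 100.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(3)
        truth = rng.integers(0, 2, size=4000)
        scores = rng.random(4000)
        assert abs(roc_auc(list(scores), list(truth)) - 50.0) < 3.0

    def test_single_class_undefined(self):
        assert roc_auc([0.1, 0.9], [1, 1]) is None


class TestMcc:
    def test_perfect_and_inverted(self):
        assert mcc(ConfusionCounts(tp=5, tn=5)) == 1.0
        assert mcc(ConfusionCounts(fp=5, fn=5)) == -1.0

    def test_direct_formula(self):
        assert mcc(ConfusionCounts(tp=45, fp=5, fn=5, tn=45)) == pytest.approx(0.8)

    def test_zero_marginal_gives_zero(self):
        assert mcc(ConfusionCounts(tp=10, fp=5)) == 0.0

    def test_sign_flips_on_inversion_and_bounded(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            tp, fp, tn, fn = (int(v) for v in rng.integers(1, 30, size=4))
            m = mcc(ConfusionCounts(tp, fp, tn, fn))
            m_inv = mcc(ConfusionCounts(fn, tn, fp, tp))
            assert m == pytest.approx(-m_inv)
            assert abs(m) <= 1.0

    def test_matches_sklearn(self):
        from sklearn.metrics import matthews_corrcoef

        rng = np.random.default_rng(5)
        truth = rng.integers(0, 2, size=100)
        pred = np.where(rng.random(100) < 0.7, truth, 1 - truth)
        ours = mcc(confusion(list(pred), list(truth)))
        assert ours == pytest.approx(matthews_corrcoef(truth, pred))


class TestExactTests:
    def test_binomial_all_correct(self):
        assert binomial_significance(10, 10) == pytest.approx(2.0 ** -10)

    def test_binomial_none_correct(self):
        assert binomial_significance(0, 12) == 1.0

    def test_binomial_at_null_mean(self):
        assert binomial_significance(500, 1000) == pytest.approx(0.5, abs=0.02)

    def test_binomial_closed_form_oracle(self):
        n, k, p0 = 20, 14, 0.5
        expected = sum(math.comb(n, i) * p0**i * (1 - p0) ** (n - i) for i in range(k, n + 1))
        assert binomial_significance(k, n, p0) == pytest.approx(expected)

    def test_binomial_invalid_counts(self):
        with pytest.raises(ValueError):
            binomial_significance(11, 10)

    def test_fisher_diagonal_closed_form(self):
        # both margins 10/10: only the two perfect tables are as extreme
        p = fisher_significance(ConfusionCounts(tp=10, tn=10))
        assert p == pytest.approx(2.0 / math.comb(20, 10))

    def test_fisher_uniform_table(self):
        assert fisher_significance(ConfusionCounts(5, 5, 5, 5)) == 1.0

    def test_fisher_transpose_symmetry(self):
        a = fisher_significance(ConfusionCounts(tp=8, fp=2, fn=3, tn=9))
        b = fisher_significance(ConfusionCounts(tp=8, fp=3, fn=2, tn=9))  # transposed
        assert a == pytest.approx(b)


class TestAggregateReport:
    def test_single_row_identity(self):
        r = MetricsReport(f0=94.9, fa=90.0, fn=95.7, roc=91.5)
        agg = aggregate_report([r])
        assert (agg.f0, agg.fa, agg.fn, agg.roc) == (94.9, 90.0, 95.7, 91.5)

    def test_mean_rounds_half_up(self):
        rows = [MetricsReport(f0=v) for v in (100.0, 97.2, 99.5)]
        assert aggregate_report(rows).f0 == 98.9

    def test_none_columns_skipped(self):
        rows = [MetricsReport(f0=90.0, fa=None), MetricsReport(f0=92.0, fa=None)]
        agg = aggregate_report(rows)
        assert agg.f0 == 91.0 and agg.fa is None

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_report([])


class TestApplicabilityDomain:
    def test_hand_computed_bounds(self):
        x = np.array([[-1.0], [-2.0], [-3.0]])
        b = fit_applicability_domain(x, ["S1"])
        assert b.lower[0] == pytest.approx(-5.0)  # mean -2, sample sd 1
        assert b.upper[0] == pytest.approx(1.0)
        assert (b.global_min, b.global_max) == (pytest.approx(-5.0), pytest.approx(1.0))

    def test_constant_column_zero_band(self):
        x = np.full((4, 1), -7.3)
        b = fit_applicability_domain(x, ["S1"])
        assert b.lower[0] == b.upper[0] == pytest.approx(-7.3)

    def test_global_extrema_over_sites(self):
        rng = np.random.default_rng(6)
        x = np.column_stack([rng.normal(-9, 0.5, 30), rng.normal(-3, 2.0, 30)])
        b = fit_applicability_domain(x, ["S1", "S2"])
        assert b.global_min == pytest.approx(min(b.lower))
        assert b.global_max == pytest.approx(max(b.upper))

    def test_fewer_than_two_rows_rejected(self):
        with pytest.raises(ValueError):
            fit_applicability_domain(np.array([[-5.0, -6.0]]), ["S1", "S2"])

    def test_training_values_inside_global_range(self):
        # holds for samples without >3-sigma outliers (small n keeps that true)
        rng = np.random.default_rng(7)
        x = rng.normal(-6, 1, size=(30, 3))
        b = fit_applicability_domain(x, [f"S{j}" for j in range(3)])
        assert x.min() >= b.global_min and x.max() <= b.global_max

    def test_global_vs_per_site_modes(self):
        x = np.column_stack([np.linspace(-10, -9, 10), np.linspace(-3, -2, 10)])
        b = fit_applicability_domain(x, ["S1", "S2"])
        # inside the pooled global range but outside S1's own band
        probe = np.array([-3.0, -2.5])
        assert in_domain(probe, b, mode="global") is True
        assert in_domain(probe, b, mode="per_site") is False

    def test_site_means_in_domain(self):
        rng = np.random.default_rng(8)
        x = rng.normal(-6, 1, size=(50, 3))
        b = fit_applicability_domain(x, ["S1", "S2", "S3"])
        assert in_domain(x.mean(axis=0), b, mode="per_site") is True

    def test_below_global_min_out(self):
        x = np.random.default_rng(9).normal(-6, 1, size=(50, 3))
        b = fit_applicability_domain(x, ["S1", "S2", "S3"])
        probe = np.array([b.global_min - 1.0, -6.0, -6.0])
        assert in_domain(probe, b, mode="global") is False


@settings(max_examples=50, deadline=None)
@given(
    tp=st.integers(0, 40), fp=st.integers(0, 40),
    tn=st.integers(0, 40), fn=st.integers(0, 40),
)
def test_mcc_bounded_property(tp, fp, tn, fn):
    assert abs(mcc(ConfusionCounts(tp, fp, tn, fn))) <= 1.0 + 1e-12
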