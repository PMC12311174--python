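"""Diagnostic metrics against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fusemil.evaluation import (aggregate_folds, confusion_at_threshold,
                                probability_histogram, stratified_report,
                                summary_metrics, tradeoff_curve)


def pair_count_auc(scores, labels):
    """Exhaustive positive-negative pair counting, ties counted 1/2."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestConfusion:
    def test_basic_counts(self):
        assert confusion_at_threshold([0.6, 0.4], [1, 0], 0.5) == (1, 0, 1, 0)

    def test_threshold_zero_all_positive(self):
        tp, fp, tn, fn = confusion_at_threshold([0.2, 0.8, 0.5], [1, 0, 1], 0.0)
        assert (tp, fp, tn, fn) == (2, 1, 0, 0)

    def test_threshold_above_max_all_negative(self):
        tp, fp, tn, fn = confusion_at_threshold([0.2, 0.8], [1, 0], 0.81)
        assert (tp, fp, tn, fn) == (0, 0, 1, 1)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_at_threshold([0.5], [1, 0])


class TestSummaryMetrics:
    def test_hand_example_auc_half(self):
        rep = summary_metrics([0.9, 0.8, 0.3], [1, 0, 1])
        assert rep.roc_auc == pytest.approx(0.5)

    def test_perfect_separation(self):
        rep = summary_metrics([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0], t=0.5)
        assert rep.roc_auc == 1.0 and rep.ppa == 1.0 and rep.npa == 1.0
        assert rep.f1 == 1.0 and rep.accuracy == 1.0

    def test_identities_hold(self, rng):
        scores = rng.random(40)
        labels = rng.integers(0, 2, size=40)
        labels[0], labels[1] = 0, 1
        rep = summary_metrics(scores, labels, t=0.4)
        assert rep.ppa == pytest.approx(rep.tp / max(rep.tp + rep.fn, 1))
        assert rep.npa == pytest.approx(rep.tn / max(rep.tn + rep.fp, 1))
        if rep.ppv + rep.ppa > 0:
            assert rep.f1 == pytest.approx(
                2 * rep.ppv * rep.ppa / (rep.ppv + rep.ppa))
        assert rep.tp + rep.fp + rep.tn + rep.fn == rep.n

    def test_single_class_flags_undefined_auc(self):
        rep = summary_metrics([0.2, 0.7], [1, 1])
        assert not rep.auc_defined and np.isnan(rep.roc_auc)

    @settings(derandomize=True, deadline=None, max_examples=40)
    @given(st.integers(0, 10_000))
    def test_auc_equals_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 50))
        scores = np.round(rng.random(n), 2)      # force some ties
        labels = rng.integers(0, 2, size=n)
        labels[:2] = [0, 1]
        rep = summary_metrics(scores, labels)
        assert rep.roc_auc == pytest.approx(pair_count_auc(scores, labels), abs=1e-12)

    def test_auc_invariant_to_monotone_transform(self, rng):
        scores = rng.random(30)
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]
        a1 = summary_metrics(scores, labels).roc_auc
        a2 = summary_metrics(np.exp(3 * scores), labels).roc_auc
        assert a1 == pytest.approx(a2)


class TestTradeoff:
    def test_boundary_behaviour(self, rng):
        scores = rng.random(50)
        labels = rng.integers(0, 2, size=50)
        labels[:2] = [0, 1]
        curve = tradeoff_curve(scores, labels)
        prevalence = labels.mean()
        assert curve.ppa[0] == 1.0 and curve.tn_rate[0] == 0.0 and curve.fn_rate[0] == 0.0
        assert curve.fn_rate[-1] == pytest.approx(prevalence)
        assert curve.tn_rate[-1] == pytest.approx(1 - prevalence)
        assert curve.ppa[-1] == 0.0

    def test_rates_monotone_in_threshold(self, rng):
        scores = rng.random(80)
        labels = rng.integers(0, 2, size=80)
        labels[:2] = [0, 1]
        curve = tradeoff_curve(scores, labels)
        assert (np.diff(curve.fn_rate) >= 0).all()
        assert (np.diff(curve.tn_rate) >= 0).all()

    def test_fn_rate_consistent_with_ppa(self, rng):
        """FN/n = prevalence * (1 - PPA) at every threshold."""
        scores = rng.random(60)
        labels = rng.integers(0, 2, size=60)
        labels[:2] = [0, 1]
        curve = tradeoff_curve(scores, labels)
        prevalence = labels.mean()
        assert np.allclose(curve.fn_rate, prevalence * (1 - curve.ppa))


class TestHistogram:
    def test_masses_normalized(self, rng):
        scores = rng.random(100)
        labels = rng.integers(0, 2, size=100)
        edges, h0, h1 = probability_histogram(scores, labels, bins=13)
        assert edges[0] == 0.0 and edges[-1] == 1.0
        assert h0.sum() == pytest.approx(1.0, abs=1e-9)
        assert h1.sum() == pytest.approx(1.0, abs=1e-9)

    def test_single_bin_and_empty_class(self):
        edges, h0, h1 = probability_histogram([0.5, 0.5], [0, 0], bins=4)
        assert h0[2] == 1.0
        assert h1.sum() == 0.0


class TestAggregate:
    def test_mean_and_sd(self):
        r1 = summary_metrics([0.9, 0.1], [1, 0])
        r2 = summary_metrics([0.8, 0.4], [1, 0])
        r1.roc_auc, r2.roc_auc = 0.8, 0.9
        agg = aggregate_folds([r1, r2])
        assert agg["roc_auc"]["mean"] == pytest.approx(0.85)
        assert agg["roc_auc"]["sd"] == pytest.approx(np.std([0.8, 0.9], ddof=1))

    def test_identical_reports_zero_sd(self):
        r = summary_metrics([0.9, 0.1], [1, 0])
        assert aggregate_folds([r, r, r])["ppa"]["sd"] == 0.0

    def test_single_report_flagged(self):
        r = summary_metrics([0.9, 0.1], [1, 0])
        agg = aggregate_folds([r])
        assert agg["roc_auc"]["sd"] == 0.0 and agg["roc_auc"]["sd_flag"]


class TestStratified:
    def test_single_stratum_equals_all(self, rng):
        scores = rng.random(30)
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]
        reports = stratified_report(scores, labels, ["Bx"] * 30)
        assert reports["ALL"].roc_auc == reports["Bx"].roc_auc

    def test_strata_partition_all(self, rng):
        scores = rng.random(40)
        labels = rng.integers(0, 2, size=40)
        labels[:4] = [0, 1, 0, 1]
        strata = np.array(["Bx", "Rx"] * 20)
        reports = stratified_report(scores, labels, strata)
        assert reports["Bx"].n + reports["Rx"].n == reports["ALL"].n

    def test_identical_distributions_similar_auc(self):
        rng = np.random.default_rng(0)
        n = 4000
        labels = rng.integers(0, 2, size=n)
        scores = np.clip(labels * 0.3 + rng.random(n) * 0.7, 0, 1)
        strata = np.array(["Bx", "Rx"])[rng.integers(0, 2, size=n)]
        reports = stratified_report(scores, labels, strata)
        assert abs(reports["Bx"].roc_auc - reports["Rx"].roc_auc) < 0.05
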