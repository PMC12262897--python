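"""Evaluation harness: partitioning, metrics, t-test, importance roll-up."""

import numpy as np
import pandas as pd
import pytest

from bimm import (
    BimmError,
    DegenerateOutcomeError,
    PhiUndefinedError,
    RFParams,
    SplitFunctionSpec,
    aggregate_importance,
    compute_auc,
    confusion_metrics,
    partition_by_individual,
    phi_coefficient,
    run_experiment,
    two_sample_t,
)
from bimm.evaluation import summarize_metrics


def _brute_force_auc(y, s):
    y = np.asarray(y)
    s = np.asarray(s, float)
    pos = s[y == 1]
    neg = s[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestPartitionByIndividual:
    def test_seventy_thirty_rounding(self, small_cohort):
        ten = small_cohort[small_cohort["person_id"] <= 10]
        train, test = partition_by_individual(ten, 0.7, seed=0)
        assert train["person_id"].nunique() == 7 and len(train) == 14
        assert test["person_id"].nunique() == 3 and len(test) == 6

    def test_partition_properties(self, small_cohort):
        train, test = partition_by_individual(small_cohort, 0.7, seed=5)
        assert set(train["person_id"]) & set(test["person_id"]) == set()
        merged = pd.concat([train, test]).sort_index()
        pd.testing.assert_frame_equal(merged, small_cohort)

    def test_bad_fraction(self, small_cohort):
        with pytest.raises(BimmError):
            partition_by_individual(small_cohort, 1.0, seed=0)


class TestComputeAuc:
    def test_worked_example(self):
        assert compute_auc([0, 0, 1, 1], [0.1, 0.6, 0.4, 0.8]) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert compute_auc([0, 0, 1], [0.1, 0.2, 0.9]) == 1.0

    def test_all_ties_give_half(self):
        assert compute_auc([0, 1, 0, 1], [0.5] * 4) == 0.5

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            n = rng.integers(4, 50)
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            s = np.round(rng.random(n), 2)  # coarse grid forces ties
            assert compute_auc(y, s) == pytest.approx(
                _brute_force_auc(y, s), abs=1e-12
            )

    def test_single_class_signalled(self):
        with pytest.raises(DegenerateOutcomeError):
            compute_auc([1, 1], [0.2, 0.4])


class TestConfusionMetrics:
    def test_perfect_classifier(self):
        assert confusion_metrics([1, 1, 0, 0], [0.9, 0.9, 0.1, 0.1], 0.5) == (
            1.0, 1.0, 1.0, 0.0,
        )

    def test_inverted_classifier(self):
        assert confusion_metrics([1, 0], [0.2, 0.9], 0.5) == (0.0, 0.0, 0.0, 1.0)

    def test_counting_example(self):
        # 3 positives (2 detected), 7 negatives (1 false positive)
        y = [1, 1, 1, 0, 0, 0, 0, 0, 0, 0]
        s = [0.9, 0.8, 0.2, 0.7, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1]
        sens, spec, acc, fpr = confusion_metrics(y, s, 0.5)
        assert sens == pytest.approx(2 / 3)
        assert spec == pytest.approx(6 / 7)
        assert fpr == pytest.approx(1 - 6 / 7)
        assert acc == pytest.approx(8 / 10)

    def test_ties_at_threshold_go_to_class_zero(self):
        sens, spec, *_ = confusion_metrics([1, 0], [0.78, 0.10], 0.78)
        # strictly-greater rule: a score equal to the cut-off predicts 0
        assert sens == 0.0 and spec == 1.0

    def test_fpr_complements_specificity(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 100)
        y[:2] = [0, 1]
        s = rng.random(100)
        _, spec, _, fpr = confusion_metrics(y, s, 0.4)
        assert fpr + spec == pytest.approx(1.0, abs=1e-12)


class TestPhiCoefficient:
    def test_worked_examples(self):
        assert phi_coefficient(40, 10, 10, 40) == pytest.approx(0.6)
        assert phi_coefficient(25, 25, 25, 25) == 0.0
        assert phi_coefficient(50, 0, 0, 50) == pytest.approx(1.0)

    def test_matches_direct_arithmetic_on_random_tables(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            a, b, c, d = rng.integers(1, 60, 4)
            import math

            direct = (a * d - b * c) / math.sqrt(
                (a + b) * (c + d) * (a + c) * (b + d)
            )
            assert phi_coefficient(int(a), int(b), int(c), int(d)) == pytest.approx(
                direct, abs=1e-12
            )

    def test_zero_margin_signalled(self):
        with pytest.raises(PhiUndefinedError):
            phi_coefficient(10, 0, 5, 0)


class TestTwoSampleT:
    def test_identical_samples_null(self):
        t, p, lo, hi = two_sample_t([0.7, 0.72, 0.71], [0.7, 0.72, 0.71])
        assert t == 0.0 and p == pytest.approx(1.0)
        assert lo == pytest.approx(-hi)

    def test_matches_welch_formulas(self):
        a = np.array([0.71, 0.74, 0.69, 0.73, 0.70])
        b = np.array([0.68, 0.66, 0.70, 0.67, 0.69])
        t, p, lo, hi = two_sample_t(a, b)
        va, vb = a.var(ddof=1) / 5, b.var(ddof=1) / 5
        t_hand = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df_hand = (va + vb) ** 2 / (va**2 / 4 + vb**2 / 4)
        from scipy import stats

        p_hand = 2 * stats.t.sf(abs(t_hand), df_hand)
        assert t == pytest.approx(t_hand, abs=1e-8)
        assert p == pytest.approx(p_hand, abs=1e-8)
        assert lo <= a.mean() - b.mean() <= hi

    def test_zero_variance_signalled(self):
        with pytest.raises(DegenerateOutcomeError):
            two_sample_t([0.5, 0.5], [0.6, 0.6])


class TestAggregateImportance:
    def test_identical_lists(self):
        lst = [(f"x{i}", 1.0 / (i + 1)) for i in range(20)]
        unique, top10 = aggregate_importance([lst] * 100)
        assert unique == 20
        assert top10[0] == ("x0", pytest.approx(1.0))
        assert len(top10) == 10

    def test_disjoint_lists(self):
        a = [(f"a{i}", 1.0) for i in range(20)]
        b = [(f"b{i}", 2.0) for i in range(20)]
        unique, _ = aggregate_importance([a, b])
        assert unique == 40

    def test_hand_computed_averages(self):
        l1 = [("u", 3.0), ("v", 2.0)] + [(f"f{i}", 0.1) for i in range(18)]
        l2 = [("u", 1.0), ("w", 5.0)] + [(f"f{i}", 0.1) for i in range(18)]
        l3 = [("u", 2.0), ("v", 4.0)] + [(f"f{i}", 0.1) for i in range(18)]
        _, top = aggregate_importance([l1, l2, l3], top_k_mean=3)
        means = dict(top)
        assert means["w"] == pytest.approx(5.0)  # present once: mean over 1
        assert means["v"] == pytest.approx(3.0)  # (2+4)/2
        assert means["u"] == pytest.approx(2.0)  # (3+1+2)/3
        _, top_z = aggregate_importance(
            [l1, l2, l3], top_k_mean=3, absent_as_zero=True
        )
        assert dict(top_z)["w"] == pytest.approx(5.0 / 3)

    def test_malformed_input(self):
        with pytest.raises(BimmError):
            aggregate_importance([])
        with pytest.raises(BimmError):
            aggregate_importance([[("x", 1.0)]])  # wrong list length


class TestRunExperiment:
    def test_summary_is_mean_of_partition_metrics(self, small_cohort, fast_rf):
        s = run_experiment(
            small_cohort, SplitFunctionSpec("h2", k2=1.5), fast_rf,
            n_partitions=2, max_iter=4, seed=5,
        )
        recomputed = summarize_metrics(s.metrics)
        pd.testing.assert_frame_equal(s.summary, recomputed)
        bimm_auc = s.metrics[s.metrics["method"] == "BiMM"]["auc"]
        assert s.summary.loc["BiMM", ("auc", "mean")] == pytest.approx(
            bimm_auc.mean()
        )

    def test_reproducible_from_master_seed(self, small_cohort, fast_rf):
        kw = dict(n_partitions=2, max_iter=3, seed=9)
        a = run_experiment(small_cohort, SplitFunctionSpec("h3"), fast_rf, **kw)
        b = run_experiment(small_cohort, SplitFunctionSpec("h3"), fast_rf, **kw)
        pd.testing.assert_frame_equal(a.metrics, b.metrics)
        assert a.t_statistic == b.t_statistic
        assert a.unique_top_variables == b.unique_top_variables

    def test_row_conservation_per_partition(self, small_cohort):
        train, test = partition_by_individual(small_cohort, 0.7, seed=123)
        assert len(train) + len(test) == len(small_cohort)
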