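"""LOSO harness: splits, metrics, thresholds, trial aggregation, McNemar."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from wristgait.evaluation import (ConfusionCounts, EvaluationReport,
                                  FoldResult, UndefinedMetricError,
                                  UndefinedTestError, aggregate_trial,
                                  apply_threshold, compare_methods,
                                  loso_splits, mcnemar_test, metrics,
                                  threshold_sweep, trial_predictions)


class TestLosoSplits:
    def test_three_subjects(self):
        folds = loso_splits(["A", "B", "C"])
        assert folds == [(["B", "C"], "A"), (["A", "C"], "B"), (["A", "B"], "C")]

    def test_eighteen_subjects_eighteen_folds(self):
        ids = [f"S{i}" for i in range(18)]
        folds = loso_splits(ids)
        assert len(folds) == 18
        assert sorted(test for _, test in folds) == sorted(ids)

    def test_partition_no_overlap(self):
        folds = loso_splits(["a", "b", "c", "d"])
        for train, test in folds:
            assert test not in train
            assert set(train) | {test} == {"a", "b", "c", "d"}

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            loso_splits(["only"])


class TestMetrics:
    def test_worked_example(self):
        c = ConfusionCounts(tp=45, fn=5, tn=40, fp=10)
        acc, sens, spec = metrics(c)
        assert acc == 0.85 and sens == 0.90 and spec == 0.80

    def test_perfect_classifier(self):
        assert metrics(ConfusionCounts(tp=7, tn=7)) == (1.0, 1.0, 1.0)

    def test_zero_denominator_raises(self):
        with pytest.raises(UndefinedMetricError):
            metrics(ConfusionCounts(tp=0, fn=0, tn=5, fp=5))

    def test_agrees_with_bruteforce_recount(self, rng):
        for _ in range(100):
            n = rng.integers(4, 60)
            y = rng.integers(0, 2, n)
            p = rng.integers(0, 2, n)
            if len(set(y)) < 2:
                continue
            c = ConfusionCounts.from_predictions(y, p)
            acc, sens, spec = metrics(c)
            assert acc == np.mean(y == p)
            assert sens == np.mean(p[y == 1] == 1)
            assert spec == np.mean(p[y == 0] == 0)


class TestThreshold:
    def test_quoted_rule(self):
        probs = [(0.75, 0.25)]
        assert apply_threshold(probs, 0.8)[0] == 1   # abnormal
        assert apply_threshold(probs, 0.5)[0] == 0   # normal

    def test_boundary_is_abnormal(self):
        assert apply_threshold([(0.8, 0.2)], 0.8)[0] == 1

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            apply_threshold([(0.9, 0.3)], 0.5)


class TestTrialAggregation:
    def test_majority(self):
        assert aggregate_trial([1, 1, 0]) == 1
        assert aggregate_trial([0, 0]) == 0

    def test_tie_goes_abnormal(self):
        assert aggregate_trial([0, 1]) == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_trial([])

    def test_grouping(self):
        ids = ["a", "a", "b", "b", "b"]
        truth = [1, 1, 0, 0, 0]
        pred = [1, 0, 0, 1, 0]
        tids, t_true, t_pred = trial_predictions(ids, truth, pred)
        assert list(tids) == ["a", "b"]
        assert list(t_true) == [1, 0]
        assert list(t_pred) == [1, 0]  # a: tie->abnormal, b: majority normal


class TestMcNemar:
    def _paired(self, b, c, n_extra=30):
        """Construct predictions with exactly b and c discordant pairs."""
        labels = np.zeros(b + c + n_extra, dtype=int)
        a = np.zeros_like(labels)
        bb = np.zeros_like(labels)
        a[:b] = 0; bb[:b] = 1                   # A right, B wrong
        a[b:b + c] = 1; bb[b:b + c] = 0        # A wrong, B right
        return a, bb, labels

    def test_statistic_example(self):
        a, b, labels = self._paired(10, 2)
        stat, p, db, dc = mcnemar_test(a, b, labels)
        assert abs(stat - 49 / 12) < 1e-12
        assert (db, dc) == (10, 2)
        # b + c < 25 -> exact two-sided binomial tail
        expected = min(1.0, 2 * sum(stats.binom.pmf(k, 12, 0.5) for k in range(3)))
        assert abs(p - expected) < 1e-9

    def test_symmetric_p_one(self):
        a, b, labels = self._paired(4, 4)
        _, p, _, _ = mcnemar_test(a, b, labels)
        assert p == 1.0

    def test_continuity_corrected_statistic(self):
        a, b, labels = self._paired(5, 5)
        stat, _, _, _ = mcnemar_test(a, b, labels)
        assert abs(stat - 0.1) < 1e-12

    def test_no_discordant_rejected(self):
        labels = np.zeros(10, int)
        with pytest.raises(UndefinedTestError):
            mcnemar_test(labels, labels, labels)

    def test_matches_exact_binomial_oracle(self):
        """Exact-binomial agreement for every discordant split b+c <= 20."""
        for n in range(1, 21):
            for b in range(n + 1):
                c = n - b
                a_pred, b_pred, labels = self._paired(b, c)
                _, p, _, _ = mcnemar_test(a_pred, b_pred, labels)
                k = min(b, c)
                oracle = min(1.0, 2 * float(stats.binom.cdf(k, n, 0.5)))
                if b == c:
                    oracle = 1.0
                assert abs(p - oracle) < 1e-9

    def test_matches_statsmodels_exact(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar
        for b, c in [(10, 2), (7, 1), (3, 9), (6, 6)]:
            a_pred, b_pred, labels = self._paired(b, c)
            _, p, _, _ = mcnemar_test(a_pred, b_pred, labels)
            table = [[0, b], [c, 0]]
            ref = sm_mcnemar(table, exact=True).pvalue
            assert abs(p - ref) < 1e-9


def _fold(rng, subject, n=40):
    labels = rng.integers(0, 2, n)
    p_ab = np.clip(0.5 * labels + rng.uniform(0, 0.5, n), 0, 1)
    probs = np.column_stack([1 - p_ab, p_ab])
    trials = np.array([f"{subject}/t{i % 4}/{l}" for i, l in
                       zip(range(n), labels)], dtype=object)
    return FoldResult(test_subject=subject, window_labels=labels,
                      window_probs=probs, trial_ids=trials,
                      wrists=np.full(n, "right", object))


class TestReportAndSweep:
    @pytest.fixture()
    def report(self, rng):
        rep = EvaluationReport(method="proposed", sensors="AGR",
                               wrist_policy=("both", "both"), seed=0)
        rep.folds = [_fold(rng, f"S{i}") for i in range(4)]
        return rep

    def test_pooled_equals_sum_of_folds(self, report):
        pooled = report.pooled_confusion(0.5)
        total = ConfusionCounts()
        for f in report.folds:
            total = total + f.confusion(0.5)
        assert pooled == total

    def test_sweep_monotonicity(self, report):
        table = threshold_sweep(report)
        sens = table["segment_sensitivity"].to_numpy()
        spec = table["segment_specificity"].to_numpy()
        assert (np.diff(sens) >= -1e-12).all()
        assert (np.diff(spec) <= 1e-12).all()

    def test_sweep_first_row_is_default(self, report):
        table = threshold_sweep(report)
        row = table.iloc[0]
        acc, sens, spec = report.pooled_metrics(0.5)
        assert row["threshold"] == 0.5
        assert row["segment_accuracy"] == acc

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=50, deadline=None)
    def test_monotonicity_for_arbitrary_probabilities(self, seed):
        """Raising the normal threshold can only grow the abnormal set."""
        r = np.random.default_rng(seed)
        n = int(r.integers(6, 60))
        labels = r.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        p_ab = r.uniform(0, 1, n)
        probs = np.column_stack([1 - p_ab, p_ab])
        prev_sens, prev_spec = -1.0, 2.0
        for thr in (0.5, 0.6, 0.7, 0.8, 0.9):
            pred = apply_threshold(probs, thr)
            c = ConfusionCounts.from_predictions(labels, pred)
            _, sens, spec = metrics(c)
            assert sens >= prev_sens - 1e-12
            assert spec <= prev_spec + 1e-12
            prev_sens, prev_spec = sens, spec

    def test_json_roundtrip(self, report, tmp_path):
        path = tmp_path / "report.json"
        report.to_json(path)
        back = EvaluationReport.from_json(path)
        assert back.method == report.method
        assert len(back.folds) == len(report.folds)
        np.testing.assert_array_equal(back.folds[0].window_labels,
                                      report.folds[0].window_labels)
        np.testing.assert_allclose(back.folds[0].window_probs,
                                   report.folds[0].window_probs, atol=1e-6)

    def test_compare_methods_table(self, report, rng):
        other = EvaluationReport(method="rf", sensors="AGR",
                                 wrist_policy=("both", "both"), seed=0)
        rng2 = np.random.default_rng(1)
        other.folds = [_fold(rng2, f"S{i}") for i in range(4)]
        # same instances: copy labels/trials from the reference report
        for fo, fr in zip(other.folds, report.folds):
            fo.window_labels = fr.window_labels
            fo.trial_ids = fr.trial_ids
        table = compare_methods({"proposed": report, "rf": other})
        assert set(table["method"]) == {"proposed", "rf"}
        row = table[table.method == "rf"].iloc[0]
        assert 0 <= row["mcnemar_p"] <= 1 or np.isnan(row["mcnemar_p"])
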