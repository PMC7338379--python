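"""Split protocol, cross-validation bookkeeping and metric identities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spheroscreen.training import (
    SplitPlan,
    evaluate,
    make_splits,
    metrics_from_confusion,
)


def _labels(n_per_class):
    return np.repeat(["unaffected", "mildly_affected", "affected"], n_per_class)


class TestMakeSplits:
    def test_1200_items_split_into_960_pool_and_240_test(self):
        splits = make_splits(_labels(400), SplitPlan(seed=0))
        assert len(splits.test_idx) == 240
        assert len(splits.train_pool_idx) == 960

    def test_each_fold_is_768_train_192_validation(self):
        splits = make_splits(_labels(400), SplitPlan(seed=0))
        for tr, va in splits.folds:
            assert len(tr) == 768
            assert len(va) == 192

    def test_partition_disjointness_and_coverage(self):
        splits = make_splits(_labels(400), SplitPlan(seed=1))
        test = set(splits.test_idx)
        pool = set(splits.train_pool_idx)
        assert not test & pool
        assert test | pool == set(range(1200))
        val_union = set()
        for tr, va in splits.folds:
            assert not set(tr) & set(va)
            assert set(tr) | set(va) == pool
            assert not val_union & set(va)
            val_union |= set(va)
        assert val_union == pool

    def test_single_fold_plan_is_rejected(self):
        with pytest.raises(ValueError, match="n_folds"):
            SplitPlan(n_folds=1)

    def test_too_few_items_per_class_rejected(self):
        with pytest.raises(ValueError):
            make_splits(_labels(3), SplitPlan(n_folds=5))

    def test_unlabeled_items_rejected(self):
        y = np.array(["unaffected"] * 20 + ["unlabeled"] * 5)
        with pytest.raises(ValueError, match="unlabeled"):
            make_splits(y, SplitPlan())

    def test_deterministic_under_seed(self):
        a = make_splits(_labels(50), SplitPlan(seed=5))
        b = make_splits(_labels(50), SplitPlan(seed=5))
        np.testing.assert_array_equal(a.test_idx, b.test_idx)
        for (t1, v1), (t2, v2) in zip(a.folds, b.folds):
            np.testing.assert_array_equal(v1, v2)

    @given(st.integers(min_value=10, max_value=80), st.integers(min_value=2, max_value=6))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_partition_property_for_arbitrary_sizes(self, per_class, n_folds):
        y = _labels(per_class)
        splits = make_splits(y, SplitPlan(n_folds=n_folds, seed=0))
        n = len(y)
        test = set(splits.test_idx)
        pool = set(splits.train_pool_idx)
        assert not test & pool and test | pool == set(range(n))
        sizes = [len(va) for _, va in splits.folds]
        assert max(sizes) - min(sizes) <= len(np.unique(y))  # near-equal folds
        val_union = set()
        for _, va in splits.folds:
            assert not val_union & set(va)
            val_union |= set(va)
        assert val_union == pool


def _bruteforce_metrics(cm):
    """Independent oracle: per-class P/R/F1 by explicit counting loops."""
    k = cm.shape[0]
    out = []
    for c in range(k):
        tp = cm[c, c]
        fp = sum(cm[r, c] for r in range(k) if r != c)
        fn = sum(cm[c, r] for r in range(k) if r != c)
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * p * r / (p + r) if p + r else 0.0
        out.append((p, r, f1))
    return out


class TestMetrics:
    def test_hand_computed_confusion_example(self):
        cm = np.array([[8, 1, 1], [0, 9, 1], [2, 0, 8]])
        rep = metrics_from_confusion(cm, ("a", "b", "c"))
        assert rep.precision["a"] == pytest.approx(0.8)
        assert rep.recall["a"] == pytest.approx(0.8)
        assert rep.f1["a"] == pytest.approx(0.8)

    def test_equal_precision_and_recall_give_equal_f1(self):
        # harmonic mean of 0.9 and 0.9 is 0.9
        p, r = 0.9, 0.9
        assert 2 * p * r / (p + r) == pytest.approx(0.9)
        cm = np.array([[9, 1], [1, 9]])
        rep = metrics_from_confusion(cm, ("x", "y"))
        assert rep.precision["x"] == rep.recall["x"] == pytest.approx(0.9)
        assert rep.f1["x"] == pytest.approx(0.9)

    def test_perfect_predictions_score_one_everywhere(self):
        cm = np.diag([10, 12, 9])
        rep = metrics_from_confusion(cm, ("a", "b", "c"))
        for c in ("a", "b", "c"):
            assert rep.precision[c] == rep.recall[c] == rep.f1[c] == 1.0
        assert rep.accuracy == 1.0

    def test_pipeline_metrics_match_bruteforce_oracle_on_random_matrices(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            cm = rng.integers(0, 30, size=(3, 3))
            rep = metrics_from_confusion(cm, ("a", "b", "c"))
            oracle = _bruteforce_metrics(cm)
            for c, (p, r, f1) in zip(("a", "b", "c"), oracle):
                assert rep.precision[c] == pytest.approx(p)
                assert rep.recall[c] == pytest.approx(r)
                assert rep.f1[c] == pytest.approx(f1)
            assert rep.accuracy == pytest.approx(
                np.trace(cm) / cm.sum() if cm.sum() else 0.0
            )

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_f1_lies_between_min_and_harmonic_bound(self, seed):
        cm = np.random.default_rng(seed).integers(0, 20, size=(3, 3))
        rep = metrics_from_confusion(cm, ("a", "b", "c"))
        for c in ("a", "b", "c"):
            p, r, f1 = rep.precision[c], rep.recall[c], rep.f1[c]
            assert f1 <= max(p, r) + 1e-12
            if p + r > 0:
                lo, hi = min(p, r), max(p, r)
                assert f1 >= lo * (2 * hi / (hi + lo)) - 1e-12


class _StubModel:
    """Deterministic fake classifier for evaluate() plumbing tests."""

    classes_ = np.array(["affected", "mildly_affected", "unaffected"])

    def __init__(self, predictions):
        self._pred = np.asarray(predictions)

    def predict(self, X):
        return self._pred[: len(X)]


class TestEvaluate:
    def test_perfect_stub_model_scores_one(self):
        y = np.array(["affected", "mildly_affected", "unaffected"] * 4)
        model = _StubModel(y)
        rep = evaluate(model, np.zeros((12, 4, 4)), y)
        assert rep.accuracy == 1.0
        assert all(v == 1.0 for v in rep.f1.values())

    def test_confusion_rows_sum_to_true_class_counts(self):
        y = np.array(["affected"] * 5 + ["unaffected"] * 7)
        pred = np.array(["affected"] * 4 + ["unaffected"] * 8)
        rep = evaluate(_StubModel(pred), np.zeros((12, 4, 4)), y)
        row_sums = rep.confusion.sum(axis=1)
        assert row_sums[list(rep.classes).index("affected")] == 5
        assert row_sums[list(rep.classes).index("unaffected")] == 7

    def test_unlabeled_test_items_rejected(self):
        y = np.array(["affected", "unlabeled"])
        with pytest.raises(ValueError, match="unlabeled"):
            evaluate(_StubModel(y), np.zeros((2, 4, 4)), y)

    def test_empty_test_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            evaluate(_StubModel([]), np.zeros((0, 4, 4)), [])
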