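"""Metrics, fold construction, nested CV selection, and the report grid."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.base import BaseEstimator, ClassifierMixin

from slepredict.evaluation import (
    CVPlan,
    auc_mann_whitney,
    compute_metrics,
    make_folds,
    mean_metrics,
    nested_cv,
    report,
    run_grid,
)


def brute_force_auc(labels, scores):
    """All-pairs comparison statistic: wins + half-ties over pos x neg pairs."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


class TestComputeMetrics:
    def test_perfect_separation(self):
        m = compute_metrics([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1])
        assert m.auc == m.accuracy == m.recall == m.specificity == 1.0
        assert m.ppv == m.f1 == 1.0

    def test_reversed_scores(self):
        m = compute_metrics([1, 0], [0.4, 0.6])
        assert m.auc == 0.0
        assert m.recall == 0.0 and m.specificity == 0.0
        # the one prediction >= 0.5 is a false positive
        assert m.accuracy == 0.0

    def test_tied_scores_half_credit(self):
        m = compute_metrics([1, 1, 0, 0], [0.6, 0.4, 0.6, 0.4])
        assert m.auc == pytest.approx(brute_force_auc([1, 1, 0, 0], [0.6, 0.4, 0.6, 0.4]))
        assert m.auc == pytest.approx(0.5)

    def test_single_class_auc_is_nan_not_zero(self):
        m = compute_metrics([1, 1], [0.2, 0.9])
        assert np.isnan(m.auc)
        assert m.recall == 0.5

    def test_f_beta_reduces_to_f1_at_beta_one(self):
        m = compute_metrics([1, 1, 0, 0, 1], [0.9, 0.3, 0.7, 0.1, 0.8], beta=1.0)
        assert m.f_beta == pytest.approx(m.f1)
        assert m.f1 == pytest.approx(2 * m.ppv * m.recall / (m.ppv + m.recall))

    def test_undefined_ppv_is_nan(self):
        m = compute_metrics([1, 0], [0.1, 0.2])  # nothing predicted positive
        assert np.isnan(m.ppv) and np.isnan(m.f1)

    @given(
        labels=st.lists(st.integers(0, 1), min_size=2, max_size=200).filter(
            lambda ls: 0 < sum(ls) < len(ls)
        ),
        data=st.data(),
    )
    @settings(max_examples=60, derandomize=True)
    def test_rank_auc_equals_brute_force_with_ties(self, labels, data):
        # coarse score grid forces plenty of ties
        scores = data.draw(
            st.lists(
                st.sampled_from([0.0, 0.25, 0.5, 0.75, 1.0]),
                min_size=len(labels),
                max_size=len(labels),
            )
        )
        assert auc_mann_whitney(labels, scores) == pytest.approx(
            brute_force_auc(labels, scores), abs=1e-12
        )

    def test_agrees_with_sklearn_reference(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 150)
        y[0], y[1] = 0, 1
        s = np.round(rng.random(150), 1)
        assert auc_mann_whitney(y, s) == pytest.approx(roc_auc_score(y, s))

    def test_mean_of_folds_is_arithmetic_mean(self):
        m1 = compute_metrics([1, 0], [0.9, 0.1])
        m2 = compute_metrics([1, 1, 0, 0], [0.6, 0.4, 0.6, 0.4])
        mm = mean_metrics([m1, m2])
        assert mm.auc == pytest.approx((1.0 + 0.5) / 2)
        assert mm.accuracy == pytest.approx((m1.accuracy + m2.accuracy) / 2)


class TestFolds:
    def test_partition_properties(self):
        y = np.array([1] * 40 + [0] * 160)
        folds = make_folds(y, 20, stratified=True, seed=0)
        all_test = np.concatenate([t for _, t in folds])
        assert len(folds) == 20
        assert sorted(all_test) == list(range(200))
        sizes = [len(t) for _, t in folds]
        assert max(sizes) - min(sizes) <= 1
        pos_counts = [y[t].sum() for _, t in folds]
        assert max(pos_counts) - min(pos_counts) <= 1

    def test_auto_reduction_when_too_few_positives(self):
        y = np.array([1] * 3 + [0] * 97)
        with pytest.warns(UserWarning, match="reducing folds"):
            folds = make_folds(y, 20, stratified=True, seed=0)
        assert len(folds) == 3

    def test_grouped_folds_keep_patients_whole(self):
        y = np.tile([1, 0, 0, 0], 10)
        groups = np.repeat(np.arange(10), 4)
        folds = make_folds(y, 5, stratified=True, groups=groups, seed=0)
        for train, test in folds:
            assert set(groups[train]).isdisjoint(set(groups[test]))


class _OracleClassifier(ClassifierMixin, BaseEstimator):
    """Scores the first column if `good`, else a constant: a controllable
    candidate for grid-selection tests (X[:, 0] is built to equal y)."""

    def __init__(self, good=True):
        self.good = good

    def fit(self, X, y):
        self.classes_ = np.unique(y)
        return self

    def predict_proba(self, X):
        s = X[:, 0] if self.good else np.full(len(X), 0.5)
        return np.column_stack([1 - s, s])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


class TestNestedCV:
    def _data(self, n=80):
        rng = np.random.default_rng(0)
        y = (rng.random(n) < 0.4).astype(int)
        y[:4] = [0, 0, 1, 1]
        X = np.column_stack([y.astype(float), rng.normal(size=n)])
        return X, y

    def test_strictly_better_candidate_always_chosen(self):
        X, y = self._data()
        plan = CVPlan(outer_folds=4, inner_folds=3, seed=0)
        res = nested_cv(X, y, _OracleClassifier(), [{"good": False}, {"good": True}], plan)
        assert all(p == {"good": True} for p in res.chosen_params)
        assert res.mean.accuracy == 1.0

    def test_single_candidate_is_forced_choice(self):
        X, y = self._data()
        plan = CVPlan(outer_folds=3, inner_folds=2, seed=1)
        res = nested_cv(X, y, _OracleClassifier(), [{"good": True}], plan)
        assert res.chosen_params == [{"good": True}] * 3

    def test_perfectly_separable_mean_accuracy_one(self):
        X, y = self._data()
        plan = CVPlan(outer_folds=5, inner_folds=2, seed=2)
        res = nested_cv(X, y, _OracleClassifier(), None, plan)
        assert res.mean.accuracy == 1.0
        assert len(res.per_fold) == 5

    def test_manifest_records_fold_partition(self):
        X, y = self._data()
        plan = CVPlan(outer_folds=4, inner_folds=2, seed=3)
        res = nested_cv(X, y, _OracleClassifier(), None, plan)
        all_test = sorted(
            i for f in res.manifest["outer_folds"] for i in f["test_indices"]
        )
        assert all_test == list(range(len(y)))
        for f in res.manifest["outer_folds"]:
            assert set(f["train_indices"]).isdisjoint(f["test_indices"])


@pytest.fixture(scope="module")
def tiny_grid(small_series):
    from slepredict.ensemble import BaggedDifferentialClassifier
    from slepredict.evaluation import differential_builder

    est = BaggedDifferentialClassifier(n_bags=2, families=("tree", "gnb"), random_state=0)
    plan = CVPlan(outer_folds=3, inner_folds=2, seed=0)
    models = {
        "Differential": (est, None, differential_builder),
        "LSTM": (est, None, differential_builder),
    }
    return run_grid(small_series, [6], [12], models, plan)


class TestGridAndReport:
    def test_single_cell_grid(self, tiny_grid):
        assert not tiny_grid.errors
        assert set(tiny_grid.entries) == {(6, 12, "Differential"), (6, 12, "LSTM")}
        entry = tiny_grid.entries[(6, 12, "Differential")]
        assert entry["total"] == 40 * 6

    def test_identical_models_give_zero_ld(self, tiny_grid):
        ld = tiny_grid.ld_table("auc")
        np.testing.assert_allclose(ld.to_numpy(), 0.0)

    def test_report_tables_and_determinism(self, tiny_grid, tmp_path):
        tables = report(tiny_grid, tmp_path / "a")
        auc = tables["auc"]
        assert list(auc.columns) == ["x_months", "y_months", "D", "L", "L-D"]
        np.testing.assert_allclose(auc["L-D"], auc["L"] - auc["D"])
        report(tiny_grid, tmp_path / "b")
        assert (tmp_path / "a" / "auc.csv").read_bytes() == (
            tmp_path / "b" / "auc.csv"
        ).read_bytes()
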