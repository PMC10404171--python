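"""ROC construction and Youden-optimal cut-off selection.

The implementation (midpoint candidate thresholds, ``>=`` orientation) is
checked against a brute-force oracle that enumerates every threshold and
tallies confusion matrices by explicit loops, and against
sklearn.metrics.roc_curve as an independent reference for the attainable
operating points.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn import metrics as skm
from sklearn.base import clone

from protreact import YoudenThresholdClassifier, optimal_cutoff, roc_curve
from protreact.exceptions import DegenerateDataError


def brute_force_operating_points(scores, labels):
    """Every achievable (tpr, fpr) of the rule ``score >= t``, by enumeration."""
    scores = list(map(float, scores))
    labels = list(map(bool, labels))
    candidates = sorted(set(scores)) + [max(scores) + 1.0]
    points = set()
    for t in candidates:
        tp = sum(1 for s, y in zip(scores, labels) if y and s >= t)
        fp = sum(1 for s, y in zip(scores, labels) if not y and s >= t)
        points.add((tp / sum(labels), fp / (len(labels) - sum(labels))))
    return points


def brute_force_best_j(scores, labels):
    return max(tpr - fpr for tpr, fpr in brute_force_operating_points(scores, labels))


class TestRocCurve:
    def test_perfectly_separable(self):
        curve = roc_curve([0, 0, 100, 100], [False, False, True, True])
        result = optimal_cutoff(curve)
        assert 0 < result.threshold < 100
        assert result.sensitivity == 1.0 and result.specificity == 1.0
        assert result.youden_j == 1.0 and result.balanced_accuracy == 1.0

    def test_all_scores_equal_gives_chance(self):
        curve = roc_curve([5.0] * 6, [True, True, True, False, False, False])
        assert len(curve.thresholds) == 2  # only the two sentinels
        assert brute_force_best_j([5.0] * 6, [1, 1, 1, 0, 0, 0]) == 0.0
        assert optimal_cutoff(curve).youden_j == 0.0

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateDataError):
            roc_curve([1, 2, 3], [True, True, True])

    def test_monotone_rates(self):
        rng = np.random.default_rng(0)
        scores = rng.uniform(0, 100, 50)
        labels = rng.random(50) < 0.5
        labels[0], labels[1] = True, False
        curve = roc_curve(scores, labels)
        assert (np.diff(curve.tpr) <= 0).all()
        assert (np.diff(curve.fpr) <= 0).all()

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 31)
        scores = np.round(rng.uniform(0, 100, n), 1)
        labels = rng.random(n) < 0.5
        labels[0], labels[1] = True, False
        curve = roc_curve(scores, labels)
        ours = set(zip(np.round(curve.tpr, 12), np.round(curve.fpr, 12)))
        brute = {
            (round(t, 12), round(f, 12))
            for t, f in brute_force_operating_points(scores, labels)
        }
        assert brute <= ours  # midpoints reach every enumerated matrix
        assert optimal_cutoff(curve).youden_j == pytest.approx(
            brute_force_best_j(scores, labels)
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_sklearn_reference(self, seed):
        rng = np.random.default_rng(100 + seed)
        scores = rng.normal(50, 20, 40)
        labels = rng.random(40) < 0.5
        labels[0], labels[1] = True, False
        curve = roc_curve(scores, labels)
        fpr, tpr, _ = skm.roc_curve(labels, scores)
        assert max(curve.youden_j) == pytest.approx(max(tpr - fpr))
        assert curve.auc == pytest.approx(skm.roc_auc_score(labels, scores))


class TestOptimalCutoff:
    def test_tie_interval_members_classify_identically(self):
        rng = np.random.default_rng(7)
        scores = rng.uniform(0, 100, 30)
        labels = rng.random(30) < 0.5
        labels[0], labels[1] = True, False
        result = optimal_cutoff(roc_curve(scores, labels))
        low, high = result.tie_interval
        assert low < result.threshold <= high
        reference = scores >= result.threshold
        for t in np.linspace(low, high, 7)[1:]:  # (low, high]
            assert ((scores >= t) == reference).all()

    def test_shuffled_labels_give_near_zero_j(self):
        rng = np.random.default_rng(42)
        scores = rng.uniform(0, 100, 400)
        labels = rng.permutation([True] * 200 + [False] * 200)
        j = optimal_cutoff(roc_curve(scores, labels)).youden_j
        # argmax over ~400 thresholds of a chance-level J; small positive bias
        assert 0.0 <= j < 0.2

    def test_fixture_cys_cutoff_equivalent_to_published(self, records):
        """The Youden-optimal ProtReact Cys cut-off sits in the same
        inter-score interval as the published 13.935% threshold, so both
        induce the identical classification of the 106 chemicals."""
        scores = np.array([r.protreact.cys_pct for r in records])
        labels = [r.hazard.value == "sensitizer" for r in records]
        result = optimal_cutoff(roc_curve(scores, labels))
        low, high = result.tie_interval
        assert low < 13.935 <= high
        assert ((scores >= result.threshold) == (scores >= 13.935)).all()
        # balanced accuracy can only improve on the reference threshold
        assert result.balanced_accuracy >= 0.7736 - 1e-9

    def test_fixture_mean_cutoff_equivalent_to_published(self, records):
        scores = np.array([r.protreact.mean_pct for r in records])
        labels = [r.hazard.value == "sensitizer" for r in records]
        result = optimal_cutoff(roc_curve(scores, labels))
        low, high = result.tie_interval
        assert low < 9.563 <= high


@settings(deadline=None, max_examples=100)
@given(st.data())
def test_property_interval_classification_invariance(data):
    """Any two thresholds inside one inter-score gap induce identical
    confusion matrices under the >= rule."""
    scores = data.draw(
        st.lists(st.floats(0, 100, allow_nan=False), min_size=3, max_size=20)
    )
    distinct = sorted(set(scores))
    if len(distinct) < 2:
        return
    i = data.draw(st.integers(0, len(distinct) - 2))
    lo, hi = distinct[i], distinct[i + 1]
    t1 = data.draw(st.floats(lo, hi, exclude_min=True, allow_nan=False))
    t2 = data.draw(st.floats(lo, hi, exclude_min=True, allow_nan=False))
    arr = np.asarray(scores)
    assert ((arr >= t1) == (arr >= t2)).all()


class TestEstimatorApi:
    def test_fit_predict_roundtrip(self):
        X = np.array([1.0, 2.0, 30.0, 40.0])
        y = ["non_sensitizer", "non_sensitizer", "sensitizer", "sensitizer"]
        est = YoudenThresholdClassifier().fit(X, y)
        assert 2.0 < est.threshold_ <= 30.0
        assert list(est.predict([0.0, 35.0])) == ["non_sensitizer", "sensitizer"]
        assert est.score(X, y) == 1.0

    def test_clone_and_params(self):
        est = YoudenThresholdClassifier(criterion="balanced_accuracy")
        cloned = clone(est)
        assert cloned.get_params() == {"criterion": "balanced_accuracy"}

    def test_column_vector_input(self):
        X = np.array([[1.0], [2.0], [30.0], [40.0]])
        est = YoudenThresholdClassifier().fit(X, [0, 0, 1, 1])
        assert est.n_features_in_ == 1
        assert est.predict([[50.0]])[0] == "sensitizer"
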