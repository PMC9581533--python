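"""Repeated-split evaluation, confusion metrics, ROC, CV, KS comparison."""

import numpy as np
import pytest

import tpeflim as tf
from tpeflim.evaluation import (
    confusion_matrix, confusion_metrics, kfold_cv, ks_compare,
    repeated_split_eval, roc_curve, tree_roc,
)
from tpeflim.synthetic_data import sample_cells


def _blobs(n_per_class=30, sep=8.0, seed=0, k=2):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(i * sep, 1.0, (n_per_class, 2))
                   for i in range(k)])
    y = np.repeat(np.arange(k), n_per_class)
    return X, y


# ---------------------------------------------------------------------------
# confusion metrics


def test_confusion_matrix_layout():
    cm = confusion_matrix([0, 0, 1, 2], [0, 1, 1, 2], labels=[0, 1, 2])
    assert np.array_equal(cm, [[1, 1, 0], [0, 1, 0], [0, 0, 1]])


def test_metrics_stained_m1_verification_case():
    """8 of 9 cells called M1 were truly positive; every true positive was
    called: PPV 8/9, sensitivity 1.0."""
    cm = np.array([[8, 0], [1, 90]])  # rows true, cols predicted
    m = confusion_metrics(cm)
    assert m["ppv"][0] == pytest.approx(8 / 9)
    assert m["sensitivity"][0] == pytest.approx(1.0)


def test_metrics_stained_m2_verification_case():
    """12 of 14 cells with the M2 signature stained positive: PPV 12/14."""
    cm = np.array([[12, 0], [2, 80]])
    m = confusion_metrics(cm)
    assert m["ppv"][0] == pytest.approx(12 / 14)
    assert m["sensitivity"][0] == pytest.approx(1.0)


def test_metrics_diagonal_matrix_is_perfect():
    m = confusion_metrics(np.diag([5, 7, 9]))
    assert np.allclose(m["sensitivity"], 1.0)
    assert np.allclose(m["specificity"], 1.0)


def test_metrics_zero_denominator_is_nan():
    cm = np.array([[0, 0], [3, 7]])  # no true positives of class 0 at all
    m = confusion_metrics(cm)
    assert np.isnan(m["sensitivity"][0])
    assert not np.isnan(m["specificity"][0])
    with pytest.raises(ValueError):
        confusion_metrics(np.array([[1, -1], [0, 2]]))


def test_metrics_match_direct_definitions():
    rng = np.random.default_rng(1)
    y = rng.integers(0, 3, 200)
    p = rng.integers(0, 3, 200)
    cm = confusion_matrix(y, p, labels=[0, 1, 2])
    m = confusion_metrics(cm)
    for k in range(3):
        tp = np.sum((y == k) & (p == k))
        fn = np.sum((y == k) & (p != k))
        tn = np.sum((y != k) & (p != k))
        fp = np.sum((y != k) & (p == k))
        assert m["sensitivity"][k] == pytest.approx(tp / (tp + fn))
        assert m["specificity"][k] == pytest.approx(tn / (tn + fp))


# ---------------------------------------------------------------------------
# repeated splits


def test_separable_clusters_score_perfectly():
    X, y = _blobs(sep=10.0)
    rep = repeated_split_eval(X, y, n_repeats=20, seed=1)
    assert np.allclose(rep.sensitivity_mean, 1.0)
    assert np.allclose(rep.specificity_mean, 1.0)
    assert np.allclose(rep.sensitivity_sd, 0.0)


def test_repeated_split_is_seed_reproducible():
    X, y = _blobs(sep=2.0, seed=3)
    a = repeated_split_eval(X, y, n_repeats=5, seed=9)
    b = repeated_split_eval(X, y, n_repeats=5, seed=9)
    assert np.array_equal(a.sensitivity_mean, b.sensitivity_mean)
    assert np.array_equal(a.confusion_pooled, b.confusion_pooled)


def test_missing_class_splits_are_redrawn():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(20, 2))
    y = np.zeros(20, dtype=int)
    y[:2] = 1  # rare class: many 50/50 splits strand both copies together
    X[y == 1] += 10
    rep = repeated_split_eval(X, y, n_repeats=40, seed=2)
    assert rep.n_redraws > 0
    assert rep.n_repeats == 40


def test_mean_estimate_stabilises_with_more_repeats():
    """Disagreement between two independent runs shrinks as repeats grow."""
    X, y = _blobs(sep=2.5, seed=5)

    def disagreement(n_repeats):
        a = repeated_split_eval(X, y, n_repeats=n_repeats, seed=11)
        b = repeated_split_eval(X, y, n_repeats=n_repeats, seed=12)
        return abs(a.sensitivity_mean[0] - b.sensitivity_mean[0])

    assert disagreement(400) < disagreement(8) + 1e-12


def test_single_class_input_rejected():
    with pytest.raises(ValueError):
        repeated_split_eval(np.zeros((10, 2)), np.zeros(10), n_repeats=1)


# ---------------------------------------------------------------------------
# ROC


def test_roc_hand_example_auc():
    fpr, tpr, thr, auc = roc_curve([0.9, 0.8, 0.3, 0.2], [1, 0, 1, 0], 1)
    assert auc == pytest.approx(0.75)


def test_roc_perfect_and_null():
    _, _, _, auc = roc_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], 1)
    assert auc == pytest.approx(1.0)
    rng = np.random.default_rng(4)
    scores = rng.uniform(size=4000)
    labels = rng.integers(0, 2, 4000)
    _, _, _, auc = roc_curve(scores, labels, 1)
    assert auc == pytest.approx(0.5, abs=0.05)


def test_roc_auc_equals_pair_counting_oracle():
    """AUC = P(score_pos > score_neg) + 0.5 P(tie), counted exhaustively."""
    rng = np.random.default_rng(8)
    for _ in range(10):
        n = int(rng.integers(6, 25))
        scores = np.round(rng.uniform(size=n), 1)  # coarse grid forces ties
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            continue
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        expected = wins / (len(pos) * len(neg))
        _, _, _, auc = roc_curve(scores, labels, 1)
        assert auc == pytest.approx(expected, abs=1e-12)


def test_roc_single_class_rejected():
    with pytest.raises(ValueError):
        roc_curve([0.5, 0.6], [1, 1], 1)


def test_tree_roc_on_separable_data():
    X, y = _blobs(sep=10.0)
    fpr, tpr, thr, auc = tree_roc(X, y, positive_class=1, seed=0)
    assert auc == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# cross-validation


def test_kfold_perfect_on_separable_data():
    X, y = _blobs(sep=10.0, n_per_class=25)
    scores, mean = kfold_cv(X, y, k=5, seed=0)
    assert len(scores) == 5
    assert np.allclose(scores, 1.0) and mean == 1.0


def test_kfold_seed_reproducible():
    X, y = _blobs(sep=2.0, seed=7)
    s1, _ = kfold_cv(X, y, k=5, seed=3)
    s2, _ = kfold_cv(X, y, k=5, seed=3)
    assert np.array_equal(s1, s2)
    with pytest.raises(ValueError):
        kfold_cv(X, y, k=1)


# ---------------------------------------------------------------------------
# KS comparison


def test_ks_identical_samples_not_rejected():
    x = np.linspace(0, 1, 50)
    d, p, reject = ks_compare(x, x)
    assert d == 0.0 and not reject


def test_ks_separated_m1_m2_lifetimes_rejected(table):
    """tau1 distributions of in vivo M1 (196+/-40) and M2 (442+/-54) cells
    are reliably distinguished at the study's sample sizes (35 vs 25)."""
    m1 = table.get("M1 macrophages", "in_vivo")
    m2 = table.get("M2 macrophages", "in_vivo")
    rejections = 0
    for seed in range(20):
        a = [c.true_tau1 for c in sample_cells(m1, 35, seed=seed)]
        b = [c.true_tau1 for c in sample_cells(m2, 25, seed=1000 + seed)]
        rejections += ks_compare(a, b)[2]
    assert rejections >= 19


def test_ks_type_one_error_rate_near_alpha(table):
    row = table.get("M1 macrophages", "in_vivo")
    rejections = 0
    trials = 300
    for seed in range(trials):
        a = [c.true_tau1 for c in sample_cells(row, 30, seed=2 * seed)]
        b = [c.true_tau1 for c in sample_cells(row, 30, seed=2 * seed + 1)]
        rejections += ks_compare(a, b)[2]
    rate = rejections / trials
    assert 0.005 <= rate <= 0.12  # near the nominal 5%


def test_ks_empty_sample_rejected():
    with pytest.raises(ValueError):
        ks_compare([], [1.0, 2.0])
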