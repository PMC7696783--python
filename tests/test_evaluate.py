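"""Evaluation protocol: balancing, cross-validation, ROC, thresholds, reports."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from breathnet import (CANCER, HEALTHY, CVConfig, CVResult, NetworkConfig,
                       balance_dataset, confusion_report, cross_validate,
                       roc_curve, scatter_report, select_threshold)
from breathnet.exceptions import (BalancingError, FoldConstructionError,
                                  ParameterError, ROCUndefinedError)
from conftest import make_feature_cohort

FAST_NET = NetworkConfig(hidden_dim=8, max_epochs=400,
                         validation_check_interval=25, patience=4, seed=0)


def _result(healthy_scores, cancer_scores):
    scores = np.concatenate([healthy_scores, cancer_scores])
    labels = ([HEALTHY] * len(healthy_scores) + [CANCER] * len(cancer_scores))
    ids = [f"s{i}" for i in range(len(scores))]
    return CVResult(subject_ids=ids, y_true=labels, scores=scores,
                    fold_assignment={i: 0 for i in ids})


def _auc_by_pair_counting(healthy_scores, cancer_scores):
    """Independent oracle: exhaustive concordant-pair count, ties half."""
    total = 0.0
    for c in cancer_scores:
        for h in healthy_scores:
            if c > h:
                total += 1.0
            elif c == h:
                total += 0.5
    return total / (len(healthy_scores) * len(cancer_scores))


# -- balancing ------------------------------------------------------------

def test_balance_undersamples_majority():
    cohort = make_feature_cohort(69, 21, seed=0)
    balanced = balance_dataset(cohort, seed=5)
    labels = [f.label for f in balanced]
    assert len(balanced) == 42
    assert labels.count(HEALTHY) == 21 and labels.count(CANCER) == 21
    # every minority subject retained
    cancer_ids = {f.subject_id for f in cohort if f.label == CANCER}
    assert cancer_ids <= {f.subject_id for f in balanced}


def test_balance_already_even_keeps_everyone():
    cohort = make_feature_cohort(31, 31, seed=0)
    balanced = balance_dataset(cohort, seed=1)
    assert {f.subject_id for f in balanced} == {f.subject_id for f in cohort}


def test_balance_minimal_pair():
    cohort = make_feature_cohort(1, 1, seed=0)
    assert len(balance_dataset(cohort, seed=0)) == 2


def test_balance_missing_class_errors():
    cohort = make_feature_cohort(4, 0, seed=0)
    with pytest.raises(BalancingError):
        balance_dataset(cohort, seed=0)


def test_balance_deterministic_in_seed():
    cohort = make_feature_cohort(10, 4, seed=0)
    a = [f.subject_id for f in balance_dataset(cohort, seed=3)]
    b = [f.subject_id for f in balance_dataset(cohort, seed=3)]
    assert a == b


# -- cross-validation -----------------------------------------------------

def test_loo_scores_every_subject_once():
    features = make_feature_cohort(6, 6, effect=3.0, seed=1)
    result = cross_validate(features, CVConfig(scheme="leave-one-out"),
                            FAST_NET)
    assert len(result.scores) == 12
    assert sorted(result.subject_ids) == sorted(f.subject_id
                                                for f in features)
    assert len(set(result.fold_assignment.values())) == 12
    assert np.all((result.scores > -1) & (result.scores < 1))


def test_kfold_with_k_equal_n_matches_loo_structure():
    features = make_feature_cohort(4, 4, effect=3.0, seed=2)
    cv = CVConfig(scheme="k-fold", k=8, stratified=False, seed=0)
    result = cross_validate(features, cv, FAST_NET)
    # every fold holds out exactly one subject, as in leave-one-out
    folds = list(result.fold_assignment.values())
    assert sorted(np.bincount(folds)) == [1] * 8


def test_single_class_training_fold_rejected():
    features = make_feature_cohort(3, 1, seed=0)
    with pytest.raises(FoldConstructionError):
        cross_validate(features, CVConfig(scheme="leave-one-out"), FAST_NET)


def test_separable_cohort_reaches_high_auc():
    features = make_feature_cohort(8, 8, effect=4.0, noise=0.2, seed=3)
    result = cross_validate(features,
                            CVConfig(scheme="k-fold", k=4, seed=0), FAST_NET)
    assert roc_curve(result).auc >= 0.95


def test_auc_monotone_over_effect_grid():
    """Separability recovery: AUC non-decreasing in the class effect."""
    aucs = []
    for effect in (0.0, 1.0, 4.0):
        features = make_feature_cohort(7, 7, effect=effect, noise=0.3, seed=4)
        result = cross_validate(
            features, CVConfig(scheme="k-fold", k=7, seed=0), FAST_NET)
        aucs.append(roc_curve(result).auc)
    assert aucs[0] - 0.2 <= aucs[1] <= aucs[2] + 1e-9
    assert aucs[2] >= 0.9


# -- ROC ------------------------------------------------------------------

def test_perfect_separation_auc_one():
    roc = roc_curve(_result([-0.9, -0.5], [0.5, 0.9]))
    assert roc.auc == pytest.approx(1.0)
    assert roc.fpr[0] == 0.0 and roc.tpr[0] == 0.0
    assert roc.fpr[-1] == 1.0 and roc.tpr[-1] == 1.0


def test_all_tied_scores_auc_half():
    roc = roc_curve(_result([0.2, 0.2], [0.2, 0.2]))
    assert roc.auc == pytest.approx(0.5)


def test_four_point_auc_three_quarters():
    """Exhaustive oracle: 4 pairs, 3 concordant."""
    roc = roc_curve(_result([0.1, 0.4], [0.2, 0.8]))
    assert roc.auc == pytest.approx(0.75)


def test_roc_curve_monotone_and_anchored():
    rng = np.random.default_rng(7)
    roc = roc_curve(_result(rng.normal(size=11), rng.normal(0.4, 1, size=9)))
    assert np.all(np.diff(roc.fpr) >= 0) and np.all(np.diff(roc.tpr) >= 0)
    assert (roc.fpr[0], roc.tpr[0]) == (0.0, 0.0)
    assert (roc.fpr[-1], roc.tpr[-1]) == (1.0, 1.0)


def test_single_class_roc_undefined():
    with pytest.raises(ROCUndefinedError):
        roc_curve(_result([0.1, 0.2], []))


@settings(derandomize=True, max_examples=60, deadline=None)
@given(st.data())
def test_auc_equals_pair_counting_and_sklearn(data):
    """Trapezoidal AUC == Mann-Whitney pair counting == sklearn oracle."""
    n_h = data.draw(st.integers(1, 25))
    n_c = data.draw(st.integers(1, 25))
    # quantized scores force plenty of ties
    pool = st.integers(-5, 5).map(lambda v: v / 5.0)
    h = data.draw(st.lists(pool, min_size=n_h, max_size=n_h))
    c = data.draw(st.lists(pool, min_size=n_c, max_size=n_c))
    result = _result(np.array(h), np.array(c))
    auc = roc_curve(result).auc
    assert auc == pytest.approx(_auc_by_pair_counting(h, c), abs=1e-12)
    from sklearn.metrics import roc_auc_score
    y = [0] * n_h + [1] * n_c
    assert auc == pytest.approx(roc_auc_score(y, np.concatenate([h, c])),
                                abs=1e-12)


# -- threshold selection --------------------------------------------------

def _brute_force_youden(healthy_scores, cancer_scores):
    """Exhaustive search over all cut-points (including midpoints)."""
    scores = np.concatenate([healthy_scores, cancer_scores])
    uniq = np.unique(scores)
    candidates = list(uniq) + [-np.inf] + [
        (a + b) / 2 for a, b in zip(uniq[:-1], uniq[1:])]
    best_j, best_conf = -np.inf, None
    for t in candidates:
        tpr = np.mean(np.asarray(cancer_scores) > t) if len(cancer_scores) else 0
        fpr = np.mean(np.asarray(healthy_scores) > t) if len(healthy_scores) else 0
        j = tpr - fpr
        if j > best_j + 1e-12:
            best_j, best_conf = j, (tpr, fpr)
    return best_j, best_conf


def test_threshold_perfect_separation():
    roc = roc_curve(_result([-0.9, -0.5], [0.5, 0.9]))
    t = select_threshold(roc)
    assert t == pytest.approx(-0.5)  # largest candidate below all cancers


def test_threshold_all_tied_classifies_all_negative():
    result = _result([0.3, 0.3], [0.3, 0.3])
    t = select_threshold(roc_curve(result))
    report = confusion_report(result, t)
    assert report.tp == 0 and report.fp == 0
    assert report.fn == 2 and report.tn == 2


def test_threshold_four_point_example():
    roc = roc_curve(_result([0.1, 0.4], [0.2, 0.8]))
    t = select_threshold(roc)
    assert 0.4 <= t < 0.8
    assert (roc.tpr - roc.fpr).max() == pytest.approx(0.5)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(st.data())
def test_threshold_matches_brute_force(data):
    pool = st.integers(-6, 6).map(lambda v: v / 6.0)
    h = np.array(data.draw(st.lists(pool, min_size=1, max_size=15)))
    c = np.array(data.draw(st.lists(pool, min_size=1, max_size=15)))
    result = _result(h, c)
    t = select_threshold(roc_curve(result))
    tpr = np.mean(c > t)
    fpr = np.mean(h > t)
    best_j, _ = _brute_force_youden(h, c)
    assert tpr - fpr == pytest.approx(best_j, abs=1e-12)


# -- confusion reports ----------------------------------------------------

@pytest.mark.parametrize(
    "tp,fn,tn,fp,acc,sens,spec",
    [
        # lung-cancer experiment: 1 of 21 cancers and 5 of 21 healthy wrong
        (20, 1, 16, 5, 85.71, 95.24, 76.19),
        # full-cohort experiment: 12 of 52 and 12 of 69 wrong
        (40, 12, 57, 12, 80.17, 76.92, 82.61),
        # laryngeal/oropharyngeal experiment: 10 of 31 and 4 of 31 wrong
        (21, 10, 27, 4, 77.42, 67.74, 87.10),
        (10, 0, 10, 0, 100.0, 100.0, 100.0),
    ])
def test_confusion_metric_arithmetic(tp, fn, tn, fp, acc, sens, spec):
    h = np.concatenate([np.full(tn, -0.5), np.full(fp, 0.5)])
    c = np.concatenate([np.full(tp, 0.5), np.full(fn, -0.5)])
    report = confusion_report(_result(h, c), threshold=0.0)
    assert (report.tp, report.fn, report.tn, report.fp) == (tp, fn, tn, fp)
    assert report.accuracy == pytest.approx(acc, abs=0.005)
    assert report.sensitivity == pytest.approx(sens, abs=0.005)
    assert report.specificity == pytest.approx(spec, abs=0.005)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(tp=st.integers(0, 40), fn=st.integers(0, 40),
       tn=st.integers(0, 40), fp=st.integers(0, 40))
def test_metric_identity(tp, fn, tn, fp):
    """accuracy == (sens * n_pos + spec * n_neg) / n, on raw fractions."""
    if tp + fn == 0 or tn + fp == 0:
        return
    h = np.concatenate([np.full(tn, -0.5), np.full(fp, 0.5)])
    c = np.concatenate([np.full(tp, 0.5), np.full(fn, -0.5)])
    r = confusion_report(_result(h, c), threshold=0.0)
    n_pos, n_neg = tp + fn, tn + fp
    sens = 100.0 * tp / n_pos
    spec = 100.0 * tn / n_neg
    expected_acc = (sens * n_pos + spec * n_neg) / (n_pos + n_neg)
    assert r.accuracy == pytest.approx(expected_acc, abs=0.011)
    assert r.tp + r.fn == n_pos and r.tn + r.fp == n_neg


# -- scatter report -------------------------------------------------------

def test_scatter_table_and_plot(tmp_path):
    result = _result([-0.4, -0.1, 0.2], [0.3, 0.6])
    path = tmp_path / "scatter.png"
    frame = scatter_report(result, threshold=0.1, path=str(path))
    assert len(frame) == 5
    assert list(frame["serial"]) == [0, 1, 2, 3, 4]
    assert path.exists() and path.stat().st_size > 0


def test_scatter_single_subject():
    frame = scatter_report(_result([], [0.7]), threshold=0.0)
    assert len(frame) == 1 and frame["score"].iloc[0] == 0.7


def test_scatter_empty_errors():
    with pytest.raises(ParameterError):
        scatter_report(_result([], []), threshold=0.0)
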