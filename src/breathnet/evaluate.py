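"""Evaluation protocol: class balancing, cross-validation, ROC, reporting.

Per-subject out-of-fold scores come from cross-validation in which every
fold refits the feature scaler and the network on its training subjects
only.  The ROC sweep, trapezoidal AUC, Youden-J threshold selection and
confusion metrics are implemented directly (scikit-learn serves only as an
independent oracle in the test suite).  The diagnostic rule is
"score > threshold => pathological".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import (BalancingError, FoldConstructionError,
                         ParameterError, ROCUndefinedError)
from .mlp import NetworkConfig, TanhMLPClassifier
from .preprocess import FeatureVector, fit_normalizer
from .simulate import CANCER, HEALTHY

SCHEMES = ("leave-one-out", "k-fold")


@dataclass
class CVConfig:
    """Cross-validation layout. Leave-one-out mirrors per-subject scoring."""

    scheme: str = "leave-one-out"
    k: int = 10
    stratified: bool = True
    seed: int = 0

    def validate(self, n_subjects: Optional[int] = None) -> None:
        if self.scheme not in SCHEMES:
            raise ParameterError(f"scheme must be one of {SCHEMES}")
        if self.scheme == "k-fold":
            if self.k < 2:
                raise ParameterError("k must be >= 2")
            if n_subjects is not None and self.k > n_subjects:
                raise ParameterError(
                    f"k={self.k} exceeds n_subjects={n_subjects}")


@dataclass
class CVResult:
    """Out-of-fold score for every subject, with its fold assignment."""

    subject_ids: list
    y_true: list            # class labels ("healthy"/"cancer")
    scores: np.ndarray      # out-of-fold network scores in (-1, 1)
    fold_assignment: dict   # subject_id -> fold index

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "subject_id": self.subject_ids,
            "label": self.y_true,
            "score": self.scores,
            "fold": [self.fold_assignment[s] for s in self.subject_ids],
        })


@dataclass
class ROCResult:
    """ROC points swept over all distinct scores, plus trapezoidal AUC."""

    thresholds: np.ndarray  # descending; last entry -inf closes the curve
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass
class DiagnosticReport:
    """Confusion counts and the derived percentage metrics.

    Counts are stored exactly; percentages are rounded to two decimals
    only in the derived properties and serialized dict.
    """

    threshold: float
    tp: int
    fn: int
    tn: int
    fp: int
    auc: Optional[float] = None

    @property
    def sensitivity(self) -> float:
        return round(100.0 * self.tp / (self.tp + self.fn), 2)

    @property
    def specificity(self) -> float:
        return round(100.0 * self.tn / (self.tn + self.fp), 2)

    @property
    def accuracy(self) -> float:
        total = self.tp + self.fn + self.tn + self.fp
        return round(100.0 * (self.tp + self.tn) / total, 2)

    def as_dict(self) -> dict:
        d = {"threshold": self.threshold,
             "counts": {"TP": self.tp, "FN": self.fn,
                        "TN": self.tn, "FP": self.fp},
             "accuracy_pct": self.accuracy,
             "sensitivity_pct": self.sensitivity,
             "specificity_pct": self.specificity}
        if self.auc is not None:
            d["auc"] = self.auc
        return d


def _label_of(item) -> str:
    return item.label


def balance_dataset(subjects: Sequence, seed: int) -> list:
    """Undersample the majority class to a 50/50 ratio, seeded.

    All minority-class subjects are retained; an equally sized uniform
    random subset of the majority class joins them, and the combined list
    is shuffled deterministically.
    """
    labels = np.array([_label_of(s) for s in subjects])
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2 or counts.min() == 0:
        raise BalancingError("both classes must be present to balance")
    minority = classes[np.argmin(counts)]
    majority = classes[classes != minority][0]
    rng = np.random.default_rng(seed)
    min_idx = np.flatnonzero(labels == minority)
    maj_idx = np.flatnonzero(labels == majority)
    keep_maj = rng.choice(maj_idx, size=min_idx.size, replace=False)
    kept = np.concatenate([min_idx, keep_maj])
    kept = kept[rng.permutation(kept.size)]
    return [subjects[i] for i in kept]


def _build_folds(y: np.ndarray, cv: CVConfig) -> list[np.ndarray]:
    """Test-index arrays per fold."""
    n = y.size
    if cv.scheme == "leave-one-out":
        return [np.array([i]) for i in range(n)]
    from sklearn.model_selection import KFold, StratifiedKFold
    cls = StratifiedKFold if cv.stratified else KFold
    splitter = cls(n_splits=cv.k, shuffle=True,
                   random_state=cv.seed % (2 ** 32))
    return [test for _, test in splitter.split(np.zeros((n, 1)), y)]


def cross_validate(features: Sequence[FeatureVector], cv: CVConfig,
                   net_config: NetworkConfig) -> CVResult:
    """Score every subject out-of-fold.

    Within each fold the [-1, 1] feature scaler and the network (with its
    internal early-stopping validation split) are fitted on training
    subjects only; the held-out subjects are then scored once.
    """
    n = len(features)
    if n < 2:
        raise ParameterError("cross-validation requires >= 2 subjects")
    y = np.array([fv.label for fv in features])
    if np.unique(y).size < 2:
        raise ParameterError("both classes must be present")
    cv.validate(n)

    X_raw = np.stack([fv.values for fv in features])
    targets = np.where(y == CANCER, 1, -1)
    scores = np.empty(n)
    fold_assignment: dict = {}

    for fold_idx, test_idx in enumerate(_build_folds(y, cv)):
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        y_train = targets[train_mask]
        if np.unique(y_train).size < 2:
            raise FoldConstructionError(
                f"fold {fold_idx} training data contains a single class")
        scaler = fit_normalizer([features[i]
                                 for i in np.flatnonzero(train_mask)])
        X_train = scaler.transform(X_raw[train_mask])
        X_test = scaler.transform(X_raw[test_idx])
        fold_seed = int(np.random.SeedSequence(
            [net_config.seed, fold_idx]).generate_state(1)[0]) % (2 ** 31)
        clf = TanhMLPClassifier(
            hidden_dim=net_config.hidden_dim,
            learning_rate=net_config.learning_rate,
            max_epochs=net_config.max_epochs,
            patience=net_config.patience,
            validation_check_interval=net_config.validation_check_interval,
            init_scale=net_config.init_scale,
            seed=fold_seed)
        clf.fit(X_train, y_train)
        scores[test_idx] = clf.decision_function(X_test)
        for i in test_idx:
            fold_assignment[features[i].subject_id] = fold_idx

    return CVResult(subject_ids=[fv.subject_id for fv in features],
                    y_true=list(y), scores=scores,
                    fold_assignment=fold_assignment)


def roc_curve(result: CVResult) -> ROCResult:
    """ROC sweep over all distinct scores under the "score > t" rule.

    Tied scores are grouped on one threshold, so ties move the curve
    diagonally; the trapezoidal area then equals the normalized
    Mann-Whitney U statistic with half-credit for ties.
    """
    y = np.asarray(result.y_true)
    scores = np.asarray(result.scores, dtype=float)
    pos = y == CANCER
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ROCUndefinedError("ROC requires scores from both classes")

    thresholds = np.concatenate(
        [np.unique(scores)[::-1], [-np.inf]])
    fpr = np.empty(thresholds.size)
    tpr = np.empty(thresholds.size)
    for i, t in enumerate(thresholds):
        pred_pos = scores > t
        tpr[i] = np.sum(pred_pos & pos) / n_pos
        fpr[i] = np.sum(pred_pos & ~pos) / n_neg
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


def select_threshold(roc: ROCResult) -> float:
    """Youden-J operating point: maximize TPR - FPR.

    Ties are broken toward the larger threshold (higher specificity).
    """
    j = roc.tpr - roc.fpr
    best_j = j.max()
    candidates = roc.thresholds[np.isclose(j, best_j)]
    return float(candidates.max())


def confusion_report(result: CVResult, threshold: float,
                     auc: Optional[float] = None) -> DiagnosticReport:
    """Apply the threshold rule and tabulate the diagnostic metrics."""
    y = np.asarray(result.y_true)
    scores = np.asarray(result.scores, dtype=float)
    pos = y == CANCER
    pred = scores > threshold
    return DiagnosticReport(
        threshold=float(threshold),
        tp=int(np.sum(pred & pos)), fn=int(np.sum(~pred & pos)),
        tn=int(np.sum(~pred & ~pos)), fp=int(np.sum(pred & ~pos)),
        auc=auc)


def scatter_report(result: CVResult, threshold: float,
                   path: Optional[str] = None) -> pd.DataFrame:
    """Per-subject score table (and optional scatter plot).

    Subjects are ordered by their serial index; healthy subjects are drawn
    as triangles, pathological as squares, with a horizontal threshold line.
    """
    if len(result.subject_ids) == 0:
        raise ParameterError("cannot render an empty CV result")
    frame = result.to_frame().reset_index(names="serial")
    if path is not None:
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(8, 4))
        for label, marker in ((HEALTHY, "^"), (CANCER, "s")):
            sub = frame[frame["label"] == label]
            ax.scatter(sub["serial"], sub["score"], marker=marker,
                       label=label)
        ax.axhline(threshold, color="grey", linestyle="--",
                   label=f"threshold = {threshold:.3g}")
        ax.set_xlabel("subject serial number")
        ax.set_ylabel("network score")
        ax.set_ylim(-1.05, 1.05)
        ax.legend()
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return frame


def save_roc_plot(roc: ROCResult, path: str) -> None:
    """ROC curve with the chance diagonal, saved as an image."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(roc.fpr, roc.tpr, "k-", label=f"ROC (AUC = {roc.auc:.3f})")
    ax.plot([0, 1], [0, 1], color="grey", label="reference")
    ax.scatter(roc.fpr, roc.tpr, marker="x", color="grey", s=20)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
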