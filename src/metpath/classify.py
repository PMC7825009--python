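"""Diagnosis classification: six classical algorithms plus the deep net.

The evaluation harness mirrors common practice for moderate-size
metabolomics cohorts: repeated stratified ~4:1 train/test splits, with
k-fold cross-validation inside the training split providing the
training-side metrics, test-side metrics from the held-out fifth, and
per-repeat values retained so algorithms can be compared with paired
one-tailed t-tests.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .deepnet import DeepNetClassifier, DeepNetConfig

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "ClassificationReport",
    "ALGORITHMS",
    "compute_metrics",
    "confusion_counts",
    "evaluate_classifiers",
    "train_deepnet",
    "compare_algorithms",
]

ALGORITHMS = ("DL", "GBM", "LDA", "LOG", "RF", "RPART", "SVM")


@dataclass
class ConfusionCounts:
    """2x2 confusion counts with the case class as positive."""

    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class MetricSet:
    """Accuracy, sensitivity, specificity, F1 and balanced accuracy.

    Balanced accuracy is the arithmetic mean of sensitivity and
    specificity.  A ratio with zero denominator is reported as 0 and
    flagged via ``undefined``.
    """

    accuracy: float
    sensitivity: float
    specificity: float
    f1: float
    balanced_accuracy: float
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "f1": self.f1,
            "balanced_accuracy": self.balanced_accuracy,
        }


def compute_metrics(counts: ConfusionCounts) -> MetricSet:
    """Classification metrics from confusion counts."""
    if counts.total == 0:
        raise ValueError("no evaluated samples")
    undefined = []

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    acc = (counts.TP + counts.TN) / counts.total
    sens = ratio(counts.TP, counts.TP + counts.FN, "sensitivity")
    spec = ratio(counts.TN, counts.TN + counts.FP, "specificity")
    prec = ratio(counts.TP, counts.TP + counts.FP, "precision")
    f1 = ratio(2 * prec * sens, prec + sens, "f1")
    return MetricSet(acc, sens, spec, f1, (sens + spec) / 2.0, tuple(undefined))


def confusion_counts(y_true, y_pred, positive) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos_t, pos_p = y_true == positive, y_pred == positive
    return ConfusionCounts(
        TP=int(np.sum(pos_t & pos_p)),
        FP=int(np.sum(~pos_t & pos_p)),
        TN=int(np.sum(~pos_t & ~pos_p)),
        FN=int(np.sum(pos_t & ~pos_p)),
    )


def _make_estimator(name: str, seed: int, deepnet_config: DeepNetConfig | None):
    if name == "GBM":
        return GradientBoostingClassifier(random_state=seed)
    if name == "LDA":
        return LinearDiscriminantAnalysis()
    if name == "LOG":
        return LogisticRegression(max_iter=2000, random_state=seed)
    if name == "RF":
        return RandomForestClassifier(random_state=seed)
    if name == "RPART":
        return DecisionTreeClassifier(random_state=seed)
    if name == "SVM":
        return SVC(random_state=seed)
    if name == "DL":
        cfg = deepnet_config or DeepNetConfig()
        from dataclasses import replace

        return DeepNetClassifier(replace(cfg, seed=seed))
    raise ValueError(f"unknown algorithm {name!r}")


def _clone_est(est):
    if isinstance(est, DeepNetClassifier):
        return DeepNetClassifier(est.config)
    return clone(est)


@dataclass
class ClassificationReport:
    """Per-algorithm metrics averaged over repeats.

    ``train`` / ``test`` hold the averaged MetricSet per algorithm;
    ``per_repeat`` keeps the raw per-repeat test metrics for paired
    significance testing; ``wall_time`` is mean seconds per fit.
    """

    train: dict[str, MetricSet]
    test: dict[str, MetricSet]
    per_repeat: pd.DataFrame
    wall_time: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for split, metrics in (("train", self.train), ("test", self.test)):
            for algo, m in metrics.items():
                rows.append({"split": split, "algorithm": algo,
                             "wall_time_s": self.wall_time[algo], **m.as_dict()})
        return pd.DataFrame(rows)


def _mean_metrics(sets: list[MetricSet]) -> MetricSet:
    arr = np.array([[m.accuracy, m.sensitivity, m.specificity, m.f1, m.balanced_accuracy]
                    for m in sets]).mean(axis=0)
    return MetricSet(*[float(v) for v in arr])


def evaluate_classifiers(
    features,
    labels,
    algorithms=ALGORITHMS,
    cv_folds: int = 10,
    test_frac: float = 0.2,
    repeats: int = 10,
    seed: int = 0,
    deepnet_config: DeepNetConfig | None = None,
) -> ClassificationReport:
    """Repeated stratified train/test evaluation of the chosen algorithms.

    Per repeat: stratified split (``test_frac`` held out), ``cv_folds``
    cross-validation inside the training split (training metrics are
    the pooled out-of-fold confusion counts), refit on the whole
    training split, evaluation on the held-out test split.  The same
    seed always yields the same report.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("evaluate_classifiers requires exactly two classes")
    positive = classes[1]
    n_min = min(np.sum(y == c) for c in classes)
    unknown = set(algorithms) - set(ALGORITHMS)
    if unknown:
        raise ValueError(f"unknown algorithms: {sorted(unknown)}")

    train_sets: dict[str, list[MetricSet]] = {a: [] for a in algorithms}
    test_sets: dict[str, list[MetricSet]] = {a: [] for a in algorithms}
    times: dict[str, list[float]] = {a: [] for a in algorithms}
    rows = []
    for rep in range(repeats):
        rep_seed = seed * 1000 + rep
        Xtr, Xte, ytr, yte = train_test_split(
            X, y, test_size=test_frac, stratify=y, random_state=rep_seed
        )
        eff_folds = min(cv_folds, int(np.min([np.sum(ytr == c) for c in classes])))
        if eff_folds < 2:
            raise ValueError("too few samples per class for cross-validation")
        skf = StratifiedKFold(n_splits=eff_folds, shuffle=True, random_state=rep_seed)
        for algo in algorithms:
            est = _make_estimator(algo, rep_seed, deepnet_config)
            t0 = time.perf_counter()
            # out-of-fold predictions inside the training split
            oof = np.empty(len(ytr), dtype=y.dtype)
            for tr_idx, va_idx in skf.split(Xtr, ytr):
                fold_est = _clone_est(est)
                fold_est.fit(Xtr[tr_idx], ytr[tr_idx])
                pred = fold_est.predict(Xtr[va_idx])
                if isinstance(fold_est, DeepNetClassifier):
                    pred = fold_est.classes_[pred]
                oof[va_idx] = pred
            est.fit(Xtr, ytr)
            pred_te = est.predict(Xte)
            if isinstance(est, DeepNetClassifier):
                pred_te = est.classes_[pred_te]
            elapsed = time.perf_counter() - t0
            m_tr = compute_metrics(confusion_counts(ytr, oof, positive))
            m_te = compute_metrics(confusion_counts(yte, pred_te, positive))
            train_sets[algo].append(m_tr)
            test_sets[algo].append(m_te)
            times[algo].append(elapsed)
            rows.append({"repeat": rep, "algorithm": algo, **m_te.as_dict()})

    return ClassificationReport(
        train={a: _mean_metrics(v) for a, v in train_sets.items()},
        test={a: _mean_metrics(v) for a, v in test_sets.items()},
        per_repeat=pd.DataFrame(rows),
        wall_time={a: float(np.mean(v)) for a, v in times.items()},
    )


def train_deepnet(features, labels, config: DeepNetConfig) -> tuple[DeepNetClassifier, MetricSet]:
    """Train the deep net with an explicit config; returns the fitted
    model and its training-set metrics."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    clf = DeepNetClassifier(config).fit(X, y)
    pred = clf.classes_[clf.predict(X)]
    return clf, compute_metrics(confusion_counts(y, pred, positive=clf.classes_[1]))


def compare_algorithms(
    report: ClassificationReport, reference: str = "DL", metric: str = "f1"
) -> pd.DataFrame:
    """Paired one-tailed t-tests of each algorithm against a reference.

    Tests H1: reference > other on the per-repeat test metric.
    """
    per = report.per_repeat.pivot(index="repeat", columns="algorithm", values=metric)
    if reference not in per.columns:
        raise ValueError(f"reference algorithm {reference!r} not in report")
    rows = []
    for algo in per.columns:
        if algo == reference:
            continue
        t, p = stats.ttest_rel(per[reference], per[algo], alternative="greater")
        rows.append({"algorithm": algo, "t": float(t), "p_value": float(p)})
    return pd.DataFrame(rows)
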