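"""Linear-SVM myopia predictor and the evaluation harness.

The classifier is a soft-margin SVM with linear kernel and penalty C = 1.0
(library default), calibrated to emit class-1 probabilities (Platt-type
sigmoid on the decision values); a student is called myopic when the
probability strictly exceeds the threshold (default 0.5). The harness
computes confusion-matrix metrics, ROC/AUC by threshold sweep, stratified
k-fold cross-validation, and a comparison table against standard baselines
(logistic regression, Gaussian naive Bayes, KNN, random forest, and a
small back-propagation network).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from ._utils import ConfigError, SchemaError
from .transform import FeatureMatrix

logger = logging.getLogger(__name__)

# Platt-calibrated SVC probabilities are a deliberate design choice here;
# silence scikit-learn's deprecation nudge towards CalibratedClassifierCV.
warnings.filterwarnings(
    "ignore", message=".*`probability` parameter was deprecated.*",
    category=FutureWarning,
)

__all__ = [
    "ModelConfig",
    "ConfusionCounts",
    "EvalReport",
    "train_classifier",
    "predict_labels",
    "confusion",
    "compute_metrics",
    "roc_auc",
    "kfold_cv",
    "evaluate_classifier",
    "run_baselines",
    "BASELINE_FACTORIES",
]


@dataclass
class ModelConfig:
    """SVM and evaluation settings (penalty, threshold, CV folds, seed)."""

    C: float = 1.0
    kernel: str = "linear"
    probability_threshold: float = 0.5
    cv_folds: int = 10
    test_size: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.C <= 0:
            raise ConfigError("C must be > 0")
        if not (0.0 < self.probability_threshold < 1.0):
            raise ConfigError("probability_threshold must lie in (0, 1)")
        if self.cv_folds < 2:
            raise ConfigError("cv_folds must be >= 2")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class EvalReport:
    """All headline metrics for one classifier on one evaluation split."""

    accuracy: float
    precision: float
    sensitivity: float
    specificity: float
    f1: float
    auc: float
    cv_mean: float
    cv_scores: list[float] = field(default_factory=list)
    roc_points: np.ndarray | None = None
    counts: ConfusionCounts | None = None
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "f1": self.f1,
            "auc": self.auc,
            "cv_mean": self.cv_mean,
        }


def _unpack(features) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(features, FeatureMatrix):
        return features.values, features.label
    raise ConfigError("expected a FeatureMatrix")


def _svm(config: ModelConfig) -> SVC:
    return SVC(
        kernel=config.kernel, C=config.C, probability=True,
        random_state=config.seed,
    )


def train_classifier(features: FeatureMatrix, config: ModelConfig):
    """Fit the probability-calibrated linear SVM on all rows."""
    config.validate()
    X, y = _unpack(features)
    if len(np.unique(y)) < 2:
        raise ConfigError("training data contains a single class")
    if np.isnan(X).any():
        raise ConfigError("feature matrix contains missing values")
    clf = _svm(config)
    clf.fit(X, y)
    clf._n_features = X.shape[1]
    return clf


def predict_labels(clf, features, threshold: float = 0.5):
    """Class-1 probabilities and thresholded labels (strictly greater than)."""
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    expected = getattr(clf, "_n_features", getattr(clf, "n_features_in_", None))
    if expected is not None and X.shape[1] != expected:
        raise SchemaError(f"expected {expected} feature columns, got {X.shape[1]}")
    probs = clf.predict_proba(X)[:, 1]
    labels = (probs > threshold).astype(int)
    return probs, labels


def confusion(true_labels, pred_labels) -> ConfusionCounts:
    """2x2 cross-tabulation; the positive class is myopic (label 1)."""
    t = np.asarray(true_labels)
    p = np.asarray(pred_labels)
    if len(t) != len(p):
        raise ConfigError("label vectors must have equal length")
    for arr in (t, p):
        if not np.isin(arr, [0, 1]).all():
            raise ConfigError("labels must be binary 0/1")
    return ConfusionCounts(
        tp=int(((t == 1) & (p == 1)).sum()),
        fp=int(((t == 0) & (p == 1)).sum()),
        tn=int(((t == 0) & (p == 0)).sum()),
        fn=int(((t == 1) & (p == 0)).sum()),
    )


def compute_metrics(counts: ConfusionCounts) -> EvalReport:
    """Accuracy, precision, sensitivity, specificity and f1 from counts.

    A metric with a zero denominator is reported as 0 with a warning flag
    rather than raising; all-zero counts are an error.
    """
    if counts.total == 0:
        raise ConfigError("cannot compute metrics from zero samples")
    warns: list[str] = []

    def safe(num, den, name):
        if den == 0:
            warns.append(f"{name} undefined (zero denominator); reported 0")
            return 0.0
        return num / den

    precision = safe(counts.tp, counts.tp + counts.fp, "precision")
    sensitivity = safe(counts.tp, counts.tp + counts.fn, "sensitivity")
    specificity = safe(counts.tn, counts.tn + counts.fp, "specificity")
    f1 = safe(2 * precision * sensitivity, precision + sensitivity, "f1")
    return EvalReport(
        accuracy=(counts.tp + counts.tn) / counts.total,
        precision=precision,
        sensitivity=sensitivity,
        specificity=specificity,
        f1=f1,
        auc=float("nan"),
        cv_mean=float("nan"),
        counts=counts,
        warnings=warns,
    )


def roc_auc(probabilities, true_labels) -> tuple[np.ndarray, float]:
    """ROC by sweeping unique score thresholds; AUC by the trapezoidal rule.

    Tied scores step simultaneously. The curve starts at (0, 0) and ends at
    (1, 1); both classes must be present.
    """
    y = np.asarray(true_labels)
    s = np.asarray(probabilities, dtype=float)
    if len(np.unique(y)) < 2:
        raise ConfigError("ROC requires both classes present")
    fpr, tpr, _ = roc_curve(y, s)
    points = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(tpr, fpr))
    return points, auc


def kfold_cv(
    features: FeatureMatrix,
    config: ModelConfig,
    estimator=None,
) -> tuple[float, list[float]]:
    """Stratified k-fold accuracy with a seeded shuffle.

    Folds are disjoint and cover every row; the mean fold accuracy is the
    cross-validation score. ``estimator`` defaults to the pipeline's SVM.
    """
    config.validate()
    X, y = _unpack(features)
    if len(y) < config.cv_folds:
        raise ConfigError("need at least cv_folds samples")
    base = estimator if estimator is not None else _svm(config)
    skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    scores = []
    for train_idx, test_idx in skf.split(X, y):
        est = clone(base)
        est.fit(X[train_idx], y[train_idx])
        scores.append(float((est.predict(X[test_idx]) == y[test_idx]).mean()))
    return float(np.mean(scores)), scores


def evaluate_classifier(
    features: FeatureMatrix,
    config: ModelConfig,
    estimator=None,
) -> EvalReport:
    """Full harness: stratified 80/20 holdout metrics + k-fold CV + ROC."""
    config.validate()
    X, y = _unpack(features)
    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx, test_size=config.test_size, stratify=y, random_state=config.seed
    )
    base = estimator if estimator is not None else _svm(config)
    est = clone(base)
    est.fit(X[train_idx], y[train_idx])
    probs = est.predict_proba(X[test_idx])[:, 1]
    labels = (probs > config.probability_threshold).astype(int)
    report = compute_metrics(confusion(y[test_idx], labels))
    report.roc_points, report.auc = roc_auc(probs, y[test_idx])
    report.cv_mean, report.cv_scores = kfold_cv(features, config, estimator=base)
    return report


BASELINE_FACTORIES = {
    "Logistic Regression": lambda seed: LogisticRegression(max_iter=1000),
    "Naive Bayes": lambda seed: GaussianNB(),
    "KNN": lambda seed: KNeighborsClassifier(),
    "Random Forest": lambda seed: RandomForestClassifier(random_state=seed),
    "BP Neural Network": lambda seed: MLPClassifier(
        hidden_layer_sizes=(16,), max_iter=2000, random_state=seed
    ),
}


def run_baselines(
    features: FeatureMatrix,
    config: ModelConfig,
    baselines: list[str] | None = None,
) -> pd.DataFrame:
    """Comparison table: the SVM and each baseline under the identical
    holdout/CV harness. A baseline that fails to fit gets a ``failed`` row
    without affecting the others."""
    names = baselines if baselines is not None else list(BASELINE_FACTORIES)
    rows = []
    methods = {"SVM (linear, C=1.0)": lambda seed: _svm(config)}
    for name in names:
        methods[name] = BASELINE_FACTORIES[name]
    for name, factory in methods.items():
        try:
            report = evaluate_classifier(features, config, estimator=factory(config.seed))
            rows.append({
                "Method": name,
                "Accuracy": report.accuracy,
                "CV10": report.cv_mean,
                "Precision": report.precision,
                "Sensitivity": report.sensitivity,
                "f1": report.f1,
                "AUC": report.auc,
                "Specificity": report.specificity,
                "Status": "ok",
            })
        except Exception as exc:  # noqa: BLE001 - isolate baseline failures
            logger.warning("baseline %s failed: %s", name, exc)
            rows.append({"Method": name, "Status": f"failed: {exc}"})
    return pd.DataFrame(rows)
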