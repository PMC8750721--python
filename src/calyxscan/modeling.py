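"""PCA feature extraction, the classifier bank, CV and metrics.

The pixel classifiers operate either on the raw preprocessed spectra or on
the leading principal-component scores (default: 3 components, which on data
like these carry >98% of the variance).  Six classifier families are exposed
under short tags; "infested" is the positive class throughout and per-class
precision/recall/F1 plus overall accuracy are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.cross_decomposition import PLSRegression
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import (AdaBoostClassifier, GradientBoostingClassifier,
                              RandomForestClassifier)
from sklearn.metrics import precision_recall_fscore_support
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .errors import AlignmentError, DegenerateLabelError, ParameterError

POSITIVE_CLASS = "infested"
CLASSIFIER_TAGS = ("lda", "knn", "svm", "rf", "gtb", "plsda", "adaboost")


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean F1 = 2RP/(R+P); 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * recall * precision / (recall + precision)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaModel:
    """Principal components of the training spectra.

    ``loadings`` holds orthonormal eigenvectors of the covariance matrix as
    columns (B×K); sign fixed so each column's largest-magnitude entry is
    positive.  ``explained_variance`` are the covariance eigenvalues.
    """

    mean: np.ndarray
    loadings: np.ndarray
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray


def fit_pca(train_spectra: np.ndarray, k) -> PcaModel:
    """Fit PCA by SVD of the centred matrix.

    ``k`` is either a component count (int) or a cumulative explained-variance
    target in (0, 1] (float): the smallest K whose cumulative ratio reaches
    the target is kept.
    """
    x = np.asarray(train_spectra, dtype=np.float64)
    n, b = x.shape
    if n < 2:
        raise ParameterError("PCA needs at least 2 observations")
    mean = x.mean(axis=0)
    _, s, vt = np.linalg.svd(x - mean, full_matrices=False)
    ev = s ** 2 / (n - 1)
    total = ev.sum()
    ratio = ev / total if total > 0 else np.zeros_like(ev)

    max_k = min(n - 1, b)
    # int → component count; float → cumulative-variance target (1.0 = all)
    if isinstance(k, (float, np.floating)):
        if not 0 < k <= 1:
            raise ParameterError(f"variance target must be in (0, 1], got {k}")
        n_comp = int(np.searchsorted(np.cumsum(ratio), k - 1e-12) + 1)
        n_comp = min(n_comp, max_k)
    else:
        n_comp = int(k)
        if not 1 <= n_comp <= max_k:
            raise ParameterError(f"k={n_comp} outside [1, min(N-1, B)={max_k}]")

    loadings = vt[:n_comp].T.copy()
    # sign convention: largest-|entry| of each component positive (ties→lower idx)
    for j in range(n_comp):
        if loadings[np.argmax(np.abs(loadings[:, j])), j] < 0:
            loadings[:, j] = -loadings[:, j]
    return PcaModel(mean, loadings, ev[:n_comp], ratio[:n_comp])


def transform_pca(model: PcaModel, spectra: np.ndarray) -> np.ndarray:
    """Project spectra onto the fitted components: (x − mean)·loadings."""
    x = np.atleast_2d(np.asarray(spectra, dtype=np.float64))
    if x.shape[1] != len(model.mean):
        raise AlignmentError(
            f"{x.shape[1]} bands in input, model fitted on {len(model.mean)}"
        )
    return (x - model.mean) @ model.loadings


# ---------------------------------------------------------------------------
# Classifier bank
# ---------------------------------------------------------------------------

class PLSDAClassifier(BaseEstimator, ClassifierMixin):
    """PLS-DA: PLS regression on a {0,1}-coded response, 0.5 threshold."""

    def __init__(self, n_components: int = 10):
        self.n_components = n_components

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise DegenerateLabelError("PLS-DA requires exactly two classes")
        coded = (np.asarray(y) == self.classes_[1]).astype(float)
        k = min(self.n_components, X.shape[1], X.shape[0] - 1)
        self.pls_ = PLSRegression(n_components=k)
        self.pls_.fit(X, coded)
        return self

    def predict(self, X):
        score = self.pls_.predict(np.asarray(X, dtype=np.float64)).ravel()
        return np.where(score > 0.5, self.classes_[1], self.classes_[0])


_DEFAULTS = {
    "lda": {},
    "knn": {"n_neighbors": 5},
    "svm": {"kernel": "rbf", "C": 1.0},
    "rf": {"n_estimators": 500},
    "gtb": {"n_estimators": 500, "max_depth": 3, "learning_rate": 0.1},
    "plsda": {"n_components": 10},
    "adaboost": {"n_estimators": 100},
}
_SEEDED = {"rf", "gtb", "adaboost", "svm"}


def make_classifier(tag: str, hyperparams: dict | None = None, seed: int = 0):
    """Unfitted estimator for a classifier tag with logged default settings."""
    tag = tag.lower()
    if tag not in CLASSIFIER_TAGS:
        raise ParameterError(f"unknown classifier tag '{tag}'")
    params = dict(_DEFAULTS[tag])
    params.update(hyperparams or {})
    if tag in _SEEDED and tag != "svm":
        params.setdefault("random_state", seed)
    cls = {
        "lda": LinearDiscriminantAnalysis,
        "knn": KNeighborsClassifier,
        "svm": SVC,
        "rf": RandomForestClassifier,
        "gtb": GradientBoostingClassifier,
        "plsda": PLSDAClassifier,
        "adaboost": AdaBoostClassifier,
    }[tag]
    return cls(**params)


def train_classifier(tag: str, features: np.ndarray, labels: np.ndarray,
                     hyperparams: dict | None = None, seed: int = 0):
    """Fit a classifier from the bank; requires both classes present."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise DegenerateLabelError("training labels contain a single class")
    model = make_classifier(tag, hyperparams, seed)
    model.fit(np.asarray(features, dtype=np.float64), labels)
    return model


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass
class ClassificationReport:
    """Per-class precision/recall/F1 and overall accuracy for one partition."""

    per_class: dict
    accuracy: float
    n_observations: int
    partition: str = ""
    classifier: str = ""
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "classifier": self.classifier,
            "partition": self.partition,
            "n_observations": self.n_observations,
            "accuracy": self.accuracy,
            "per_class": self.per_class,
            "config": self.config,
        }


def report_from_predictions(labels, predicted, partition: str = "",
                            classifier: str = "") -> ClassificationReport:
    labels = np.asarray(labels)
    predicted = np.asarray(predicted)
    classes = sorted(set(labels) | set(predicted))
    p, r, f1, _ = precision_recall_fscore_support(
        labels, predicted, labels=classes, zero_division=0
    )
    per_class = {
        c: {"precision": float(p[i]), "recall": float(r[i]), "f1": float(f1[i])}
        for i, c in enumerate(classes)
    }
    return ClassificationReport(
        per_class=per_class,
        accuracy=float(np.mean(labels == predicted)),
        n_observations=len(labels),
        partition=partition,
        classifier=classifier,
    )


def evaluate(model, features, labels, partition: str = "validation",
             classifier_tag: str = "") -> ClassificationReport:
    """Predict and score; metrics per class with 'infested' as the positive class."""
    pred = model.predict(np.asarray(features, dtype=np.float64))
    return report_from_predictions(labels, pred, partition, classifier_tag)


def cross_validate(tag: str, features, labels, folds: int = 5, seed: int = 0,
                   hyperparams: dict | None = None) -> dict:
    """Stratified k-fold CV; returns mean ± sd accuracy and per-fold reports."""
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    if len(labels) < folds:
        raise ParameterError(f"n={len(labels)} < folds={folds}")
    if len(np.unique(labels)) < 2:
        raise DegenerateLabelError("CV labels contain a single class")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    proto = make_classifier(tag, hyperparams, seed)
    reports, accs = [], []
    for i, (tr, te) in enumerate(skf.split(features, labels)):
        model = clone(proto)
        model.fit(features[tr], labels[tr])
        rep = evaluate(model, features[te], labels[te],
                       partition=f"cv-fold-{i}", classifier_tag=tag)
        reports.append(rep)
        accs.append(rep.accuracy)
    return {
        "classifier": tag,
        "folds": folds,
        "seed": seed,
        "mean_accuracy": float(np.mean(accs)),
        "sd_accuracy": float(np.std(accs, ddof=0)),
        "fold_reports": reports,
    }
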