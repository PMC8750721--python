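"""Sequential forward selection of informative wavebands.

A wrapper selector: starting from the empty set, each iteration tries every
unselected band appended to the current set, scores the candidate set by
stratified cross-validated accuracy (or F1) with a fixed classifier, and
keeps the argmax.  The fold assignment is frozen once per run so the greedy
path is deterministic given the seed; ties break toward the lower band index.
No early stopping: the full accuracy-vs-k curve is returned so the user can
read off the plateau (in practice a couple dozen bands out of hundreds).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold

from .errors import DegenerateLabelError, ParameterError
from .modeling import (POSITIVE_CLASS, evaluate, make_classifier,
                       report_from_predictions)
from .split import SplitResult, kennard_stone


@dataclass
class SfsResult:
    """Ordered selected bands plus the accuracy-after-each-addition curve."""

    selected_band_indices: list
    selected_wavelengths_nm: list
    accuracy_curve: list
    classifier: str
    cv_folds: int
    seed: int
    criterion: str = "accuracy"
    config: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=float)

    def to_csv(self, path) -> None:
        pd.DataFrame({
            "order": np.arange(1, len(self.selected_band_indices) + 1),
            "band_index": self.selected_band_indices,
            "wavelength_nm": self.selected_wavelengths_nm,
            self.criterion: self.accuracy_curve,
        }).to_csv(path, index=False)


def _cv_score(proto, features, labels, fold_pairs, criterion: str) -> float:
    scores = []
    for tr, te in fold_pairs:
        model = clone(proto)
        model.fit(features[tr], labels[tr])
        pred = model.predict(features[te])
        if criterion == "accuracy":
            scores.append(np.mean(pred == labels[te]))
        else:  # f1 of the positive class
            rep = report_from_predictions(labels[te], pred)
            scores.append(rep.per_class.get(POSITIVE_CLASS, {"f1": 0.0})["f1"])
    return float(np.mean(scores))


def sfs_select(features: np.ndarray, labels: np.ndarray,
               classifier_tag: str = "gtb", max_k: int = 30, folds: int = 5,
               seed: int = 0, hyperparams: dict | None = None,
               wavelengths: np.ndarray | None = None,
               criterion: str = "accuracy") -> SfsResult:
    """Greedy forward band selection with a frozen CV fold assignment.

    The default criterion classifier is gradient tree boosting in a cheaper
    profile (100 trees) than the final model; override via ``hyperparams``.
    """
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    n, b = features.shape
    if max_k < 1:
        raise ParameterError(f"max_k must be >= 1, got {max_k}")
    if max_k > b:
        raise ParameterError(f"max_k={max_k} exceeds band count {b}")
    if len(np.unique(labels)) < 2:
        raise DegenerateLabelError("SFS needs both classes present")
    if criterion not in ("accuracy", "f1"):
        raise ParameterError(f"unknown criterion '{criterion}'")

    if classifier_tag == "gtb" and hyperparams is None:
        hyperparams = {"n_estimators": 100}
    proto = make_classifier(classifier_tag, hyperparams, seed)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_pairs = list(skf.split(np.zeros((n, 1)), labels))  # frozen folds

    selected: list[int] = []
    curve: list[float] = []
    remaining = list(range(b))
    for _ in range(max_k):
        scores = np.array([
            _cv_score(proto, features[:, selected + [j]], labels,
                      fold_pairs, criterion)
            for j in remaining
        ])
        best = int(np.argmax(scores))  # first occurrence → lower band index
        selected.append(remaining.pop(best))
        curve.append(float(scores[best]))

    wl = (np.asarray(wavelengths)[selected].tolist()
          if wavelengths is not None else [float(i) for i in selected])
    return SfsResult(
        selected_band_indices=selected,
        selected_wavelengths_nm=wl,
        accuracy_curve=curve,
        classifier=classifier_tag,
        cv_folds=folds,
        seed=seed,
        criterion=criterion,
        config={"hyperparams": hyperparams or {}},
    )


def subset_report(features: np.ndarray, labels: np.ndarray, band_subset,
                  classifier_tag: str = "gtb", split: SplitResult | None = None,
                  seed: int = 0, hyperparams: dict | None = None):
    """Train/validate a classifier restricted to ``band_subset``.

    The 70/30 Kennard–Stone split is computed on the *full*-band features
    (so reports for different subsets share one partition) unless a
    precomputed ``split`` is supplied.  Returns the validation
    :class:`~calyxscan.modeling.ClassificationReport`.
    """
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    band_subset = list(band_subset)
    if not band_subset:
        raise ParameterError("band subset is empty")
    if any(j < 0 or j >= features.shape[1] for j in band_subset):
        raise ParameterError(f"band index out of range in {band_subset}")
    if split is None:
        split = kennard_stone(features, 0.7)
    sub = features[:, band_subset]
    model = make_classifier(classifier_tag, hyperparams, seed)
    model.fit(sub[split.train_idx], labels[split.train_idx])
    rep = evaluate(model, sub[split.val_idx], labels[split.val_idx],
                   partition="validation", classifier_tag=classifier_tag)
    rep.config = {"band_subset": band_subset, "seed": seed}
    return rep
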