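"""Activity prediction from fingerprints: one-vs-rest classification and CV.

Each activity class is scored against all the others grouped (one-vs-rest):
the negative examples for a class are simply the peptides carrying any other
activity.  Two classifier families are provided:

* ``naive_bayes`` — multinomial naive Bayes over monomer counts with
  Laplace (+1) smoothing, the natural event model for occurrence vectors.
  A Gaussian-per-feature variant is available via
  ``hyperparams={"event_model": "gaussian"}`` for comparison with toolkits
  that default to Gaussian likelihoods on numeric attributes.
* ``linear`` — L2-regularized logistic regression (liblinear solver,
  C = 1.0), fitting an independent one-vs-rest linear decision function per
  class.

Evaluation follows stratified k-fold cross-validation: out-of-fold
multiclass predictions (argmax over per-class scores) feed the confusion
matrix and overall accuracy, while per-class precision / recall / F-measure
and ROC AUC come from one-vs-rest binarization of the same pooled
predictions and scores.  AUC is the tie-aware Mann-Whitney statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.multiclass import OneVsRestClassifier
from sklearn.naive_bayes import GaussianNB, MultinomialNB

from .fingerprint import MCFP, AlphabetMismatchError, MonomerAlphabet, PeptideRecord, compute_mcfp

__all__ = [
    "ClassifierKind",
    "LabeledFingerprintSet",
    "ClassMetrics",
    "ConfusionMatrix",
    "ClassifierModel",
    "CrossValidationResult",
    "train_classifier",
    "predict",
    "cross_validate",
    "roc_auc",
    "evaluate_multilabel",
]

ClassifierKind = Literal["naive_bayes", "linear"]


@dataclass
class LabeledFingerprintSet:
    """Parallel fingerprints / single activity labels / peptide ids."""

    fps: list[MCFP]
    labels: list[str]
    ids: list[str]

    def __post_init__(self) -> None:
        if not (len(self.fps) == len(self.labels) == len(self.ids)):
            raise ValueError("fps, labels and ids must have equal length")
        if not self.fps:
            raise ValueError("empty labeled set")
        first = self.fps[0]
        if any(not first.same_alphabet(fp) for fp in self.fps[1:]):
            raise AlphabetMismatchError("fingerprints span multiple alphabets")

    def __len__(self) -> int:
        return len(self.fps)

    @property
    def alphabet(self) -> MonomerAlphabet:
        return self.fps[0].alphabet

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.labels)))

    def matrix(self) -> np.ndarray:
        return np.stack([fp.dense(dtype=np.float64) for fp in self.fps])

    @classmethod
    def from_records(
        cls, records: Sequence[PeptideRecord], alphabet: MonomerAlphabet
    ) -> "LabeledFingerprintSet":
        """Build from curated (single-activity) records."""
        fps, labels, ids = [], [], []
        for r in records:
            if len(r.activities) != 1:
                raise ValueError(
                    f"peptide {r.id!r} has {len(r.activities)} activities; "
                    "curate to single-activity records first"
                )
            fps.append(compute_mcfp(r, alphabet))
            labels.append(next(iter(r.activities)))
            ids.append(r.id)
        return cls(fps, labels, ids)


@dataclass(frozen=True)
class ClassMetrics:
    """One-vs-rest performance for a single activity class."""

    label: str
    precision: float
    recall: float
    f_measure: float
    auc: float


@dataclass
class ConfusionMatrix:
    """Multiclass confusion counts: cells[i][j] = true class i, predicted j."""

    labels: tuple[str, ...]
    cells: np.ndarray

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=np.int64)
        if self.cells.shape != (len(self.labels), len(self.labels)):
            raise ValueError("confusion matrix shape does not match labels")
        if np.any(self.cells < 0):
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.cells.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.cells) / self.total)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.cells, index=self.labels, columns=self.labels)


def _make_estimator(kind: ClassifierKind, hyperparams: Mapping | None):
    hp = dict(hyperparams or {})
    if kind == "naive_bayes":
        event_model = hp.pop("event_model", "multinomial")
        if event_model == "multinomial":
            return MultinomialNB(alpha=hp.pop("alpha", 1.0), **hp)
        if event_model == "gaussian":
            return GaussianNB(**hp)
        raise ValueError(f"unknown event_model {event_model!r}")
    if kind == "linear":
        # L2 regularization (the solver default), C = 1.0
        base = LogisticRegression(
            C=hp.pop("C", 1.0),
            solver="liblinear",
            max_iter=hp.pop("max_iter", 1000),
            **hp,
        )
        # explicit one-vs-rest: each class against all the others, grouped
        return OneVsRestClassifier(base)
    raise ValueError(f"unknown classifier kind {kind!r}")


@dataclass
class ClassifierModel:
    """A fitted classifier bound to the alphabet it was trained on."""

    kind: ClassifierKind
    estimator: object
    classes: tuple[str, ...]
    alphabet: MonomerAlphabet

    def scores(self, fp: MCFP) -> dict[str, float]:
        """Per-class probability scores for one fingerprint."""
        if not (
            fp.alphabet is self.alphabet
            or fp.alphabet.codes == self.alphabet.codes
        ):
            raise AlphabetMismatchError(
                "fingerprint alphabet differs from the training alphabet"
            )
        proba = self.estimator.predict_proba(
            fp.dense(dtype=np.float64)[None, :]
        )[0]
        est_classes = list(self.estimator.classes_)
        return {c: float(proba[est_classes.index(c)]) for c in self.classes}


def train_classifier(
    train: LabeledFingerprintSet,
    kind: ClassifierKind = "naive_bayes",
    hyperparams: Mapping | None = None,
) -> ClassifierModel:
    """Fit a one-vs-rest activity classifier on labeled fingerprints."""
    classes = train.classes
    if len(classes) < 2:
        raise ValueError("training set must contain at least two classes")
    est = _make_estimator(kind, hyperparams)
    est.fit(train.matrix(), np.asarray(train.labels))
    return ClassifierModel(
        kind=kind, estimator=est, classes=classes, alphabet=train.alphabet
    )


def predict(model: ClassifierModel, fp: MCFP) -> tuple[str, dict[str, float]]:
    """Predict the single most likely activity for one fingerprint.

    The label is the argmax of the per-class scores; exact ties resolve to
    the first class in sorted label order.
    """
    scores = model.scores(fp)
    best = max(model.classes, key=lambda c: (scores[c], ))
    # max() keeps the first maximal element; model.classes is sorted, so the
    # tie-break is lexicographic by construction.
    return best, scores


def roc_auc(scores: Sequence[float], positives: Sequence[bool]) -> float:
    """Area under the ROC curve via the tie-aware Mann-Whitney statistic.

    Equals the probability that a random positive outranks a random
    negative, counting ties as 1/2: midranks of the positive scores give
    ``AUC = (R_pos - n_pos (n_pos + 1) / 2) / (n_pos * n_neg)``.
    """
    scores = np.asarray(scores, dtype=np.float64)
    pos = np.asarray(positives, dtype=bool)
    if scores.shape != pos.shape:
        raise ValueError("scores and positives must have equal length")
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs at least one positive and one negative")
    ranks = rankdata(scores)
    r_pos = float(ranks[pos].sum())
    return (r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


@dataclass
class CrossValidationResult:
    """Pooled out-of-fold evaluation of one classifier kind."""

    per_class: dict[str, ClassMetrics]
    confusion: ConfusionMatrix
    accuracy: float
    n_folds: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "n_folds": self.n_folds,
            "seed": self.seed,
            "per_class": {
                label: {
                    "precision": m.precision,
                    "recall": m.recall,
                    "f_measure": m.f_measure,
                    "auc": m.auc,
                }
                for label, m in self.per_class.items()
            },
            "confusion": {
                "labels": list(self.confusion.labels),
                "cells": self.confusion.cells.tolist(),
            },
        }


def cross_validate(
    data: LabeledFingerprintSet,
    kind: ClassifierKind = "naive_bayes",
    n_folds: int = 10,
    seed: int = 0,
    hyperparams: Mapping | None = None,
) -> CrossValidationResult:
    """Stratified k-fold cross-validation with pooled out-of-fold metrics.

    Every instance is predicted exactly once by a model that never saw it;
    the pooled predictions yield the multiclass confusion matrix and overall
    accuracy (correct classifications over total classifications), and their
    one-vs-rest binarization yields per-class precision, recall, F-measure
    and AUC.  Classes smaller than ``n_folds`` trigger a stratification
    warning but are still evaluated.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if n_folds > len(data):
        raise ValueError("n_folds exceeds the dataset size")
    classes = data.classes
    if len(classes) < 2:
        raise ValueError("cross-validation needs at least two classes")
    y = np.asarray(data.labels)
    x = data.matrix()
    smallest = min(np.sum(y == c) for c in classes)
    if smallest < n_folds:
        warnings.warn(
            f"smallest class has {smallest} members (< {n_folds} folds); "
            "stratification is approximate",
            UserWarning,
            stacklevel=2,
        )

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    n = len(data)
    pred = np.empty(n, dtype=object)
    proba = np.zeros((n, len(classes)))
    class_pos = {c: i for i, c in enumerate(classes)}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # sklearn fold-size chatter
        for train_idx, test_idx in skf.split(x, y):
            est = _make_estimator(kind, hyperparams)
            est.fit(x[train_idx], y[train_idx])
            p = est.predict_proba(x[test_idx])
            for j, c in enumerate(est.classes_):
                proba[test_idx, class_pos[c]] = p[:, j]
            # argmax with lexicographic tie-break over the global class order
            for i in test_idx:
                row = proba[i]
                pred[i] = classes[int(np.argmax(row))]

    cells = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for true, hat in zip(y, pred):
        cells[class_pos[true], class_pos[hat]] += 1
    confusion = ConfusionMatrix(labels=classes, cells=cells)

    per_class: dict[str, ClassMetrics] = {}
    for c in classes:
        i = class_pos[c]
        tp = int(cells[i, i])
        fp = int(cells[:, i].sum() - tp)
        fn = int(cells[i, :].sum() - tp)
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f = (
            2 * precision * recall / (precision + recall)
            if precision + recall
            else 0.0
        )
        auc = roc_auc(proba[:, i], y == c)
        per_class[c] = ClassMetrics(
            label=c, precision=precision, recall=recall, f_measure=f, auc=auc
        )

    return CrossValidationResult(
        per_class=per_class,
        confusion=confusion,
        accuracy=confusion.accuracy,
        n_folds=n_folds,
        seed=seed,
    )


@dataclass
class MultilabelEvaluation:
    """Per-record predictions on a multi-label evaluation set."""

    rows: list[dict]
    percent_correct: float


def evaluate_multilabel(
    model: ClassifierModel, eval_records: Sequence[PeptideRecord]
) -> MultilabelEvaluation:
    """Score a model on peptides with several known activities.

    A prediction is counted correct when the single predicted label is one
    of the record's known activities — the natural criterion for peptides
    that genuinely carry several activities.
    """
    rows = []
    n_correct = 0
    for r in eval_records:
        if not r.activities:
            raise ValueError(f"peptide {r.id!r} has no known activities")
        fp = compute_mcfp(r, model.alphabet, unknown_policy="ignore")
        label, scores = predict(model, fp)
        correct = label in r.activities
        n_correct += correct
        rows.append(
            {
                "id": r.id,
                "known": sorted(r.activities),
                "predicted": label,
                "correct": bool(correct),
            }
        )
    rate = 100.0 * n_correct / len(rows) if rows else 0.0
    return MultilabelEvaluation(rows=rows, percent_correct=rate)
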