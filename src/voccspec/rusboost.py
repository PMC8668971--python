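"""RUSBoost: random-undersampling boosting for a 2:1-imbalanced cohort.

Each boosting round draws a balanced (1:1) random undersample of the majority
class, fits a weak hypothesis on it, then evaluates the AdaBoost.M2
pseudo-loss on the FULL weighted training set.  Misclassified examples gain
weight; the final classifier is a weighted vote of the weak hypotheses with
vote weights log(1/a_t), a_t = delta_t / (1 - delta_t).  Undersampling before
each fit keeps the minority (non-deleted) class from being swamped without
discarding its examples from the loss.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

logger = logging.getLogger(__name__)

__all__ = [
    "LabeledFeatureTable",
    "EnsembleModel",
    "MetricsReport",
    "random_undersample",
    "train_rusboost",
    "predict",
    "decision_scores",
    "stratified_kfold_cv",
    "compute_metrics",
]


@dataclass
class LabeledFeatureTable:
    """Feature matrix (n, d) + binary labels + normalized example weights."""

    X: np.ndarray
    y: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X must be (n, d) with one label per row")
        if self.X.shape[0] < 2:
            raise ValueError("need at least 2 examples")
        if self.weights is None:
            self.weights = np.full(len(self.y), 1.0 / len(self.y))
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != self.y.shape or np.any(self.weights < 0):
                raise ValueError("weights must be non-negative, one per example")
            if abs(self.weights.sum() - 1.0) > 1e-9:
                raise ValueError("weights must sum to 1")

    def __len__(self) -> int:
        return len(self.y)

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.y)


@dataclass
class EnsembleModel:
    """Trained RUSBoost ensemble: weak hypotheses + their vote weights."""

    hypotheses: list
    vote_weights: np.ndarray
    classes: np.ndarray
    minority_class: object
    weak_learner_spec: str = "decision tree, depth 2"
    #: per-iteration record: resampled class counts, pseudo-loss, post-update
    #: weight sum — kept for auditing the boosting contract
    trace: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.hypotheses) < 1:
            raise ValueError("ensemble needs at least one hypothesis")
        self.vote_weights = np.asarray(self.vote_weights, dtype=float)
        if not np.all(np.isfinite(self.vote_weights)):
            raise ValueError("vote weights must be finite")


@dataclass
class MetricsReport:
    """Pooled confusion matrix with the derived per-class metric set.

    ``precision``/``recall``/``f_score`` map class label -> value; a metric
    with a zero denominator is NaN and its (class, metric) pair is recorded
    in ``undefined``.
    """

    confusion: np.ndarray
    classes: list
    precision: dict
    recall: dict
    f_score: dict
    accuracy: float
    auc: float | None = None
    undefined: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return int(self.confusion.sum())


def _minority_label(y: np.ndarray) -> object:
    classes, counts = np.unique(y, return_counts=True)
    return classes[np.argmin(counts)]


def random_undersample(
    table: LabeledFeatureTable, seed: int | np.random.Generator = 0
) -> LabeledFeatureTable:
    """Balance classes 1:1 by randomly dropping majority examples.

    The minority class is kept intact; the majority class is subsampled
    without replacement down to the minority count.  Retained weights are
    renormalized to sum to 1.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    classes, counts = np.unique(table.y, return_counts=True)
    if classes.size < 2:
        raise ValueError("undersampling requires both classes present")
    n_min = counts.min()
    keep: list[np.ndarray] = []
    for cls, cnt in zip(classes, counts):
        idx = np.flatnonzero(table.y == cls)
        if cnt > n_min:
            idx = rng.choice(idx, size=n_min, replace=False)
        keep.append(idx)
    sel = np.sort(np.concatenate(keep))
    w = table.weights[sel]
    return LabeledFeatureTable(table.X[sel], table.y[sel], w / w.sum())


def _default_weak_learner(depth: int = 2) -> DecisionTreeClassifier:
    return DecisionTreeClassifier(max_depth=depth)


def _class_probabilities(
    hypothesis, X: np.ndarray, classes: np.ndarray
) -> np.ndarray:
    """predict_proba aligned to ``classes`` columns (missing classes -> 0)."""
    proba = hypothesis.predict_proba(X)
    out = np.zeros((X.shape[0], classes.size))
    for col, cls in enumerate(hypothesis.classes_):
        out[:, np.flatnonzero(classes == cls)[0]] = proba[:, col]
    return out


def train_rusboost(
    table: LabeledFeatureTable,
    n_iterations: int = 100,
    weak_learner=None,
    seed: int = 0,
    max_resample_retries: int = 5,
) -> EnsembleModel:
    """Train the RUSBoost ensemble.

    Per iteration: balanced undersample -> fit weak hypothesis on it ->
    AdaBoost.M2 pseudo-loss delta_t on the full weighted set -> a_t =
    delta_t/(1-delta_t) -> multiplicative weight update favoring misclassified
    examples -> renormalize.  A round whose pseudo-loss reaches 0.5 is retried
    with a fresh undersample up to ``max_resample_retries`` times, after which
    training stops early and keeps the hypotheses collected so far.  A weak
    hypothesis that is constant on its balanced sample is skipped with a
    warning.
    """
    if n_iterations < 1:
        raise ValueError("need at least one boosting iteration")
    if len(table) < 4:
        raise ValueError("need at least 4 training examples")
    classes = table.classes
    if classes.size != 2:
        raise ValueError("training requires exactly 2 classes present")
    if weak_learner is None:
        weak_learner = _default_weak_learner()
    rng = np.random.default_rng(seed)
    minority = _minority_label(table.y)
    n = len(table)
    w = np.full(n, 1.0 / n)
    y_idx = np.searchsorted(classes, table.y)
    other_idx = 1 - y_idx

    hypotheses: list = []
    vote_weights: list[float] = []
    trace: list[dict] = []
    for t in range(n_iterations):
        fitted = None
        for _ in range(max_resample_retries + 1):
            sub = random_undersample(
                LabeledFeatureTable(table.X, table.y, w / w.sum()), rng
            )
            h = clone(weak_learner)
            h.fit(sub.X, sub.y, sample_weight=sub.weights * len(sub))
            if np.unique(h.predict(sub.X)).size < 2:
                logger.warning("iteration %d: constant weak hypothesis, skipped", t)
                fitted = "skip"
                break
            proba = _class_probabilities(h, table.X, classes)
            p_true = proba[np.arange(n), y_idx]
            p_other = proba[np.arange(n), other_idx]
            delta = 0.5 * float(np.sum(w * (1.0 - p_true + p_other)))
            if delta < 0.5:
                fitted = (h, delta, p_true, p_other)
                break
        if fitted == "skip":
            continue
        if fitted is None:
            logger.warning("iteration %d: pseudo-loss >= 0.5 after retries; stopping", t)
            break
        h, delta, p_true, p_other = fitted
        a = max(delta / (1.0 - delta), 1e-12)  # delta=0 would give an infinite vote
        w = w * a ** (0.5 * (1.0 + p_true - p_other))
        w = w / w.sum()
        hypotheses.append(h)
        vote_weights.append(math.log(1.0 / a))
        sub_classes, sub_counts = np.unique(sub.y, return_counts=True)
        trace.append({
            "resampled_counts": dict(zip(sub_classes.tolist(), sub_counts.tolist())),
            "pseudo_loss": delta,
            "weight_sum": float(w.sum()),
        })
    if not hypotheses:
        raise ValueError("no usable weak hypothesis: every iteration was skipped")
    return EnsembleModel(
        hypotheses, np.asarray(vote_weights), classes, minority,
        weak_learner_spec=repr(weak_learner), trace=trace,
    )


def decision_scores(model: EnsembleModel, X: np.ndarray) -> np.ndarray:
    """Per-class weighted-vote scores, shape (n, 2), normalized to sum to 1."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.hypotheses[0].n_features_in_:
        raise ValueError("feature dimensionality does not match the trained model")
    scores = np.zeros((X.shape[0], model.classes.size))
    for h, beta in zip(model.hypotheses, model.vote_weights):
        scores += beta * _class_probabilities(h, X, model.classes)
    total = model.vote_weights.sum()
    return scores / total if total > 0 else scores


def predict(model: EnsembleModel, X: np.ndarray) -> np.ndarray:
    """Weighted-vote class prediction; exact ties go to the minority class."""
    scores = decision_scores(model, np.asarray(X, dtype=float))
    min_col = int(np.flatnonzero(model.classes == model.minority_class)[0])
    best = np.argmax(scores, axis=1)
    ties = scores[:, 0] == scores[:, 1]
    best[ties] = min_col
    return model.classes[best]


def compute_metrics(
    confusion: np.ndarray, classes: Sequence, auc: float | None = None
) -> MetricsReport:
    """Per-class precision/recall/F-score + accuracy from a confusion matrix.

    ``confusion[i, j]`` counts true class i predicted as class j.  A zero
    denominator yields NaN (flagged in ``undefined``), never a silent 0.
    """
    C = np.asarray(confusion, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1] or np.any(C < 0) or C.sum() == 0:
        raise ValueError("confusion matrix must be square, non-negative, non-empty")
    classes = list(classes)
    precision, recall, fscore, undefined = {}, {}, {}, []
    for i, cls in enumerate(classes):
        tp = C[i, i]
        pred_pos = C[:, i].sum()
        true_pos = C[i, :].sum()
        p = tp / pred_pos if pred_pos > 0 else float("nan")
        r = tp / true_pos if true_pos > 0 else float("nan")
        if pred_pos == 0:
            undefined.append((cls, "precision"))
        if true_pos == 0:
            undefined.append((cls, "recall"))
        if not math.isnan(p) and not math.isnan(r) and (p + r) > 0:
            f = 2 * p * r / (p + r)
        else:
            f = float("nan")
            undefined.append((cls, "f_score"))
        precision[cls], recall[cls], fscore[cls] = float(p), float(r), float(f)
    accuracy = float(np.trace(C) / C.sum())
    return MetricsReport(C.astype(int), classes, precision, recall, fscore,
                         accuracy, auc=auc, undefined=undefined)


def stratified_kfold_cv(
    table: LabeledFeatureTable,
    k: int = 10,
    n_iterations: int = 100,
    weak_learner=None,
    seed: int = 0,
) -> MetricsReport:
    """Stratified k-fold cross-validation with a pooled confusion matrix.

    Each fold trains a fresh ensemble on the remaining folds and predicts the
    held-out fold; all held-out predictions are pooled into one confusion
    matrix.  AUC is the rank-based area under the ROC computed from the pooled
    minority-class vote scores.  Deterministic for a fixed seed.
    """
    classes, counts = np.unique(table.y, return_counts=True)
    if classes.size != 2:
        raise ValueError("cross-validation requires exactly 2 classes")
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} members < k={k}; reduce k"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    C = np.zeros((2, 2))
    pooled_scores = np.zeros(len(table))
    minority = _minority_label(table.y)
    min_col = int(np.flatnonzero(classes == minority)[0])
    for fold, (tr, te) in enumerate(skf.split(table.X, table.y)):
        model = train_rusboost(
            LabeledFeatureTable(table.X[tr], table.y[tr]),
            n_iterations=n_iterations,
            weak_learner=weak_learner,
            seed=seed + 7919 * (fold + 1),
        )
        pred = predict(model, table.X[te])
        pooled_scores[te] = decision_scores(model, table.X[te])[:, min_col]
        for yt, yp in zip(table.y[te], pred):
            C[np.flatnonzero(classes == yt)[0], np.flatnonzero(classes == yp)[0]] += 1
    from sklearn.metrics import roc_auc_score

    auc = float(roc_auc_score(table.y == minority, pooled_scores))
    return compute_metrics(C, list(classes), auc=auc)
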