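"""Classifier evaluation: stratified cross-validation, hold-out, and metrics.

Six standard binary classifiers are supported, each at its library
defaults (no hyper-parameter tuning): logistic regression, an RBF-kernel
SVM with Platt-scaled probabilities, a small feed-forward network (three
fully connected layers: input, one hidden layer of width
``min(10, ceil(d/2))``, sigmoid output), random forest, XGBoost and
LightGBM.  Evaluation uses stratified k-fold cross-validation (default
k=10) or a stratified 80:20 hold-out; per-fold metrics are accuracy,
precision, recall, F1, MCC and AUC-ROC, aggregated by the fold mean.

Embedding models (when the feature spec includes "pro2vec") are trained
only on the training folds' sequences, so no test information leaks into
the representation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .assembly import FeatureSpec, extract_matrix, feature_dimension
from .embedding import build_corpus, train_embedding
from .alphabet import load_alphabet, reduce_sequence

__all__ = [
    "MODEL_NAMES",
    "ConfusionCounts",
    "EvalReport",
    "stratified_folds",
    "classification_metrics",
    "auc_roc",
    "make_model",
    "train_fold_embeddings",
    "run_cv",
    "run_holdout",
]

logger = logging.getLogger(__name__)

MODEL_NAMES: tuple[str, ...] = ("logistic", "svm", "ann", "rf", "xgb", "lgbm")

METRIC_NAMES: tuple[str, ...] = ("accuracy", "precision", "recall", "f1", "mcc", "auc_roc")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class EvalReport:
    """Per-fold and mean-aggregated metrics of one (model, spec) evaluation."""

    model_name: str
    spec: FeatureSpec
    seed: int
    per_fold: list[dict[str, float]]
    fold_assignments: np.ndarray | None = None
    aggregate: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        self.aggregate = {
            m: float(np.mean([f[m] for f in self.per_fold])) for m in METRIC_NAMES
        }

    def to_table_row(self) -> dict:
        """One row in the layout of the result tables."""
        return {
            "Model": self.model_name,
            "Representations": tuple(self.spec.representations),
            "Feat types": tuple(self.spec.feature_types),
            "Offsets": tuple(self.spec.offsets),
            "Nfeat": feature_dimension(self.spec),
            "Accuracy": self.aggregate["accuracy"],
            "Precision": self.aggregate["precision"],
            "Recall": self.aggregate["recall"],
            "F1 score": self.aggregate["f1"],
            "AUC ROC": self.aggregate["auc_roc"],
            "MCC": self.aggregate["mcc"],
        }

    def to_json_dict(self) -> dict:
        return {
            "model": self.model_name,
            "spec": self.spec.to_json_dict(),
            "seed": self.seed,
            "per_fold": self.per_fold,
            "aggregate": self.aggregate,
        }


def stratified_folds(labels: np.ndarray, k: int = 10, seed: int = 0) -> np.ndarray:
    """Assign each instance to one of k stratified test folds.

    Per-fold class counts differ from perfect proportionality by at most
    one instance.  Returns an integer fold index per instance.
    """
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if counts.min() < k:
        raise ValueError(
            f"class {classes[counts.argmin()]} has only {counts.min()} members for k={k}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(labels), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        assignment[test_idx] = fold
    return assignment


def classification_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Accuracy, precision, recall, F1 and MCC from confusion counts.

    A degenerate denominator (e.g. no predicted positives) yields 0 for
    that metric, with a log record.
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn

    def _ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            logger.debug("degenerate denominator for %s; defined as 0", name)
            return 0.0
        return num / den

    precision = _ratio(tp, tp + fp, "precision")
    recall = _ratio(tp, tp + fn, "recall")
    f1 = _ratio(2 * precision * recall, precision + recall, "f1")
    accuracy = _ratio(tp + tn, counts.total, "accuracy")
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _ratio(tp * tn - fp * fn, mcc_den, "mcc")
    return {
        "accuracy": accuracy,
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "mcc": mcc,
    }


def auc_roc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve.

    Equals the Mann-Whitney probability that a randomly chosen positive
    outscores a randomly chosen negative, ties counting one half.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(labels, np.asarray(scores)))


def make_model(model_name: str, n_features: int, seed: int = 0):
    """Instantiate a classifier by its short name at library defaults."""
    if model_name == "logistic":
        return LogisticRegression(max_iter=1000, random_state=seed)
    if model_name == "svm":
        return SVC(probability=True, random_state=seed)
    if model_name == "ann":
        hidden = min(10, max(1, math.ceil(n_features / 2)))
        return MLPClassifier(hidden_layer_sizes=(hidden,), max_iter=500, random_state=seed)
    if model_name == "rf":
        return RandomForestClassifier(random_state=seed)
    if model_name == "xgb":
        from xgboost import XGBClassifier

        return XGBClassifier(random_state=seed, eval_metric="logloss")
    if model_name == "lgbm":
        from lightgbm import LGBMClassifier

        return LGBMClassifier(random_state=seed, verbose=-1)
    raise ValueError(f"unknown model {model_name!r}; valid: {MODEL_NAMES}")


def train_fold_embeddings(records, spec: FeatureSpec, seed: int = 0):
    """Train per-representation embedding models on one set of sequences."""
    if "pro2vec" not in spec.feature_types:
        return None
    models = {}
    for rep in spec.representations:
        ngram_size, dimension = spec.embedding_config[rep]
        alpha = load_alphabet(rep)
        reps = [reduce_sequence(r.sequence, alpha, r.id) for r in records]
        corpus = build_corpus(reps, ngram_size)
        models[rep] = train_embedding(
            corpus, dimension, alpha, ngram_size, epochs=3, seed=seed
        )
    return models


def _fold_metrics(model, x_tr, y_tr, x_te, y_te) -> dict[str, float]:
    model.fit(x_tr, y_tr)
    prob = model.predict_proba(x_te)[:, 1]
    pred = (prob >= 0.5).astype(int)
    counts = ConfusionCounts(
        tp=int(np.sum((pred == 1) & (y_te == 1))),
        tn=int(np.sum((pred == 0) & (y_te == 0))),
        fp=int(np.sum((pred == 1) & (y_te == 0))),
        fn=int(np.sum((pred == 0) & (y_te == 1))),
    )
    metrics = classification_metrics(counts)
    metrics["auc_roc"] = auc_roc(prob, y_te)
    return metrics


def run_cv(
    dataset,
    spec: FeatureSpec,
    model_name: str,
    k: int = 10,
    seed: int = 0,
) -> EvalReport:
    """Stratified k-fold cross-validation of one model on one feature spec.

    Per fold the classifier is fit on k-1 folds and scored on the held-out
    fold; embedding models, when used, are retrained per fold on the
    training folds only.  Metrics are aggregated by the fold mean.
    """
    records = list(dataset)
    labels = np.array([r.label for r in records])
    folds = stratified_folds(labels, k=k, seed=seed)
    uses_embeddings = "pro2vec" in spec.feature_types

    shared_matrix = None
    if not uses_embeddings:
        shared_matrix = extract_matrix(records, spec).values

    per_fold = []
    for fold in range(k):
        test_mask = folds == fold
        if uses_embeddings:
            train_records = [r for r, m in zip(records, test_mask) if not m]
            models = train_fold_embeddings(train_records, spec, seed=seed)
            x_tr = extract_matrix(train_records, spec, models).values
            x_te = extract_matrix(
                [r for r, m in zip(records, test_mask) if m], spec, models
            ).values
        else:
            x_tr, x_te = shared_matrix[~test_mask], shared_matrix[test_mask]
        y_tr, y_te = labels[~test_mask], labels[test_mask]
        model = make_model(model_name, x_tr.shape[1], seed=seed)
        per_fold.append(_fold_metrics(model, x_tr, y_tr, x_te, y_te))
    return EvalReport(
        model_name=model_name, spec=spec, seed=seed, per_fold=per_fold, fold_assignments=folds
    )


def run_holdout(
    dataset,
    spec: FeatureSpec,
    model_name: str,
    test_size: float = 0.2,
    seed: int = 0,
):
    """Stratified hold-out evaluation (default 80:20 train:test).

    Returns ``(report, fitted_model, (x_train, y_train, x_test, y_test))``
    so the fitted model can be handed to the explanation module.
    """
    records = list(dataset)
    labels = np.array([r.label for r in records])
    idx_tr, idx_te = train_test_split(
        np.arange(len(records)),
        test_size=test_size,
        stratify=labels,
        random_state=seed,
    )
    train_records = [records[i] for i in idx_tr]
    test_records = [records[i] for i in idx_te]
    models = train_fold_embeddings(train_records, spec, seed=seed)
    x_tr = extract_matrix(train_records, spec, models).values
    x_te = extract_matrix(test_records, spec, models).values
    y_tr, y_te = labels[idx_tr], labels[idx_te]
    model = make_model(model_name, x_tr.shape[1], seed=seed)
    metrics = _fold_metrics(model, x_tr, y_tr, x_te, y_te)
    report = EvalReport(model_name=model_name, spec=spec, seed=seed, per_fold=[metrics])
    return report, model, (x_tr, y_tr, x_te, y_te)
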