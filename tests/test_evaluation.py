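"""Folds, metrics and cross-validation behaviour."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ampfeat.assembly import FeatureSpec
from ampfeat.data import generate_synthetic
from ampfeat.evaluation import (
    ConfusionCounts,
    auc_roc,
    classification_metrics,
    make_model,
    run_cv,
    run_holdout,
    stratified_folds,
)

counts_strategy = st.builds(
    ConfusionCounts,
    tp=st.integers(0, 200),
    tn=st.integers(0, 200),
    fp=st.integers(0, 200),
    fn=st.integers(0, 200),
)


def test_stratified_folds_partition_arithmetic():
    labels = np.array([1] * 153 + [0] * 250)
    folds = stratified_folds(labels, k=10, seed=0)
    for fold in range(10):
        mask = folds == fold
        assert mask.sum() in (40, 41)
        assert labels[mask].sum() in (15, 16)


def test_stratified_folds_tiny_balanced_case():
    folds = stratified_folds(np.array([1, 1, 0, 0]), k=2, seed=1)
    for fold in range(2):
        assert np.array([1, 1, 0, 0])[folds == fold].sum() == 1


def test_stratified_folds_deterministic():
    labels = np.array([0, 1] * 30)
    np.testing.assert_array_equal(
        stratified_folds(labels, k=5, seed=3), stratified_folds(labels, k=5, seed=3)
    )


def test_stratified_folds_errors():
    with pytest.raises(ValueError, match="both classes"):
        stratified_folds(np.ones(20), k=2)
    with pytest.raises(ValueError, match="only"):
        stratified_folds(np.array([1] * 3 + [0] * 50), k=10)


def test_metrics_perfect_classifier():
    m = classification_metrics(ConfusionCounts(tp=10, tn=10, fp=0, fn=0))
    assert m == {"accuracy": 1.0, "precision": 1.0, "recall": 1.0, "f1": 1.0, "mcc": 1.0}


def test_metrics_all_wrong_classifier():
    m = classification_metrics(ConfusionCounts(tp=0, tn=0, fp=10, fn=10))
    assert m["accuracy"] == 0.0
    assert m["mcc"] == -1.0  # denominator is defined here; the formula gives -1


def test_metrics_undefined_mcc_falls_back_to_zero():
    # no predicted positives at all: tp+fp = 0 zeroes the denominator
    m = classification_metrics(ConfusionCounts(tp=0, tn=10, fp=0, fn=10))
    assert m["mcc"] == 0.0
    assert m["precision"] == 0.0


def test_metrics_formula_oracle():
    """Direct recomputation of the five formulas for a worked confusion table."""
    m = classification_metrics(ConfusionCounts(tp=70, tn=90, fp=30, fn=10))
    precision, recall = 70 / 100, 70 / 80
    assert m["precision"] == pytest.approx(precision)
    assert m["recall"] == pytest.approx(recall)
    assert m["f1"] == pytest.approx(2 * precision * recall / (precision + recall))
    assert m["accuracy"] == pytest.approx(160 / 200)
    mcc = (70 * 90 - 30 * 10) / math.sqrt(100 * 80 * 120 * 100)
    assert m["mcc"] == pytest.approx(mcc)


@settings(derandomize=True, max_examples=100)
@given(counts=counts_strategy)
def test_f1_is_harmonic_mean_where_defined(counts):
    m = classification_metrics(counts)
    if m["precision"] > 0 and m["recall"] > 0:
        hm = 2 / (1 / m["precision"] + 1 / m["recall"])
        assert m["f1"] == pytest.approx(hm)
    assert 0 <= m["accuracy"] <= 1 and -1 <= m["mcc"] <= 1


@settings(derandomize=True, max_examples=100)
@given(counts=counts_strategy)
def test_mcc_invariant_under_class_swap(counts):
    swapped = ConfusionCounts(tp=counts.tn, tn=counts.tp, fp=counts.fn, fn=counts.fp)
    a = classification_metrics(counts)["mcc"]
    b = classification_metrics(swapped)["mcc"]
    assert a == pytest.approx(b)


def test_auc_perfect_separation():
    assert auc_roc(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0])) == 1.0


def test_auc_null_large_sample(rng):
    labels = rng.integers(0, 2, size=4000)
    labels[:2] = [0, 1]
    scores = rng.random(4000)
    assert abs(auc_roc(scores, labels) - 0.5) < 0.05


def test_auc_matches_all_pairs_oracle(rng):
    scores = rng.random(20)
    labels = np.array([1] * 8 + [0] * 12)
    wins = sum(
        1.0 if sp > sn else 0.5 if sp == sn else 0.0
        for sp in scores[labels == 1]
        for sn in scores[labels == 0]
    )
    assert auc_roc(scores, labels) == pytest.approx(wins / (8 * 12))


def test_auc_single_class_errors():
    with pytest.raises(ValueError):
        auc_roc(np.array([0.1, 0.9]), np.array([1, 1]))


def test_make_model_unknown_name():
    with pytest.raises(ValueError, match="unknown model"):
        make_model("perceptron", 10)


def test_ann_hidden_width_is_capped():
    assert make_model("ann", 100).hidden_layer_sizes == (10,)
    assert make_model("ann", 6).hidden_layer_sizes == (3,)


def test_run_cv_null_signal_auc_near_half():
    records = generate_synthetic(150, 150, center_residues=None, seed=21)
    spec = FeatureSpec(("no_reduction",), ("counts",))
    report = run_cv(records, spec, "logistic", k=5, seed=21)
    assert abs(report.aggregate["auc_roc"] - 0.5) < 0.12


def test_run_cv_planted_signal_auc_high():
    records = generate_synthetic(150, 150, center_residues=None,
                                 composition_shift={"K": 1.5}, seed=22)
    spec = FeatureSpec(("no_reduction",), ("counts",))
    report = run_cv(records, spec, "logistic", k=5, seed=22)
    assert report.aggregate["auc_roc"] > 0.9


def test_run_cv_deterministic():
    records = generate_synthetic(40, 40, seed=23)
    spec = FeatureSpec(("hydro",), ("counts", "tfeat"), (1,))
    a = run_cv(records, spec, "logistic", k=4, seed=23)
    b = run_cv(records, spec, "logistic", k=4, seed=23)
    assert a.per_fold == b.per_fold


def test_run_cv_report_table_row_layout():
    records = generate_synthetic(30, 30, seed=24)
    spec = FeatureSpec(("no_reduction", "hydro"), ("counts", "tfeat"), (1, 3))
    row = run_cv(records, spec, "logistic", k=3, seed=24).to_table_row()
    assert row["Nfeat"] == 45
    assert set(row) == {
        "Model", "Representations", "Feat types", "Offsets", "Nfeat",
        "Accuracy", "Precision", "Recall", "F1 score", "AUC ROC", "MCC",
    }


def test_run_holdout_returns_fitted_model():
    records = generate_synthetic(40, 40, composition_shift={"K": 1.5},
                                 center_residues=None, seed=25)
    spec = FeatureSpec(("no_reduction",), ("counts",))
    report, model, (x_tr, y_tr, x_te, y_te) = run_holdout(records, spec, "rf", seed=25)
    assert x_tr.shape[0] == 64 and x_te.shape[0] == 16
    # stratification of the 80:20 split
    assert y_te.sum() == 8
    assert model.predict_proba(x_te).shape == (16, 2)
    assert 0 <= report.aggregate["auc_roc"] <= 1


def test_no_leakage_embeddings_trained_per_fold(monkeypatch):
    """Embedding training must only ever see training-fold records."""
    import ampfeat.evaluation as ev

    records = generate_synthetic(15, 15, seed=26)
    spec = FeatureSpec(("no_reduction",), ("pro2vec",),
                       embedding_config={"no_reduction": (3, 4)})
    seen_sizes = []
    original = ev.train_fold_embeddings

    def spy(recs, spec_, seed=0):
        seen_sizes.append(len(recs))
        return original(recs, spec_, seed=seed)

    monkeypatch.setattr(ev, "train_fold_embeddings", spy)
    ev.run_cv(records, spec, "logistic", k=3, seed=26)
    assert seen_sizes == [20, 20, 20]  # k-1 folds of 30 records each time
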