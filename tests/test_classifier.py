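"""Splitting, cross-validation, tuning, training and evaluation of the
boosted-tree motility classifier."""

import numpy as np
import pandas as pd
import pytest

from flagmet.classifier import (
    EvalReport,
    HyperParams,
    MotilityClassifier,
    MotilityModel,
    SplitSpec,
    cross_validate,
    evaluate,
    split_train_test,
    train,
    tune_hyperparameters,
)
from flagmet.errors import ValidationError
from flagmet.io import GeneContentMatrix
from flagmet.simulate import rule_labeled_gene_matrix


def _toy(n=20, seed=0):
    """Separable toy set: label equals gene g1, plus noise genes."""
    rng = np.random.default_rng(seed)
    g1 = rng.integers(0, 2, n)
    noise = rng.integers(0, 2, (n, 3))
    df = pd.DataFrame(
        np.column_stack([g1, noise]),
        index=[f"g{i}" for i in range(n)],
        columns=["g1", "n1", "n2", "n3"],
    )
    labels = pd.Series(np.where(g1 == 1, "motile", "nonmotile"), index=df.index)
    return GeneContentMatrix(df, is_binary=True), labels


@pytest.fixture(scope="module")
def rule_fit():
    """One shared fit on the rule-labeled fixture (motile iff >=15 of 21)."""
    mat, pheno = rule_labeled_gene_matrix(n_genomes=600, seed=3)
    return MotilityClassifier(mat, pheno).fit(split=SplitSpec(seed=3)), mat, pheno


# ---------------------------------------------------------------------------
# split_train_test
# ---------------------------------------------------------------------------

def test_split_sizes_floor_rule():
    mat, pheno = _toy(10)
    parts = split_train_test(mat, pheno, SplitSpec(seed=1))
    assert len(parts.train_ids) == 7 and len(parts.test_ids) == 3


def test_split_sizes_match_study_cohort():
    # 1225 genomes (388 motile, 837 nonmotile) at 70:30 -> 857 / 368
    labels = ["motile"] * 388 + ["nonmotile"] * 837
    ids = [f"g{i}" for i in range(1225)]
    df = pd.DataFrame({"gene": [1] * 1225}, index=ids)
    mat = GeneContentMatrix(df, is_binary=True)
    pheno = pd.Series(labels, index=ids)
    parts = split_train_test(mat, pheno, SplitSpec(seed=42))
    assert len(parts.train_ids) == 857
    assert len(parts.test_ids) == 368
    # stratification: per-class fraction within one genome of 0.7
    train_motile = sum(pheno[g] == "motile" for g in parts.train_ids)
    assert abs(train_motile - 0.7 * 388) <= 1


def test_split_is_disjoint_exhaustive_and_deterministic():
    mat, pheno = _toy(31, seed=4)
    a = split_train_test(mat, pheno, SplitSpec(seed=9))
    b = split_train_test(mat, pheno, SplitSpec(seed=9))
    assert a.train_ids == b.train_ids and a.test_ids == b.test_ids
    assert set(a.train_ids) | set(a.test_ids) == set(mat.genome_ids)
    assert not set(a.train_ids) & set(a.test_ids)
    c = split_train_test(mat, pheno, SplitSpec(seed=10))
    assert c.train_ids != a.train_ids  # different seed reshuffles


def test_split_requires_two_members_per_class():
    df = pd.DataFrame({"g1": [1, 0, 0, 0]}, index=list("abcd"))
    mat = GeneContentMatrix(df, is_binary=True)
    pheno = pd.Series(["motile", "nonmotile", "nonmotile", "nonmotile"],
                      index=list("abcd"))
    with pytest.raises(ValidationError):
        split_train_test(mat, pheno, SplitSpec())


# ---------------------------------------------------------------------------
# cross_validate
# ---------------------------------------------------------------------------

def test_cv_on_separable_data_reaches_low_loss():
    mat, pheno = _toy(40, seed=2)
    parts = split_train_test(mat, pheno, SplitSpec(seed=2))
    rounds, loss = cross_validate(parts.X_train, parts.y_train, k=4, seed=2)
    assert rounds >= 1
    assert loss < 0.2


def test_cv_leave_one_out_is_valid_and_k_bounds_checked():
    mat, pheno = _toy(8, seed=3)
    y = np.array([1, 0, 1, 0, 1, 0, 1, 0])
    rounds, _ = cross_validate(mat.data, y, k=8, max_rounds=5, seed=0)
    assert rounds >= 1
    with pytest.raises(ValidationError):
        cross_validate(mat.data, y, k=9)
    with pytest.raises(ValidationError):
        cross_validate(mat.data, np.ones(8, dtype=int), k=4)


# ---------------------------------------------------------------------------
# tune_hyperparameters
# ---------------------------------------------------------------------------

def test_tuning_budget_one_and_determinism():
    mat, pheno = _toy(40, seed=5)
    parts = split_train_test(mat, pheno, SplitSpec(seed=5))
    hp1 = tune_hyperparameters(parts.X_train, parts.y_train, budget=1, seed=7,
                               max_rounds=20)
    hp2 = tune_hyperparameters(parts.X_train, parts.y_train, budget=1, seed=7,
                               max_rounds=20)
    assert hp1 == hp2
    with pytest.raises(ValidationError):
        tune_hyperparameters(parts.X_train, parts.y_train, bounds={}, budget=1)
    with pytest.raises(ValidationError):
        tune_hyperparameters(parts.X_train, parts.y_train, budget=0)


def test_tuned_cv_loss_never_worse_than_default():
    mat, pheno = rule_labeled_gene_matrix(n_genomes=200, seed=6)
    parts = split_train_test(mat, pheno, SplitSpec(seed=6))
    hp = tune_hyperparameters(parts.X_train, parts.y_train, budget=5, seed=6,
                              max_rounds=60)
    default = HyperParams()
    _, default_loss = cross_validate(parts.X_train, parts.y_train, default,
                                     k=5, max_rounds=60, seed=6)
    _, tuned_loss = cross_validate(parts.X_train, parts.y_train, hp, k=5,
                                   max_rounds=60, seed=6)
    assert tuned_loss <= default_loss + 1e-12


# ---------------------------------------------------------------------------
# train / predict
# ---------------------------------------------------------------------------

def test_training_on_single_informative_gene():
    mat, pheno = _toy(30, seed=8)
    parts = split_train_test(mat, pheno, SplitSpec(seed=8))
    model = train(parts.X_train, parts.y_train, HyperParams(n_rounds=50), seed=8)
    proba, labels = model.predict(parts.X_train)
    truth = np.where(parts.X_train["g1"] == 1, "motile", "nonmotile")
    assert (labels == truth).all()
    # importance concentrates on the informative gene
    (top_gene, top_imp), *_ = model.feature_importance()
    assert top_gene == "g1"
    imps = dict(model.feature_importance())
    assert sum(imps.values()) == pytest.approx(1.0, abs=1e-9)


def test_training_loss_non_increasing():
    mat, pheno = rule_labeled_gene_matrix(n_genomes=150, seed=9)
    model = train(mat.data, (pheno == "motile").to_numpy(int),
                  HyperParams(n_rounds=80), seed=9)
    hist = np.array(model.training_history)
    assert len(hist) == 80
    assert (np.diff(hist) <= 1e-9).all()


def test_train_rejects_degenerate_inputs():
    mat, _ = _toy(10)
    with pytest.raises(ValidationError):
        train(mat.data, np.zeros(10, dtype=int))
    with pytest.raises(ValidationError):
        HyperParams(n_rounds=0)


def test_probability_half_labels_nonmotile():
    # constant features and balanced labels give an empty tree: p = 0.5,
    # and the tie goes to nonmotile
    X = pd.DataFrame({"g1": [0] * 8}, index=[f"g{i}" for i in range(8)])
    y = np.array([0, 1] * 4)
    model = train(X, y, HyperParams(n_rounds=1), seed=0)
    proba, labels = model.predict(X)
    assert proba[0] == pytest.approx(0.5)
    assert (labels == "nonmotile").all()


def test_predict_handles_missing_and_extra_genes(rule_fit):
    results, mat, _ = rule_fit
    X = mat.data.iloc[:5].copy()
    X = X.drop(columns=[X.columns[0]])
    X["unrelated_gene"] = 1
    proba, labels = results.model.predict(X)
    assert len(proba) == 5
    assert set(labels) <= {"motile", "nonmotile"}


def test_prediction_determinism(rule_fit):
    results, mat, pheno = rule_fit
    p1 = results.model.predict_proba(mat.data.iloc[:50])
    p2 = results.model.predict_proba(mat.data.iloc[:50])
    np.testing.assert_array_equal(p1, p2)


def test_model_json_roundtrip(tmp_path, rule_fit):
    results, mat, _ = rule_fit
    path = tmp_path / "model.json"
    results.model.save(path)
    loaded = MotilityModel.load(path)
    np.testing.assert_allclose(
        loaded.predict_proba(mat.data.iloc[:40]),
        results.model.predict_proba(mat.data.iloc[:40]),
        rtol=1e-6,
    )
    assert loaded.feature_names == results.model.feature_names


# ---------------------------------------------------------------------------
# Rule-labeled fixture recovery
# ---------------------------------------------------------------------------

def test_rule_fixture_recovery(rule_fit):
    """Labels that are a deterministic function of the panel genes are
    recovered with high held-out accuracy."""
    results, _, _ = rule_fit
    assert results.report.accuracy >= 0.95
    assert results.report.sensitivity >= 0.95
    assert results.report.specificity >= 0.95


def test_rule_fixture_extremes_predicted_correctly(rule_fit):
    results, mat, _ = rule_fit
    all_present = pd.DataFrame(1, index=["full"], columns=mat.gene_ids)
    all_absent = pd.DataFrame(0, index=["empty"], columns=mat.gene_ids)
    _, label_full = results.model.predict(all_present)
    _, label_empty = results.model.predict(all_absent)
    assert label_full[0] == "motile"
    assert label_empty[0] == "nonmotile"


def test_all_panel_genes_contribute_gain(rule_fit):
    results, mat, _ = rule_fit
    nonzero = {g for g, imp in results.model.feature_importance() if imp > 0}
    assert nonzero == set(mat.gene_ids)


# ---------------------------------------------------------------------------
# evaluate
# ---------------------------------------------------------------------------

def test_eval_report_metrics():
    perfect = EvalReport(tp=5, tn=5, fp=0, fn=0)
    assert perfect.accuracy == 1.0 and perfect.specificity == 1.0
    all_motile = EvalReport(tp=5, tn=0, fp=5, fn=0)
    assert all_motile.accuracy == 0.5
    assert all_motile.specificity == 0.0
    assert all_motile.sensitivity == 1.0


def test_evaluate_rejects_empty_test_set(rule_fit):
    results, mat, _ = rule_fit
    with pytest.raises(ValidationError):
        evaluate(results.model, mat.data.iloc[:0], np.array([], dtype=int))


def test_summary_reports_key_numbers(rule_fit):
    results, _, _ = rule_fit
    text = results.summary()
    assert "held-out accuracy" in text
    assert f"{results.report.accuracy:.4f}" in text
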