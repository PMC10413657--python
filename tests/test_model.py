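"""Non-LOF lasso pipeline: identity, filtering, preprocessing, tuning,
thresholds."""

import numpy as np
import pandas as pd
import pytest

from assembly_buffer import (
    Preprocessor,
    class_balance,
    derive_thresholds,
    fit_lasso_cv,
    gen_logistic_features,
    pairwise_identity,
    predict,
    preprocess,
    redundancy_filter,
    variable_importance,
)
from assembly_buffer.errors import (
    ParameterError,
    SchemaMismatchError,
    ValidationError,
)
from assembly_buffer.model import identity_matrix


# ------------------------------------------------------ pairwise identity


def test_identity_of_identical_sequences():
    assert pairwise_identity("MKVLA", "MKVLA") == pytest.approx(100.0)


def test_identity_hand_alignment():
    # AAAA vs AATA: 3 matches over 4 columns
    assert pairwise_identity("AAAA", "AATA") == pytest.approx(75.0)


def test_identity_symmetric_and_low_for_disjoint():
    a, b = "MKVLAWGHE", "FYPDNQRST"
    assert pairwise_identity(a, b) == pytest.approx(pairwise_identity(b, a))
    assert pairwise_identity(a, b) < 15.0


def test_identity_rejects_empty():
    with pytest.raises(ParameterError):
        pairwise_identity("", "AAA")


# ----------------------------------------------------- redundancy filter


def _matrix(ids, pairs):
    mat = pd.DataFrame(100.0 if len(ids) == 1 else 0.0, index=ids, columns=ids)
    np.fill_diagonal(mat.values, 100.0)
    for a, b, v in pairs:
        mat.loc[a, b] = mat.loc[b, a] = v
    return mat


def test_single_conflict_keeps_one():
    retained = redundancy_filter(_matrix(["A", "B"], [("A", "B", 60.0)]))
    assert len(retained) == 1


def test_no_conflicts_keeps_all():
    mat = _matrix(["A", "B", "C"], [("A", "B", 10.0), ("B", "C", 20.0)])
    assert redundancy_filter(mat) == ["A", "B", "C"]


def test_greedy_most_connected_first_trace():
    # A-B 55, B-C 55, A-C 10: B has two conflicts and is removed first,
    # leaving A and C below the threshold
    mat = _matrix(
        ["A", "B", "C"],
        [("A", "B", 55.0), ("B", "C", 55.0), ("A", "C", 10.0)],
    )
    assert redundancy_filter(mat) == ["A", "C"]


def test_filter_validates_symmetry():
    mat = _matrix(["A", "B"], [("A", "B", 60.0)])
    mat.loc["A", "B"] = 10.0
    with pytest.raises(ValidationError):
        redundancy_filter(mat)


def test_identity_matrix_end_to_end_filter():
    seqs = {
        "g1": "MKVLAWGHEDD",
        "g2": "MKVLAWGHEDA",  # ~91% identical to g1
        "g3": "FYPDNQRSTCC",
    }
    mat = identity_matrix(seqs)
    retained = redundancy_filter(mat)
    assert "g3" in retained
    assert len([g for g in retained if g in ("g1", "g2")]) == 1


# ---------------------------------------------------------- preprocessing


def test_preprocess_no_missing_is_scaling_only():
    rng = np.random.default_rng(0)
    df = pd.DataFrame(rng.normal(3, 2, size=(50, 3)), columns=["a", "b", "c"])
    X = preprocess(df)
    assert np.allclose(X.mean(axis=0), 0, atol=1e-9)
    assert np.allclose(X.std(axis=0), 1, atol=1e-9)
    # no imputation happened: rank order within columns preserved
    assert np.array_equal(np.argsort(X[:, 0]), np.argsort(df["a"].to_numpy()))


def test_constant_neighbourhood_imputes_common_value():
    df = pd.DataFrame(
        {
            "x": [1.0, 1.0, 1.0, 1.0, 1.0, np.nan],
            "y": [2.0, 2.0, 2.0, 2.0, 2.0, 2.0],
            "z": [0.0, 0.1, -0.1, 0.05, -0.05, 0.0],
        }
    )
    prep = Preprocessor(k_neighbors=5).fit(df)
    # invert the final scaling to read back the imputed raw value
    imputed_scaled = prep.transform(df)[5, 0]
    raw = imputed_scaled * prep.post_std_[0] * prep.pre_std_[0] + (
        prep.post_mean_[0] * prep.pre_std_[0] + prep.pre_mean_[0]
    )
    assert raw == pytest.approx(1.0, abs=1e-9)


def test_transform_is_deterministic_and_idempotent_on_same_input():
    rng = np.random.default_rng(1)
    X, y = gen_logistic_features(100, 4, (1.0,), missing_rate=0.1, seed=2)
    df = pd.DataFrame(X, columns=list("abcd"))
    prep = Preprocessor().fit(df)
    assert np.array_equal(prep.transform(df), prep.transform(df))
    assert not np.isnan(prep.transform(df)).any()


def test_one_hot_encoding_and_unseen_category():
    df = pd.DataFrame({"sym": ["C2", "Cn>2", "C2", "Dn>1"], "v": [1.0, 2.0, 3.0, 4.0]})
    prep = Preprocessor().fit(df)
    X = prep.transform(df)
    assert X.shape == (4, 1 + 3)
    names = prep.feature_names_
    assert "sym=C2" in names and "sym=Dn>1" in names
    unseen = pd.DataFrame({"sym": ["other"], "v": [2.0]})
    Xu = prep.transform(unseen)
    assert np.all(Xu[0, 1:] == 0)  # unseen category maps to all-zero block


def test_all_missing_column_rejected():
    df = pd.DataFrame({"a": [np.nan, np.nan, np.nan], "b": [1.0, 2.0, 3.0]})
    with pytest.raises(ValidationError):
        Preprocessor().fit(df)


def test_schema_mismatch_lists_missing_columns():
    df = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]})
    prep = Preprocessor().fit(df)
    with pytest.raises(SchemaMismatchError) as exc:
        prep.transform(pd.DataFrame({"a": [1.0]}))
    assert "b" in exc.value.missing


# ----------------------------------------------------------- lasso tuning


@pytest.fixture(scope="module")
def sparse_fit():
    X, y = gen_logistic_features(2000, 10, (2.0, -2.0), sparsity=2, seed=1)
    return fit_lasso_cv(X, y, seed=1), X, y


def test_large_lambda_shrinks_everything(sparse_fit):
    fit, X, y = sparse_fit
    # the grid's top value lambda=1 must zero out all coefficients
    assert fit.support_sizes[-1] == 0


def test_support_recovery_of_true_signals(sparse_fit):
    fit, X, y = sparse_fit
    nonzero = set(np.flatnonzero(fit.coef))
    assert {0, 1} <= nonzero


def test_support_sizes_nonincreasing_in_lambda(sparse_fit):
    fit, _, _ = sparse_fit
    assert np.all(np.diff(fit.support_sizes) <= 0)


def test_signs_of_recovered_coefficients(sparse_fit):
    fit, _, _ = sparse_fit
    assert fit.coef[0] > 0 and fit.coef[1] < 0
    assert fit.coef_sign[0] == 1 and fit.coef_sign[1] == -1


def test_lambda_zero_rejected():
    X, y = gen_logistic_features(50, 3, (1.0,), seed=3)
    with pytest.raises(ParameterError):
        fit_lasso_cv(X, y, lambda_grid=[0.0, 0.1], folds=2, repeats=1)


def test_single_class_labels_rejected():
    X = np.random.default_rng(0).normal(size=(30, 3))
    with pytest.raises(ValidationError):
        fit_lasso_cv(X, np.zeros(30), folds=2, repeats=1)


def test_no_signal_accuracy_near_majority_rate():
    X, y = gen_logistic_features(100, 5, (0.0,), seed=1)
    fit = fit_lasso_cv(X, y, folds=5, repeats=1, seed=0)
    majority = max(np.mean(y), 1 - np.mean(y))
    assert abs(fit.cv_accuracy.max() - majority) < 0.15


# ------------------------------------------------------------- importance


def test_importance_direct_arithmetic():
    from assembly_buffer.model import NonLofFit

    fit = NonLofFit(
        feature_names=["a", "b", "c"],
        coef=np.array([2.0, -1.0, 0.0]),
        intercept=0.0,
        lambda_grid=np.array([0.1]),
        chosen_lambda=0.1,
        cv_accuracy=np.array([0.5]),
        support_sizes=np.array([2]),
        n_samples=10,
    )
    assert np.allclose(variable_importance(fit), [1.0, 0.5, 0.0])


def test_importance_all_zero_rejected():
    from assembly_buffer.model import NonLofFit

    fit = NonLofFit(
        feature_names=["a"],
        coef=np.array([0.0]),
        intercept=0.0,
        lambda_grid=np.array([1.0]),
        chosen_lambda=1.0,
        cv_accuracy=np.array([0.5]),
        support_sizes=np.array([0]),
        n_samples=10,
    )
    with pytest.raises(ValidationError):
        variable_importance(fit)


# -------------------------------------------------------------- thresholds


def test_separable_scores_tie_rule_lowest_candidate():
    scores = np.array([0.9, 0.8, 0.1, 0.2])
    labels = np.array([True, True, False, False])
    t1, t2 = derive_thresholds(scores, labels)
    # J=1 anywhere in (0.2, 0.8]; the lowest candidate is the midpoint 0.5
    assert t1 == pytest.approx(0.5)
    assert t2 == pytest.approx(0.5)


def test_t2_exceeds_overlapping_negative():
    scores = np.array([0.9, 0.8, 0.85, 0.1])
    labels = np.array([True, True, False, False])
    t1, t2 = derive_thresholds(scores, labels)
    assert t2 > 0.85
    # at T2 specificity is exactly 1 on the training scores
    assert (scores[~labels] >= t2).sum() == 0


def test_youden_sweep_matches_exhaustive_oracle(rng):
    scores = rng.random(60)
    labels = rng.random(60) < 0.5
    if labels.all() or not labels.any():
        labels[0] = not labels[0]
    t1, _ = derive_thresholds(scores, labels)

    def j_at(c):
        tpr = (scores[labels] >= c).mean()
        fpr = (scores[~labels] >= c).mean()
        return tpr - fpr

    # brute force over a fine grid plus all observed scores
    cands = np.concatenate([np.linspace(0, 1, 2001), scores])
    assert j_at(t1) >= max(j_at(c) for c in cands) - 1e-12


def test_thresholds_require_both_classes():
    with pytest.raises(ValidationError):
        derive_thresholds([0.1, 0.9], [True, True])


# ---------------------------------------------------------------- predict


def test_predict_intercept_only_score():
    from assembly_buffer.model import NonLofFit

    fit = NonLofFit(
        feature_names=["a", "b"],
        coef=np.array([1.0, -1.0]),
        intercept=0.3,
        lambda_grid=np.array([0.1]),
        chosen_lambda=0.1,
        cv_accuracy=np.array([0.6]),
        support_sizes=np.array([2]),
        n_samples=10,
    )
    out = predict(fit, np.zeros((1, 2)))
    assert out["score"].iloc[0] == pytest.approx(1 / (1 + np.exp(-0.3)))


def test_predict_monotone_in_positive_feature(sparse_fit):
    fit, X, _ = sparse_fit
    base = np.zeros((5, X.shape[1]))
    base[:, 0] = np.linspace(-2, 2, 5)
    scores = predict(fit, base)["score"].to_numpy()
    assert np.all(np.diff(scores) > 0)


def test_predict_schema_mismatch():
    from assembly_buffer.model import NonLofFit

    fit = NonLofFit(
        feature_names=["a", "b", "c"],
        coef=np.array([1.0, 0.0, 0.0]),
        intercept=0.0,
        lambda_grid=np.array([0.1]),
        chosen_lambda=0.1,
        cv_accuracy=np.array([0.6]),
        support_sizes=np.array([1]),
        n_samples=10,
    )
    with pytest.raises(SchemaMismatchError):
        predict(fit, np.zeros((2, 2)))


def test_train_test_flags_reproducible():
    X, y = gen_logistic_features(400, 6, (1.5, -1.5), seed=9)
    from sklearn.model_selection import train_test_split

    Xtr, Xte, ytr, yte = train_test_split(
        X, y, test_size=0.25, random_state=0, stratify=y
    )
    fits = []
    for _ in range(2):
        fit = fit_lasso_cv(Xtr, ytr, folds=5, repeats=1, seed=4)
        scores = predict(fit, Xtr)["score"].to_numpy()
        fit.t1, fit.t2 = derive_thresholds(scores, ytr.astype(bool))
        fits.append(predict(fit, Xte))
    pd.testing.assert_frame_equal(fits[0], fits[1])


# ------------------------------------------------------------ bookkeeping


def test_class_balance_percentage():
    labels = np.concatenate([np.ones(543, bool), np.zeros(791 - 543, bool)])
    assert round(class_balance(labels)) == 69
    with pytest.raises(ParameterError):
        class_balance([])
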