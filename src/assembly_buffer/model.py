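"""Penalized logistic model prioritizing non-loss-of-function disease genes.

Genes whose dominant disease mechanism is not simple loss of function
(i.e. dominant-negative or gain-of-function) are predicted from ~30 gene-,
sequence-, structure- and network-level features with an L1-penalized
logistic regression:

1. homology control — genes are redundancy-filtered so no retained pair
   shares >= 50% global sequence identity;
2. preprocessing — 5-nearest-neighbour imputation of missing numerics,
   one-hot encoding of nominal columns, z-scaling to mean 0 / SD 1, with
   all transform parameters learned on the training split only;
3. fitting — the penalty λ is tuned on a fixed grid by repeated stratified
   10-fold cross-validation (3 repeats), selecting the λ with the highest
   mean assessment-fold accuracy, then refitting on the full training set;
4. reporting — variable importance is |β| scaled so the largest equals 1,
   and two decision thresholds are swept from the score distribution:
   T1 maximizes Youden's J = sensitivity + specificity - 1, and T2 is the
   smallest cutoff at which specificity reaches 100% (no ground-truth LOF
   gene is called non-LOF).

The per-sample penalty λ maps onto scikit-learn's liblinear solver as
C = 1/(λ·n), so λ→1 drives every coefficient to zero and small λ
approaches the unpenalized fit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import RepeatedStratifiedKFold

from .errors import ParameterError, SchemaMismatchError, ValidationError

IDENTITY_THRESHOLD = 50.0


def _aligner():
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    # gaps must cost more than a mismatch so substitutions are preferred
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    return aligner


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity of a global alignment: matches / alignment columns.

    Symmetric in its arguments; identical sequences give 100.
    """
    if not seq_a or not seq_b:
        raise ParameterError("sequences must be non-empty")
    aln = _aligner().align(seq_a, seq_b)[0]
    counts = aln.counts()
    return 100.0 * counts.identities / aln.length


def identity_matrix(sequences: dict[str, str]) -> pd.DataFrame:
    """Symmetric percent-identity matrix over a set of named sequences."""
    ids = list(sequences)
    mat = pd.DataFrame(100.0, index=ids, columns=ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            v = pairwise_identity(sequences[a], sequences[b])
            mat.loc[a, b] = mat.loc[b, a] = v
    return mat


def redundancy_filter(
    identity: pd.DataFrame, threshold: float = IDENTITY_THRESHOLD
) -> list[str]:
    """Greedy homology reduction: drop genes until no pair >= threshold.

    Repeatedly removes the gene with the most remaining conflicts
    (most-connected-first); among equally connected genes the
    lexicographically last gene_id is removed, keeping earlier names.
    Returns the retained gene IDs in the matrix's input order.
    """
    if identity.shape[0] != identity.shape[1] or not np.allclose(
        identity.values, identity.values.T, atol=1e-8
    ):
        raise ValidationError("identity matrix must be square and symmetric")
    if not np.allclose(np.diag(identity.values), 100.0, atol=1e-6):
        raise ValidationError("identity matrix diagonal must be 100")
    ids = list(identity.index)
    adj = identity.values >= threshold
    np.fill_diagonal(adj, False)
    alive = np.ones(len(ids), dtype=bool)
    while True:
        degrees = (adj & alive[None, :] & alive[:, None]).sum(axis=1)
        degrees[~alive] = 0
        if degrees.max() == 0:
            break
        top = degrees.max()
        candidates = [i for i in range(len(ids)) if degrees[i] == top]
        victim = max(candidates, key=lambda i: ids[i])
        alive[victim] = False
    return [g for g, a in zip(ids, alive) if a]


class Preprocessor:
    """Imputation + encoding + scaling with train-only parameter learning.

    Numeric columns are z-scaled with NaN-tolerant statistics, imputed with
    5-nearest-neighbour Euclidean imputation (pairwise-complete distances),
    then re-standardized so the training design has mean 0 / SD 1 exactly.
    Nominal (object/categorical) columns are one-hot encoded on the
    categories seen at fit time; unseen categories map to all-zero blocks.
    """

    def __init__(self, k_neighbors: int = 5):
        self.k_neighbors = k_neighbors
        self.numeric_cols: list[str] = []
        self.nominal_cols: list[str] = []
        self.categories_: dict[str, list] = {}
        self.pre_mean_: np.ndarray | None = None
        self.pre_std_: np.ndarray | None = None
        self.post_mean_: np.ndarray | None = None
        self.post_std_: np.ndarray | None = None
        self.imputer_: KNNImputer | None = None
        self.feature_names_: list[str] = []

    def fit(self, table: pd.DataFrame) -> "Preprocessor":
        self.numeric_cols = [
            c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])
        ]
        self.nominal_cols = [c for c in table.columns if c not in self.numeric_cols]
        num = table[self.numeric_cols].to_numpy(dtype=float)
        if num.size:
            all_missing = np.isnan(num).all(axis=0)
            if all_missing.any():
                bad = [c for c, m in zip(self.numeric_cols, all_missing) if m]
                raise ValidationError(f"all-missing numeric columns: {bad}")
            self.pre_mean_ = np.nanmean(num, axis=0)
            self.pre_std_ = np.nanstd(num, axis=0)
            self.pre_std_[self.pre_std_ == 0] = 1.0
            scaled = (num - self.pre_mean_) / self.pre_std_
            self.imputer_ = KNNImputer(n_neighbors=self.k_neighbors)
            imputed = self.imputer_.fit_transform(scaled)
            self.post_mean_ = imputed.mean(axis=0)
            self.post_std_ = imputed.std(axis=0)
            self.post_std_[self.post_std_ == 0] = 1.0
        for c in self.nominal_cols:
            self.categories_[c] = sorted(table[c].dropna().astype(str).unique())
        self.feature_names_ = list(self.numeric_cols) + [
            f"{c}={cat}" for c in self.nominal_cols for cat in self.categories_[c]
        ]
        return self

    def transform(self, table: pd.DataFrame) -> np.ndarray:
        missing = [
            c for c in self.numeric_cols + self.nominal_cols if c not in table.columns
        ]
        if missing:
            raise SchemaMismatchError(missing)
        blocks = []
        if self.numeric_cols:
            num = table[self.numeric_cols].to_numpy(dtype=float)
            scaled = (num - self.pre_mean_) / self.pre_std_
            imputed = self.imputer_.transform(scaled)
            blocks.append((imputed - self.post_mean_) / self.post_std_)
        for c in self.nominal_cols:
            col = table[c].astype(str)
            onehot = np.zeros((len(table), len(self.categories_[c])))
            for j, cat in enumerate(self.categories_[c]):
                onehot[:, j] = (col == cat).to_numpy(dtype=float)
            blocks.append(onehot)
        return np.hstack(blocks) if blocks else np.empty((len(table), 0))

    def fit_transform(self, table: pd.DataFrame) -> np.ndarray:
        return self.fit(table).transform(table)


def preprocess(table: pd.DataFrame, k_neighbors: int = 5) -> np.ndarray:
    """One-shot fit+transform; use :class:`Preprocessor` for train/test."""
    return Preprocessor(k_neighbors=k_neighbors).fit_transform(table)


def default_lambda_grid(n_values: int = 18) -> np.ndarray:
    """Log-spaced penalty grid on (0, 1]; log(0) being undefined, the lower
    end is 1e-10, effectively unpenalized.  Any custom grid (e.g. one
    containing a previously selected value) can be passed instead."""
    return np.logspace(-10, 0, n_values)


@dataclass
class NonLofFit:
    """Fitted penalized model with its tuning trace and thresholds."""

    feature_names: list[str]
    coef: np.ndarray
    intercept: float
    lambda_grid: np.ndarray
    chosen_lambda: float
    cv_accuracy: np.ndarray
    support_sizes: np.ndarray
    n_samples: int
    seed: int | None = None
    preprocessor: Preprocessor | None = None
    t1: float | None = None
    t2: float | None = None
    coef_sign: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.coef = np.asarray(self.coef, dtype=float)
        self.coef_sign = np.sign(self.coef)

    def to_json(self) -> str:
        payload = {
            "feature_names": self.feature_names,
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "lambda_grid": np.asarray(self.lambda_grid).tolist(),
            "chosen_lambda": self.chosen_lambda,
            "cv_accuracy": np.asarray(self.cv_accuracy).tolist(),
            "support_sizes": np.asarray(self.support_sizes).tolist(),
            "n_samples": self.n_samples,
            "seed": self.seed,
            "t1": self.t1,
            "t2": self.t2,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _fit_at_lambda(X, y, lam, n_for_c, max_iter=2000):
    clf = LogisticRegression(
        l1_ratio=1.0,
        C=1.0 / (lam * n_for_c),
        solver="liblinear",
        max_iter=max_iter,
        tol=1e-6,
        random_state=0,
    )
    clf.fit(X, y)
    return clf


def fit_lasso_cv(
    X: np.ndarray,
    y: np.ndarray,
    lambda_grid: Sequence[float] | None = None,
    folds: int = 10,
    repeats: int = 3,
    seed: int | None = None,
    feature_names: Sequence[str] | None = None,
) -> NonLofFit:
    """Tune λ by repeated stratified CV accuracy and refit on all data.

    Ties in mean accuracy go to the largest λ (the sparsest model).  λ = 0
    is rejected: on separable data the unpenalized coefficients diverge.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int).ravel()
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValidationError(f"need binary labels, got classes {classes}")
    grid = np.asarray(
        default_lambda_grid() if lambda_grid is None else lambda_grid, dtype=float
    )
    if np.any(grid <= 0):
        raise ParameterError(
            "lambda values must be > 0 (λ=0 is unpenalized and can diverge "
            "on separable data)"
        )
    grid = np.sort(grid)
    cv = RepeatedStratifiedKFold(
        n_splits=folds, n_repeats=repeats, random_state=seed
    )
    splits = list(cv.split(X, y))
    acc = np.zeros(len(grid))
    n = len(y)
    for gi, lam in enumerate(grid):
        scores = []
        for train_idx, test_idx in splits:
            clf = _fit_at_lambda(X[train_idx], y[train_idx], lam, n)
            scores.append(clf.score(X[test_idx], y[test_idx]))
        acc[gi] = np.mean(scores)
    # argmax over reversed grid -> largest lambda among ties
    best = len(grid) - 1 - int(np.argmax(acc[::-1]))
    support_sizes = np.zeros(len(grid), dtype=int)
    final = None
    for gi, lam in enumerate(grid):
        clf = _fit_at_lambda(X, y, lam, n)
        support_sizes[gi] = int(np.sum(clf.coef_ != 0))
        if gi == best:
            final = clf
    names = (
        list(feature_names)
        if feature_names is not None
        else [f"x{j}" for j in range(X.shape[1])]
    )
    if len(names) != X.shape[1]:
        raise ValidationError("feature_names must match X columns")
    return NonLofFit(
        feature_names=names,
        coef=final.coef_.ravel(),
        intercept=float(final.intercept_[0]),
        lambda_grid=grid,
        chosen_lambda=float(grid[best]),
        cv_accuracy=acc,
        support_sizes=support_sizes,
        n_samples=n,
        seed=seed,
    )


def variable_importance(fit: NonLofFit) -> np.ndarray:
    """|β| scaled to [0, 1]; the largest-magnitude coefficient gets 1."""
    mag = np.abs(fit.coef)
    if mag.max() == 0:
        raise ValidationError("all coefficients are zero; importance undefined")
    return mag / mag.max()


def _candidate_cutoffs(scores: np.ndarray) -> np.ndarray:
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2
    return np.unique(np.concatenate([uniq, mids, [1.0]]))


def derive_thresholds(scores, labels) -> tuple[float, float]:
    """Decision thresholds from a score set with known labels.

    A gene is called non-LOF when its score >= cutoff.  T1 is the lowest
    cutoff maximizing Youden's J; T2 the smallest cutoff with zero false
    positives (specificity 1).  Candidates are the observed scores, the
    midpoints between adjacent unique scores, and 1.0.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool).ravel()
    if labels.all() or not labels.any():
        raise ValidationError("need both classes to derive thresholds")
    pos, neg = scores[labels], scores[~labels]
    cands = _candidate_cutoffs(scores)
    tpr = (pos[None, :] >= cands[:, None]).mean(axis=1)
    fpr = (neg[None, :] >= cands[:, None]).mean(axis=1)
    j = tpr - fpr
    t1 = float(cands[int(np.argmax(j))])  # argmax returns the first (lowest)
    zero_fp = np.where(fpr == 0)[0]
    if zero_fp.size == 0:
        warnings.warn("no cutoff reaches 100% specificity; T2 undefined")
        t2 = float("nan")
    else:
        t2 = float(cands[zero_fp[0]])
    return t1, t2


def predict(
    fit: NonLofFit, features: pd.DataFrame | np.ndarray
) -> pd.DataFrame:
    """Score genes with a fitted model.

    DataFrames are routed through the stored preprocessor (schema checked);
    arrays must already be in design-matrix form.  Returns score (non-LOF
    probability) plus boolean flags for any stored thresholds.
    """
    if isinstance(features, pd.DataFrame):
        if fit.preprocessor is None:
            raise ValidationError("fit has no preprocessor; pass a design matrix")
        X = fit.preprocessor.transform(features)
    else:
        X = np.asarray(features, dtype=float)
        if X.shape[1] != len(fit.feature_names):
            raise SchemaMismatchError(
                missing=[f"expected {len(fit.feature_names)} columns, got {X.shape[1]}"]
            )
    score = 1.0 / (1.0 + np.exp(-(X @ fit.coef + fit.intercept)))
    out = pd.DataFrame({"score": score})
    if fit.t1 is not None:
        out["above_T1"] = score >= fit.t1
    if fit.t2 is not None and np.isfinite(fit.t2):
        out["above_T2"] = score >= fit.t2
    return out


def class_balance(labels) -> float:
    """Percent of positive (non-LOF) labels in a training pool."""
    labels = np.asarray(labels).astype(bool).ravel()
    if labels.size == 0:
        raise ParameterError("empty label vector")
    return 100.0 * labels.mean()
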