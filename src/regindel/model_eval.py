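"""Per-tissue classifiers and evaluation protocols.

The primary classifier is a gradient-boosted tree ensemble (XGBoost)
trained per tissue on the assembled feature matrix.  Four protocols are
provided:

* feature-set ablation — the same pooled cross-validation run on the
  generic-only, generic+ref and generic+ref+alt feature sets;
* within-tissue pooled k-fold CV — every variant is scored exactly once
  by a model that never saw it, the held-out scores are concatenated
  into one vector and a single AUROC/AUPRC is computed on it;
* cross-tissue transfer — train on one tissue, test on another after
  removing any variant key shared with the training set;
* independent-study transfer — the same machinery with the test set
  drawn from a different source study.

Two re-implemented reference baselines are included: an RBF-kernel SVM
on the generic annotations alone, and a boosted logistic regression
(stump-depth gradient boosting, logistic loss) on absolute and relative
ref/alt profile differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .features import FeatureMatrix, diff_features

__all__ = [
    "DEFAULT_HYPERPARAMS",
    "TissueModel",
    "EvalResult",
    "FeaturizedSet",
    "train_model",
    "predict_scores",
    "save_model",
    "load_model",
    "auroc",
    "auprc",
    "cv_pooled",
    "cross_tissue_eval",
    "xgb_trainer",
    "svm_trainer",
    "boosted_lr_trainer",
    "baseline_svm_generic",
    "baseline_boosted_lr_diff",
]

# Mid-size defaults sized for single-threaded training on matrices with
# ~2e3 rows and ~2e3 columns; column subsampling suits the wide, highly
# correlated profile block.
DEFAULT_HYPERPARAMS: dict = {
    "n_estimators": 200,
    "max_depth": 4,
    "learning_rate": 0.1,
    "subsample": 0.8,
    "colsample_bytree": 0.3,
}


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, FeatureMatrix):
        return X.df
    if isinstance(X, pd.DataFrame):
        return X
    raise TypeError(f"expected FeatureMatrix or DataFrame, got {type(X)!r}")


@dataclass
class TissueModel:
    """A fitted per-tissue scoring model plus the metadata needed to
    apply it reproducibly."""

    tissue: str
    estimator: object
    feature_names: list[str]
    seed: int
    hyperparams: dict
    feature_set: str = "generic+ref+alt"

    def predict(self, X) -> np.ndarray:
        return predict_scores(self, X)


@dataclass
class EvalResult:
    protocol: str
    train_tissue: str
    test_tissue: str
    auroc: float
    auprc: float
    n_test: int
    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        if not (0.0 <= self.auroc <= 1.0 and 0.0 <= self.auprc <= 1.0):
            raise ValueError("AUROC/AUPRC outside [0, 1]")
        if self.n_test != len(self.scores):
            raise ValueError("n_test does not match the score vector")


@dataclass
class FeaturizedSet:
    """A labeled cohort ready for training: features, labels, keys."""

    tissue: str
    X: FeatureMatrix
    y: np.ndarray
    keys: list[str]

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=int)
        if len(self.y) != self.X.df.shape[0] or len(self.keys) != len(self.y):
            raise ValueError("features, labels and keys must align")


def _check_labels(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if not set(classes) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    return y


def train_model(
    X,
    y: Sequence[int],
    hyperparams: dict | None = None,
    seed: int = 0,
    tissue: str = "tissue",
    feature_set: str = "generic+ref+alt",
) -> TissueModel:
    """Fit the gradient-boosted classifier; deterministic under the seed
    with single-threaded training."""
    df = _as_frame(X)
    if df.shape[0] == 0:
        raise ValueError("empty feature matrix")
    y = _check_labels(np.asarray(y))
    if len(y) != df.shape[0]:
        raise ValueError("label length does not match feature rows")
    hp = dict(DEFAULT_HYPERPARAMS)
    if hyperparams:
        hp.update(hyperparams)
    est = XGBClassifier(
        objective="binary:logistic",
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
        **hp,
    )
    est.fit(df.to_numpy(dtype=np.float32), y)
    return TissueModel(
        tissue=tissue,
        estimator=est,
        feature_names=list(df.columns),
        seed=seed,
        hyperparams=hp,
        feature_set=feature_set,
    )


def predict_scores(m: TissueModel, X) -> np.ndarray:
    """Score rows with a fitted model; feature names must match the
    training layout exactly (order-sensitive)."""
    df = _as_frame(X)
    if list(df.columns) != m.feature_names:
        raise ValueError(
            "feature-name mismatch between model and input (order matters)"
        )
    return m.estimator.predict_proba(df.to_numpy(dtype=np.float32))[:, 1]


def save_model(m: TissueModel, path: str | Path) -> None:
    joblib.dump(m, path)


def load_model(path: str | Path) -> TissueModel:
    m = joblib.load(path)
    if not isinstance(m, TissueModel):
        raise TypeError(f"{path} does not contain a TissueModel")
    return m


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank concordance: probability a random positive outscores a random
    negative, ties counting one half."""
    y = _check_labels(np.asarray(labels))
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def auprc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Average precision by step integration over the score-sorted list."""
    y = np.asarray(labels, dtype=int)
    if y.sum() == 0:
        raise ValueError("at least one positive label required")
    if (y == 1).all():
        return 1.0
    return float(average_precision_score(y, np.asarray(scores, dtype=float)))


# ---------------------------------------------------------------------------
# Trainers (uniform closure interface shared by all protocols)
# ---------------------------------------------------------------------------

Trainer = Callable[[pd.DataFrame, np.ndarray, int], Callable[[pd.DataFrame], np.ndarray]]


def xgb_trainer(hyperparams: dict | None = None) -> Trainer:
    def fit(Xtr: pd.DataFrame, ytr: np.ndarray, seed: int):
        m = train_model(Xtr, ytr, hyperparams=hyperparams, seed=seed)
        return lambda Xte: predict_scores(m, Xte)

    return fit


def svm_trainer(C: float = 1.0, gamma: str | float = "scale") -> Trainer:
    """Soft-margin RBF SVM emitting continuous decision-function scores,
    with feature standardization."""

    def fit(Xtr: pd.DataFrame, ytr: np.ndarray, seed: int):
        est = make_pipeline(
            StandardScaler(),
            SVC(C=C, gamma=gamma, kernel="rbf", random_state=seed),
        )
        est.fit(Xtr.to_numpy(dtype=np.float64), ytr)
        return lambda Xte: est.decision_function(Xte.to_numpy(dtype=np.float64))

    return fit


def boosted_lr_trainer(n_estimators: int = 200, learning_rate: float = 0.1) -> Trainer:
    """Boosted logistic regression: gradient boosting with logistic loss
    on depth-1 stumps."""

    def fit(Xtr: pd.DataFrame, ytr: np.ndarray, seed: int):
        est = GradientBoostingClassifier(
            loss="log_loss",
            max_depth=1,
            n_estimators=n_estimators,
            learning_rate=learning_rate,
            random_state=seed,
        )
        est.fit(Xtr.to_numpy(dtype=np.float64), ytr)
        return lambda Xte: est.predict_proba(Xte.to_numpy(dtype=np.float64))[:, 1]

    return fit


# ---------------------------------------------------------------------------
# Protocols
# ---------------------------------------------------------------------------

def cv_pooled(
    X,
    y: Sequence[int],
    k: int = 5,
    trainer: Trainer | None = None,
    seed: int = 0,
    protocol: str = "cv_pooled",
    tissue: str = "tissue",
) -> EvalResult:
    """Stratified k-fold CV with pooled fold scores.

    Each row is scored exactly once by the model trained on the other
    folds; the held-out scores are concatenated and a single AUROC and
    AUPRC are computed on the pooled vector.
    """
    df = _as_frame(X)
    y = _check_labels(np.asarray(y))
    n = df.shape[0]
    if n < k:
        raise ValueError(f"n={n} rows cannot be split into {k} folds")
    trainer = trainer or xgb_trainer()
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    pooled = np.full(n, np.nan)
    for fold, (tr, te) in enumerate(skf.split(df, y)):
        score_fn = trainer(df.iloc[tr], y[tr], seed + fold)
        pooled[te] = score_fn(df.iloc[te])
    assert not np.isnan(pooled).any(), "every row must be scored exactly once"
    return EvalResult(
        protocol=protocol,
        train_tissue=tissue,
        test_tissue=tissue,
        auroc=auroc(pooled, y),
        auprc=auprc(pooled, y),
        n_test=n,
        scores=pooled,
        labels=y,
    )


def cross_tissue_eval(
    train_set: FeaturizedSet,
    test_set: FeaturizedSet,
    trainer: Trainer | None = None,
    seed: int = 0,
    protocol: str = "cross_tissue",
) -> EvalResult:
    """Train on one cohort, test on another after removing any test
    variant whose key appears in the training set."""
    if train_set.X.feature_names != test_set.X.feature_names:
        raise ValueError("train and test sets must share feature names")
    trainer = trainer or xgb_trainer()
    train_keys = set(train_set.keys)
    keep = [i for i, k in enumerate(test_set.keys) if k not in train_keys]
    if not keep:
        raise ValueError("test set is empty after overlap removal")
    Xte = test_set.X.df.iloc[keep]
    yte = test_set.y[keep]
    if len(np.unique(yte)) < 2:
        raise ValueError("test set lost a class after overlap removal")
    score_fn = trainer(train_set.X.df, train_set.y, seed)
    scores = score_fn(Xte)
    return EvalResult(
        protocol=protocol,
        train_tissue=train_set.tissue,
        test_tissue=test_set.tissue,
        auroc=auroc(scores, yte),
        auprc=auprc(scores, yte),
        n_test=len(keep),
        scores=np.asarray(scores, dtype=float),
        labels=yte,
    )


def baseline_svm_generic(
    X_generic,
    y: Sequence[int],
    k: int = 5,
    seed: int = 0,
    tissue: str = "tissue",
) -> EvalResult:
    """Generic-annotation SVM baseline under the pooled-CV protocol."""
    return cv_pooled(
        X_generic, y, k=k, trainer=svm_trainer(), seed=seed,
        protocol="baseline_svm_generic", tissue=tissue,
    )


def baseline_boosted_lr_diff(
    X_profiles_ref: pd.DataFrame,
    X_profiles_alt: pd.DataFrame,
    y: Sequence[int],
    k: int = 5,
    seed: int = 0,
    tissue: str = "tissue",
) -> EvalResult:
    """Sequence-model baseline: boosted logistic regression on absolute
    and relative ref/alt profile differences."""
    X = diff_features(X_profiles_ref, X_profiles_alt)
    return cv_pooled(
        X, y, k=k, trainer=boosted_lr_trainer(), seed=seed,
        protocol="baseline_boosted_lr_diff", tissue=tissue,
    )
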