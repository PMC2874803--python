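"""Per-feature RBF-SVM classifiers, cross-validation, and majority voting.

Each classifier wraps an RBF-kernel support vector machine trained on one
(or more) z-scored feature columns with LIBSVM-style defaults (C = 1,
gamma = 1 / number of features).  The ensemble predictor is a committee of
single-feature classifiers combined by majority vote, with an exact tie
resolved toward the positive (hot) class — recall is the metric this
method privileges.
"""

from __future__ import annotations

import dataclasses
import pickle
import warnings
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVC

from .evaluation import ConfusionMatrix, metrics
from .selection import FeatureMatrix, HOT, NON_HOT

__all__ = [
    "SVMParams",
    "CVConfig",
    "FeatureClassifier",
    "EnsembleModel",
    "fit",
    "cross_validate",
    "cross_validate_ensemble",
    "majority_vote",
    "build_apis",
]

_MODEL_FORMAT_VERSION = 1


@dataclasses.dataclass(frozen=True)
class SVMParams:
    """RBF-SVM hyperparameters; gamma=None means 1/#features."""

    C: float = 1.0
    gamma: float | None = None
    class_weight: Literal[None, "balanced"] = None

    def resolved_gamma(self, n_features: int) -> float:
        return self.gamma if self.gamma is not None else 1.0 / n_features


@dataclasses.dataclass(frozen=True)
class CVConfig:
    """k-fold cross-validation settings (stratified by default)."""

    k: int = 10
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("need k >= 2 folds")


@dataclasses.dataclass
class FeatureClassifier:
    """A trained SVM over a fixed feature set with frozen normalization."""

    feature_names: list[str]
    norm_mean: np.ndarray
    norm_sd: np.ndarray
    svm: SVC
    params: SVMParams
    n_train: int
    seed: int

    def _prepare(self, rows: pd.DataFrame) -> np.ndarray:
        missing_cols = [f for f in self.feature_names if f not in rows.columns]
        if missing_cols:
            raise KeyError(f"rows lack model features {missing_cols}")
        X = rows[self.feature_names].to_numpy(dtype=float)
        if np.isnan(X).any():
            warnings.warn(
                "missing feature values imputed with training means",
                stacklevel=3,
            )
            idx = np.where(np.isnan(X))
            X[idx] = self.norm_mean[idx[1]]
        return (X - self.norm_mean) / self.norm_sd

    def predict(self, rows: pd.DataFrame) -> pd.Series:
        """Hot/non-hot label per row (stored z-scoring applied first)."""
        z = self._prepare(rows)
        labels = self.svm.predict(z)
        return pd.Series(labels, index=rows.index, dtype=object)

    def save(self, path: str | Path) -> None:
        payload = {"format_version": _MODEL_FORMAT_VERSION, "model": self}
        with open(path, "wb") as fh:
            pickle.dump(payload, fh)

    @classmethod
    def load(cls, path: str | Path) -> "FeatureClassifier":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        if payload.get("format_version") != _MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format in {path}")
        return payload["model"]


def fit(
    train: FeatureMatrix,
    features: Sequence[str],
    params: SVMParams | None = None,
    seed: int = 0,
) -> FeatureClassifier:
    """Train an RBF-SVM on the given feature columns.

    Features are z-scored with the training mean/SD (stored on the model);
    missing training values are imputed with the training column mean.
    Raises on a single-class training set or a constant feature.
    """
    params = params or SVMParams()
    features = list(features)
    classes = set(train.y.dropna().unique())
    if classes != {HOT, NON_HOT}:
        raise ValueError(f"training set must contain both classes, got {sorted(classes)}")
    X = train.X[features].to_numpy(dtype=float)
    col_mean = np.nanmean(X, axis=0)
    idx = np.where(np.isnan(X))
    X[idx] = col_mean[idx[1]]
    col_sd = X.std(axis=0, ddof=0)
    constant = [f for f, s in zip(features, col_sd) if s == 0]
    if constant:
        raise ValueError(f"constant feature(s) cannot be trained on: {constant}")
    z = (X - col_mean) / col_sd
    svm = SVC(
        kernel="rbf",
        C=params.C,
        gamma=params.resolved_gamma(len(features)),
        class_weight=params.class_weight,
        random_state=seed,
    )
    svm.fit(z, train.y.to_numpy(dtype=object))
    return FeatureClassifier(
        feature_names=features,
        norm_mean=col_mean,
        norm_sd=col_sd,
        svm=svm,
        params=params,
        n_train=train.n,
        seed=seed,
    )


def _folds(matrix: FeatureMatrix, cv: CVConfig):
    if cv.k > matrix.n:
        raise ValueError(f"k={cv.k} folds exceed n={matrix.n} rows")
    labels = matrix.y.to_numpy(dtype=object)
    if cv.stratified:
        splitter = StratifiedKFold(n_splits=cv.k, shuffle=True, random_state=cv.seed)
    else:
        splitter = KFold(n_splits=cv.k, shuffle=True, random_state=cv.seed)
    yield from splitter.split(np.zeros(matrix.n), labels)


def _pool_confusion(y_true: pd.Series, y_pred: pd.Series) -> ConfusionMatrix:
    tp = int(((y_true == HOT) & (y_pred == HOT)).sum())
    tn = int(((y_true == NON_HOT) & (y_pred == NON_HOT)).sum())
    fp = int(((y_true == NON_HOT) & (y_pred == HOT)).sum())
    fn = int(((y_true == HOT) & (y_pred == NON_HOT)).sum())
    return ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn)


def cross_validate(
    data: FeatureMatrix,
    features: Sequence[str],
    cv: CVConfig | None = None,
    params: SVMParams | None = None,
) -> ConfusionMatrix:
    """Pooled k-fold cross-validated confusion matrix for one SVM.

    Every row is predicted exactly once, by a model that never saw it in
    training; stratified folds keep the class ratio within ±1 per fold.
    """
    cv = cv or CVConfig()
    preds = pd.Series(index=data.X.index, dtype=object)
    for train_idx, test_idx in _folds(data, cv):
        fold_train = FeatureMatrix(
            X=data.X.iloc[train_idx].copy(), y=data.y.iloc[train_idx]
        )
        model = fit(fold_train, features, params=params, seed=cv.seed)
        preds.iloc[test_idx] = model.predict(data.X.iloc[test_idx]).to_numpy()
    return _pool_confusion(data.y, preds)


def majority_vote(member_predictions: Sequence[Sequence[str]]) -> list[str]:
    """Combine per-member label sequences into one label per row.

    The label with strictly more votes wins; an exact tie (even committee)
    goes to hot.
    """
    if len(member_predictions) == 0:
        raise ValueError("majority_vote needs at least one member")
    arrays = [np.asarray(p, dtype=object) for p in member_predictions]
    n = len(arrays[0])
    if any(len(a) != n for a in arrays):
        raise ValueError("member prediction lengths differ")
    out: list[str] = []
    for i in range(n):
        hot_votes = sum(a[i] == HOT for a in arrays)
        out.append(HOT if hot_votes * 2 >= len(arrays) else NON_HOT)
    return out


@dataclasses.dataclass
class EnsembleModel:
    """A majority-vote committee of single-feature classifiers."""

    members: list[FeatureClassifier]
    member_cv_f1: dict[str, float] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble needs at least one member")

    @property
    def member_features(self) -> list[str]:
        return [m.feature_names[0] for m in self.members]

    def predict(self, rows: pd.DataFrame) -> pd.Series:
        votes = [m.predict(rows).to_numpy(dtype=object) for m in self.members]
        return pd.Series(majority_vote(votes), index=rows.index, dtype=object)

    def save(self, path: str | Path) -> None:
        payload = {"format_version": _MODEL_FORMAT_VERSION, "model": self}
        with open(path, "wb") as fh:
            pickle.dump(payload, fh)

    @classmethod
    def load(cls, path: str | Path) -> "EnsembleModel":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        if payload.get("format_version") != _MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format in {path}")
        return payload["model"]


def cross_validate_ensemble(
    data: FeatureMatrix,
    member_features: Sequence[str],
    cv: CVConfig | None = None,
    params: SVMParams | None = None,
) -> ConfusionMatrix:
    """Cross-validate the whole committee: members are refit on each fold's
    training split and vote on the held-out rows."""
    cv = cv or CVConfig()
    preds = pd.Series(index=data.X.index, dtype=object)
    for train_idx, test_idx in _folds(data, cv):
        fold_train = FeatureMatrix(
            X=data.X.iloc[train_idx].copy(), y=data.y.iloc[train_idx]
        )
        test_rows = data.X.iloc[test_idx]
        votes = []
        for feature in member_features:
            model = fit(fold_train, [feature], params=params, seed=cv.seed)
            votes.append(model.predict(test_rows).to_numpy(dtype=object))
        preds.iloc[test_idx] = majority_vote(votes)
    return _pool_confusion(data.y, preds)


def build_apis(
    data: FeatureMatrix,
    candidate_features: Sequence[str],
    member_rule: str = "top_k",
    k: int = 3,
    f1_threshold: float | None = None,
    cv: CVConfig | None = None,
    params: SVMParams | None = None,
    scores: dict[str, float] | None = None,
) -> EnsembleModel:
    """Build the majority-vote ensemble from single-feature classifiers.

    Candidates are scored by cross-validated F1 *on the training data* (the
    leakage-free rule); ``member_rule`` is ``"top_k"`` (default k = 3) or
    ``"f1_threshold"``.  Passing ``scores`` overrides the internal scoring
    with externally computed per-feature F1 values (e.g. test-set scores,
    for reproducing historical groupings that selected members that way).
    An even member count is reduced by dropping the weakest so the vote
    cannot tie by construction.  Members are then refit on the full
    training data.
    """
    cv = cv or CVConfig()
    if scores is None:
        scores = {}
        for feature in candidate_features:
            cm = cross_validate(data, [feature], cv=cv, params=params)
            scores[feature] = metrics(cm).f1
    else:
        scores = {f: scores[f] for f in candidate_features}
    ranked = sorted(scores, key=lambda f: (-scores[f], f))
    if member_rule == "top_k":
        chosen = ranked[:k]
    elif member_rule == "f1_threshold":
        if f1_threshold is None:
            raise ValueError("f1_threshold rule needs a threshold")
        chosen = [f for f in ranked if scores[f] > f1_threshold]
    else:
        raise ValueError(f"unknown member rule {member_rule!r}")
    if len(chosen) % 2 == 0 and len(chosen) > 1:
        chosen = chosen[:-1]  # enforce odd committee
    if not chosen:
        raise ValueError("no qualifying ensemble members")
    members = [fit(data, [f], params=params, seed=cv.seed) for f in chosen]
    return EnsembleModel(members=members, member_cv_f1={f: scores[f] for f in chosen})
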