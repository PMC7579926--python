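"""Shared learner and cross-validation machinery.

Elastic-net penalized logistic regression is parameterized glmnet-style:
the penalty is lambda * (alpha * |b|_1 + (1 - alpha)/2 * |b|_2^2) applied to
the mean log-loss, which maps onto scikit-learn's saga solver via
C = 1 / (n * lambda).  Features are standardized internally (train
statistics), as glmnet does by default, and coefficients are reported on the
original feature scale.

The linear SVM produces probabilities through Platt-type logistic
calibration of its margins fitted on the training data, so its output can be
averaged with logistic models.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

__all__ = [
    "ElasticNetLogistic",
    "PlattSVM",
    "ProbabilityEnsemble",
    "balanced_folds",
    "one_se_select",
]


class ElasticNetLogistic(BaseEstimator, ClassifierMixin):
    """Elastic-net logistic regression with glmnet-style (alpha, lambda)."""

    def __init__(self, alpha: float = 0.5, lam: float = 0.1, max_iter: int = 2000):
        self.alpha = alpha
        self.lam = lam
        self.max_iter = max_iter

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("binary labels required")
        yb = (y == self.classes_[1]).astype(int)
        self._mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        self._sd = np.where(sd > 0, sd, 1.0)
        Xs = (X - self._mean) / self._sd
        n = X.shape[0]
        C = 1.0 / max(n * self.lam, 1e-12)
        self._lr = LogisticRegression(
            solver="saga",
            l1_ratio=float(np.clip(self.alpha, 0.0, 1.0)),
            C=C,
            max_iter=self.max_iter,
            tol=1e-5,
            random_state=0,
        ).fit(Xs, yb)
        # coefficients on the original feature scale
        self.coef_ = (self._lr.coef_[0] / self._sd)[None, :]
        self.intercept_ = np.array(
            [self._lr.intercept_[0] - float(np.sum(self._lr.coef_[0] * self._mean / self._sd))]
        )
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=float)
        return X @ self.coef_[0] + self.intercept_[0]

    def predict_proba(self, X):
        p = expit(self.decision_function(X))
        return np.column_stack([1 - p, p])

    def predict(self, X):
        return self.classes_[(self.decision_function(X) > 0).astype(int)]


class PlattSVM(BaseEstimator, ClassifierMixin):
    """Linear SVM with logistic (Platt) calibration of training margins."""

    def __init__(self, C: float = 1.0, max_iter: int = 5000):
        self.C = C
        self.max_iter = max_iter

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("binary labels required")
        yb = (y == self.classes_[1]).astype(int)
        self._mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        self._sd = np.where(sd > 0, sd, 1.0)
        Xs = (X - self._mean) / self._sd
        self._svm = LinearSVC(
            C=self.C, max_iter=self.max_iter, dual="auto", random_state=0
        ).fit(Xs, yb)
        margins = self._svm.decision_function(Xs)
        # Platt scaling: 1-d logistic fit of labels on margins
        platt = LogisticRegression(C=1e6, max_iter=1000).fit(margins[:, None], yb)
        self.platt_a_ = float(platt.coef_[0, 0])
        self.platt_b_ = float(platt.intercept_[0])
        self.coef_ = (self._svm.coef_[0] / self._sd)[None, :]
        self.intercept_ = np.array(
            [self._svm.intercept_[0] - float(np.sum(self._svm.coef_[0] * self._mean / self._sd))]
        )
        self.n_features_in_ = X.shape[1]
        return self

    def margin(self, X):
        X = np.asarray(X, dtype=float)
        return X @ self.coef_[0] + self.intercept_[0]

    def decision_function(self, X):
        return self.margin(X) * self.platt_a_ + self.platt_b_

    def predict_proba(self, X):
        p = expit(self.decision_function(X))
        return np.column_stack([1 - p, p])

    def predict(self, X):
        return self.classes_[(self.decision_function(X) > 0).astype(int)]


class ProbabilityEnsemble(BaseEstimator, ClassifierMixin):
    """Uniform average of member predicted probabilities."""

    def __init__(self, members: list):
        self.members = members

    def fit(self, X, y):
        self.classes_ = np.unique(np.asarray(y))
        self.members_ = [m.fit(X, y) for m in self.members]
        return self

    def predict_proba(self, X):
        p = np.mean([m.predict_proba(X)[:, 1] for m in self.members_], axis=0)
        return np.column_stack([1 - p, p])

    def decision_function(self, X):
        p = np.clip(self.predict_proba(X)[:, 1], 1e-12, 1 - 1e-12)
        return np.log(p / (1 - p))


def balanced_folds(
    strata: pd.Series | np.ndarray,
    y: np.ndarray,
    n_folds: int,
    rng: np.random.Generator,
    max_attempts: int = 10,
) -> list[np.ndarray]:
    """Stratum-balanced fold assignment.

    Folds are drawn with a stratified splitter on the composite stratum
    label, preserving every stratum's proportion within +-1 sample per fold.
    A partition leaving any fold with a single outcome class is redrawn with
    a fresh sub-seed (up to ``max_attempts``).
    """
    strata = np.asarray(pd.Series(strata).astype(str))
    y = np.asarray(y)
    # rare strata (< n_folds members) are merged so the splitter stays valid
    vals, counts = np.unique(strata, return_counts=True)
    rare = set(vals[counts < n_folds])
    if rare:
        strata = np.where(np.isin(strata, list(vals[counts < n_folds])), "_rare_", strata)
    for _ in range(max_attempts):
        seed = int(rng.integers(0, 2**31 - 1))
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        folds = [test for _, test in skf.split(np.zeros(len(y)), strata)]
        if all(len(np.unique(y[f])) == len(np.unique(y)) for f in folds):
            return folds
    raise RuntimeError("could not draw a class-complete balanced partition")


def one_se_select(results: list[dict], metric: str = "mean", se: str = "se", reg: str = "reg"):
    """One-standard-error rule.

    ``results`` carry a mean CV metric, its standard error and a
    regularization key (larger = more regularized).  Returns the most
    regularized configuration whose mean is within one SE of the best.
    """
    if not results:
        raise ValueError("no configurations to select from")
    best = max(results, key=lambda r: r[metric])
    floor = best[metric] - best[se]
    eligible = [r for r in results if r[metric] >= floor]
    return max(eligible, key=lambda r: r[reg])
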