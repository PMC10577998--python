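"""Base-learner library for the stacking ensemble.

Five learners, mirroring a conventional country-level SuperLearner
library: main-effects linear model, forward-stepwise regression (AIC),
L1-regularized linear model, MARS, and a random forest with 500 trees,
2 candidate variables per split, and minimum node size 5 for regression
/ 1 for classification.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import (LassoCV, LinearRegression,
                                  LogisticRegression, LogisticRegressionCV)
from sklearn.multiclass import OneVsRestClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from .mars import MARSClassifier, MARSRegressor

LEARNER_NAMES = ("linear_main_effects", "stepwise_forward", "l1_linear",
                 "mars", "random_forest")

#: printed default hyperparameters
DEFAULT_HYPERPARAMS = {
    "mars": {"max_degree": 2},
    "random_forest": {"n_trees": 500, "vars_per_split": 2,
                      "min_node_size_regression": 5,
                      "min_node_size_classification": 1},
}


class ForwardStepwiseOLS(BaseEstimator, RegressorMixin):
    """Forward selection from the intercept over main effects, by AIC."""

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, p = X.shape

        def _aic(cols):
            Z = np.column_stack([np.ones(n)] + [X[:, j] for j in cols])
            coef, *_ = np.linalg.lstsq(Z, y, rcond=None)
            rss = float(np.sum((y - Z @ coef) ** 2))
            rss = max(rss, 1e-12)
            return n * np.log(rss / n) + 2 * (len(cols) + 1), coef

        selected: list[int] = []
        best_aic, best_coef = _aic(selected)
        improved = True
        while improved and len(selected) < p:
            improved = False
            trial = None
            for j in range(p):
                if j in selected:
                    continue
                aic, coef = _aic(selected + [j])
                if trial is None or aic < trial[0]:
                    trial = (aic, j, coef)
            if trial is not None and trial[0] < best_aic - 1e-9:
                best_aic, _, best_coef = trial
                selected.append(trial[1])
                improved = True
        self.selected_ = selected
        self.coef_ = best_coef
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        Z = np.column_stack([np.ones(X.shape[0])]
                            + [X[:, j] for j in self.selected_])
        return Z @ self.coef_


class ForwardStepwiseMultinomial(BaseEstimator, ClassifierMixin):
    """Forward-stepwise multinomial logistic regression by AIC."""

    def __init__(self, max_iter=1000):
        self.max_iter = max_iter

    def _fit_subset(self, X, y, cols):
        n = X.shape[0]
        K = len(self.classes_)
        if not cols:
            # intercept-only model: marginal class frequencies
            p = np.bincount(self._y_idx, minlength=K) / n
            ll = float(np.sum(np.log(np.maximum(p[self._y_idx], 1e-12))))
            return 2 * (K - 1) - 2 * ll, p
        est = LogisticRegression(C=np.inf, max_iter=self.max_iter)
        est.fit(X[:, cols], y)
        proba = est.predict_proba(X[:, cols])
        ll = float(np.sum(np.log(np.maximum(
            proba[np.arange(n), self._y_idx], 1e-12))))
        k_par = (K - 1) * (len(cols) + 1)
        return 2 * k_par - 2 * ll, est

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        # standardize once: unpenalized lbfgs converges far faster and
        # selection/predictions are scale-invariant
        self._mu = X.mean(axis=0)
        self._sd = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
        X = (X - self._mu) / self._sd
        self.classes_, self._y_idx = np.unique(y, return_inverse=True)
        p = X.shape[1]
        selected: list[int] = []
        best_aic, best_model = self._fit_subset(X, y, selected)
        improved = True
        while improved and len(selected) < p:
            improved = False
            trial = None
            for j in range(p):
                if j in selected:
                    continue
                aic, model = self._fit_subset(X, y, selected + [j])
                if trial is None or aic < trial[0]:
                    trial = (aic, j, model)
            if trial is not None and trial[0] < best_aic - 1e-9:
                best_aic, _, best_model = trial
                selected.append(trial[1])
                improved = True
        self.selected_ = selected
        self.model_ = best_model
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        X = (np.asarray(X, dtype=float) - self._mu) / self._sd
        if not self.selected_:
            return np.tile(self.model_, (X.shape[0], 1))
        return self.model_.predict_proba(X[:, self.selected_])

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


class L1MultinomialOVR(BaseEstimator, ClassifierMixin):
    """One-vs-rest L1 logistic regression with inner CV over the penalty,
    probabilities renormalized across classes."""

    def __init__(self, Cs=10, cv=3, random_state=None):
        self.Cs = Cs
        self.cv = cv
        self.random_state = random_state

    def fit(self, X, y):
        base = LogisticRegressionCV(
            Cs=self.Cs, cv=self.cv, penalty="l1", solver="liblinear",
            max_iter=500, random_state=self.random_state)
        self.est_ = make_pipeline(StandardScaler(),
                                  OneVsRestClassifier(base))
        self.est_.fit(X, y)
        self.classes_ = self.est_[-1].classes_
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "est_")
        proba = self.est_.predict_proba(X)
        proba = np.clip(proba, 1e-9, None)
        return proba / proba.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def make_learner(name: str, mode: str, seed: int | None = None,
                 hyperparameters: dict | None = None):
    """Instantiate a base learner by library name and task mode."""
    hp = hyperparameters or {}
    if mode not in ("regression", "multiclass"):
        raise ValueError(f"unknown mode {mode!r}")
    if name == "linear_main_effects":
        if mode == "regression":
            return LinearRegression()
        return make_pipeline(StandardScaler(),
                             LogisticRegression(C=np.inf, max_iter=5000))
    if name == "stepwise_forward":
        if mode == "regression":
            return ForwardStepwiseOLS()
        return ForwardStepwiseMultinomial()
    if name == "l1_linear":
        if mode == "regression":
            return make_pipeline(StandardScaler(),
                                 LassoCV(cv=hp.get("inner_cv", 5),
                                         random_state=seed))
        return L1MultinomialOVR(cv=hp.get("inner_cv", 3), random_state=seed)
    if name == "mars":
        deg = hp.get("max_degree", DEFAULT_HYPERPARAMS["mars"]["max_degree"])
        cls = MARSRegressor if mode == "regression" else MARSClassifier
        return cls(max_degree=deg)
    if name == "random_forest":
        rf_hp = DEFAULT_HYPERPARAMS["random_forest"]
        n_trees = hp.get("n_trees", rf_hp["n_trees"])
        mtry = hp.get("vars_per_split", rf_hp["vars_per_split"])
        if mode == "regression":
            return RandomForestRegressor(
                n_estimators=n_trees, max_features=mtry,
                min_samples_leaf=hp.get("min_node_size",
                                        rf_hp["min_node_size_regression"]),
                random_state=seed, n_jobs=1)
        return RandomForestClassifier(
            n_estimators=n_trees, max_features=mtry,
            min_samples_leaf=hp.get("min_node_size",
                                    rf_hp["min_node_size_classification"]),
            random_state=seed, n_jobs=1)
    raise ValueError(f"unknown learner {name!r}; "
                     f"library: {sorted(LEARNER_NAMES)}")
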