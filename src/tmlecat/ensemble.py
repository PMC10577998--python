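"""Cross-validated stacking ("SuperLearner") ensembles.

Out-of-fold predictions from every base learner are assembled over a
seeded K-fold split; meta-weights on the probability simplex are chosen
to minimize cross-validated risk (squared error for regression,
multinomial log-loss for the exposure mechanism); base learners are then
refit on the full sample and combined with those weights.

Meta-learning: non-negative least squares with normalization for
regression; projected-gradient descent on the simplex for log-loss.
A learner that raises on any fold is dropped from the library with a
warning and the weights are renormalized over the survivors.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import nnls
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin, clone
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .learners import LEARNER_NAMES, make_learner

PROB_CLIP = (1e-6, 1.0 - 1e-6)

__all__ = ["SuperLearnerRegressor", "SuperLearnerClassifier",
           "fit_superlearner", "cv_performance", "project_simplex"]


def project_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection onto the probability simplex."""
    v = np.asarray(v, dtype=float)
    u = np.sort(v)[::-1]
    css = np.cumsum(u) - 1.0
    rho = np.nonzero(u - css / (np.arange(len(v)) + 1) > 0)[0][-1]
    theta = css[rho] / (rho + 1.0)
    return np.maximum(v - theta, 0.0)


def _build_library(learners, mode, seed, hyperparameters):
    if learners is None:
        learners = list(LEARNER_NAMES)
    lib = []
    for item in learners:
        if isinstance(item, str):
            hp = (hyperparameters or {}).get(item, {})
            lib.append((item, make_learner(item, mode, seed=seed,
                                           hyperparameters=hp)))
        else:  # (name, estimator) pair
            lib.append(tuple(item))
    return lib


class _SuperLearnerBase(BaseEstimator):
    def __init__(self, learners=None, folds=10, seed=0, hyperparameters=None):
        self.learners = learners
        self.folds = folds
        self.seed = seed
        self.hyperparameters = hyperparameters

    def _check_X(self, X):
        X = np.asarray(X, dtype=float)
        if hasattr(self, "n_features_in_") and X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature mismatch: model was fit with {self.n_features_in_} "
                f"columns, got {X.shape[1]}")
        return X


class SuperLearnerRegressor(_SuperLearnerBase, RegressorMixin):
    """Stacked regression ensemble with NNLS simplex meta-weights.

    Fitted attributes: ``weights_`` (simplex), ``cv_risks_`` (per-learner
    mean squared out-of-fold error), ``oof_predictions_``,
    ``fold_assignment_``, ``cv_r2_``, ``learner_names_``, ``learners_``.
    """

    mode = "regression"

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n = len(y)
        if np.ptp(y) == 0:
            raise ValueError("degenerate target: outcome is constant")
        if not 2 <= self.folds <= n:  # folds == n is leave-one-out
            raise ValueError(f"need 2 <= folds <= n, got n={n}, "
                             f"folds={self.folds}")
        lib = _build_library(self.learners, self.mode, self.seed,
                             self.hyperparameters)

        kf = KFold(n_splits=self.folds, shuffle=True, random_state=self.seed)
        fold_of = np.empty(n, dtype=int)
        Z = np.full((n, len(lib)), np.nan)
        failed = set()
        for f, (tr, te) in enumerate(kf.split(X)):
            fold_of[te] = f
            for li, (name, est) in enumerate(lib):
                if li in failed:
                    continue
                try:
                    m = clone(est).fit(X[tr], y[tr])
                    Z[te, li] = m.predict(X[te])
                except Exception as exc:  # noqa: BLE001 - learner dropout
                    warnings.warn(f"learner {name!r} failed on fold {f} "
                                  f"({exc}); dropping it", stacklevel=2)
                    failed.add(li)
        keep = [li for li in range(len(lib)) if li not in failed]
        if not keep:
            raise RuntimeError("every base learner failed")
        lib = [lib[li] for li in keep]
        Z = Z[:, keep]

        # NNLS start, then projected-gradient refinement on the simplex:
        # the MSE meta-objective is convex, so this reaches the simplex
        # optimum (plain NNLS normalization does not guarantee it)
        w, _ = nnls(Z, y)
        if w.sum() <= 0:
            w = np.zeros(len(lib))
            w[int(np.argmin(np.mean((Z - y[:, None]) ** 2, axis=0)))] = 1.0
        w = _minimize_mse_simplex(Z, y, w / w.sum())

        self.learner_names_ = [name for name, _ in lib]
        self.learners_ = [clone(est).fit(X, y) for _, est in lib]
        self.weights_ = w
        self.cv_risks_ = np.mean((Z - y[:, None]) ** 2, axis=0)
        self.oof_predictions_ = Z
        self.fold_assignment_ = fold_of
        oof = Z @ w
        sst = float(np.sum((y - y.mean()) ** 2))
        self.cv_r2_ = 1.0 - float(np.sum((y - oof) ** 2)) / sst
        self.meta_risk_ = float(np.mean((y - oof) ** 2))
        self.n_features_in_ = X.shape[1]
        self._oof_target = y
        return self

    def predict(self, X):
        check_is_fitted(self, "weights_")
        X = self._check_X(X)
        P = np.column_stack([m.predict(X) for m in self.learners_])
        return P @ self.weights_


def _minimize_mse_simplex(Z, y, w0, max_iter=2000, tol=1e-12):
    n = Z.shape[0]
    w = project_simplex(w0)
    obj = float(np.mean((Z @ w - y) ** 2))
    step = 1.0
    for _ in range(max_iter):
        grad = 2.0 / n * Z.T @ (Z @ w - y)
        while True:
            w_new = project_simplex(w - step * grad)
            obj_new = float(np.mean((Z @ w_new - y) ** 2))
            if obj_new <= obj + 1e-16 or step < 1e-14:
                break
            step *= 0.5
        if abs(obj - obj_new) < tol and np.allclose(w, w_new, atol=1e-12):
            return w_new
        w, obj = w_new, obj_new
        step = min(step * 2.0, 10.0)
    return w


def _log_loss(stack, w, y_idx):
    """stack: (L, n, K) probability tensor; returns mean negative
    log-likelihood of the convex combination."""
    P = np.tensordot(w, stack, axes=1)
    P = np.clip(P, 1e-12, None)
    return -float(np.mean(np.log(P[np.arange(P.shape[0]), y_idx])))


def _minimize_log_loss_simplex(stack, y_idx, max_iter=2000, tol=1e-8):
    L, n, _ = stack.shape
    w = np.full(L, 1.0 / L)
    obj = _log_loss(stack, w, y_idx)
    lik = stack[:, np.arange(n), y_idx]  # (L, n) per-learner likelihoods
    step = 1.0
    for _ in range(max_iter):
        denom = np.clip(w @ lik, 1e-12, None)
        grad = -np.mean(lik / denom, axis=1)
        # backtracking projected gradient
        while True:
            w_new = project_simplex(w - step * grad)
            obj_new = _log_loss(stack, w_new, y_idx)
            if obj_new <= obj + 1e-14 or step < 1e-12:
                break
            step *= 0.5
        if abs(obj - obj_new) < tol and np.allclose(w, w_new, atol=1e-10):
            w, obj = w_new, obj_new
            break
        w, obj = w_new, obj_new
        step = min(step * 2.0, 10.0)
    return w, obj


class SuperLearnerClassifier(_SuperLearnerBase, ClassifierMixin):
    """Stacked multiclass ensemble; meta-weights minimize cross-validated
    multinomial log-loss over the simplex.

    Fitted attributes mirror the regressor, with ``cv_auc_`` (macro
    one-vs-rest AUC on out-of-fold probabilities) as the performance
    indicator and ``oof_proba_`` as the (n, K) combined matrix.
    """

    mode = "multiclass"

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        K = len(self.classes_)
        n = len(y)
        if K < 2:
            raise ValueError("degenerate target: a single class present")
        counts = np.bincount(y_idx)
        if counts.min() < self.folds:
            raise ValueError(
                f"smallest class has {counts.min()} rows < folds="
                f"{self.folds}; use fewer folds")
        lib = _build_library(self.learners, self.mode, self.seed,
                             self.hyperparameters)

        skf = StratifiedKFold(n_splits=self.folds, shuffle=True,
                              random_state=self.seed)
        fold_of = np.empty(n, dtype=int)
        stack = np.full((len(lib), n, K), np.nan)
        failed = set()
        for f, (tr, te) in enumerate(skf.split(X, y_idx)):
            fold_of[te] = f
            for li, (name, est) in enumerate(lib):
                if li in failed:
                    continue
                try:
                    m = clone(est).fit(X[tr], y[tr])
                    proba = m.predict_proba(X[te])
                    # align columns in case a learner saw a class subset
                    aligned = np.full((len(te), K), 1e-12)
                    for ci, cls in enumerate(m.classes_):
                        aligned[:, int(np.searchsorted(self.classes_, cls))] \
                            = proba[:, ci]
                    stack[li, te] = aligned
                except Exception as exc:  # noqa: BLE001 - learner dropout
                    warnings.warn(f"learner {name!r} failed on fold {f} "
                                  f"({exc}); dropping it", stacklevel=2)
                    failed.add(li)
        keep = [li for li in range(len(lib)) if li not in failed]
        if not keep:
            raise RuntimeError("every base learner failed")
        lib = [lib[li] for li in keep]
        stack = stack[keep]

        w, meta_risk = _minimize_log_loss_simplex(stack, y_idx)
        self.learner_names_ = [name for name, _ in lib]
        self.learners_ = [clone(est).fit(X, y) for _, est in lib]
        self.weights_ = w
        self.cv_risks_ = np.array([_log_loss(stack[li:li + 1], np.ones(1),
                                             y_idx)
                                   for li in range(len(lib))])
        self.meta_risk_ = meta_risk
        self.oof_stack_ = stack
        self.fold_assignment_ = fold_of
        oof = np.tensordot(w, stack, axes=1)
        self.oof_proba_ = oof / oof.sum(axis=1, keepdims=True)
        if K == 2:
            self.cv_auc_ = float(roc_auc_score(y_idx, self.oof_proba_[:, 1]))
        else:
            self.cv_auc_ = float(roc_auc_score(y_idx, self.oof_proba_,
                                               multi_class="ovr",
                                               average="macro"))
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "weights_")
        X = self._check_X(X)
        K = len(self.classes_)
        out = np.zeros((X.shape[0], K))
        for w, m in zip(self.weights_, self.learners_):
            proba = m.predict_proba(X)
            aligned = np.full((X.shape[0], K), 1e-12)
            for ci, cls in enumerate(m.classes_):
                aligned[:, int(np.searchsorted(self.classes_, cls))] \
                    = proba[:, ci]
            out += w * aligned
        out = np.clip(out, *PROB_CLIP)
        return out / out.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def fit_superlearner(features, target, mode="regression", folds=10, seed=0,
                     learners=None, hyperparameters=None):
    """Functional wrapper: fit and return the ensemble for ``mode``."""
    cls = (SuperLearnerRegressor if mode == "regression"
           else SuperLearnerClassifier)
    est = cls(learners=learners, folds=folds, seed=seed,
              hyperparameters=hyperparameters)
    return est.fit(np.asarray(features, dtype=float), target)


def cv_performance(model) -> float:
    """Cross-validated R^2 (regression) or macro one-vs-rest AUC
    (multiclass), computed from out-of-fold predictions only."""
    if isinstance(model, SuperLearnerRegressor):
        check_is_fitted(model, "cv_r2_")
        return model.cv_r2_
    if isinstance(model, SuperLearnerClassifier):
        check_is_fitted(model, "cv_auc_")
        return model.cv_auc_
    raise TypeError("expected a fitted SuperLearner estimator")
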