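"""Multivariate adaptive regression splines (MARS).

Forward stagewise selection of mirrored hinge-function pairs
max(x_j - t, 0) / max(t - x_j, 0), optionally multiplied into an existing
degree-1 term (maximum interaction degree 2 by default), followed by a
backward pruning pass scored by generalized cross-validation (GCV).

Knot candidates are interior sample quantiles of each feature, and the
forward search screens candidates by squared residual correlation before
exact least-squares evaluation of a short list — this keeps fitting
near-linear in n while preserving the greedy selection on the problems the
package targets (n up to a few thousand, p around a dozen).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.utils.validation import check_is_fitted


def _hinge(x, knot, sign):
    return np.maximum(sign * (x - knot), 0.0)


class MARSRegressor(BaseEstimator, RegressorMixin):
    """MARS for regression.

    Parameters
    ----------
    max_terms : int
        Cap on basis functions (including the intercept) after the
        forward pass.
    max_degree : int
        Maximum number of hinge factors multiplied into one term.
    n_knot_candidates : int
        Interior quantile knots considered per feature.
    penalty : float
        GCV cost per knot (Friedman's d; 3 is customary with
        interactions).
    n_exact : int
        Candidates evaluated by exact least squares per forward step
        after correlation screening.
    """

    def __init__(self, max_terms=21, max_degree=2, n_knot_candidates=15,
                 penalty=3.0, n_exact=8):
        self.max_terms = max_terms
        self.max_degree = max_degree
        self.n_knot_candidates = n_knot_candidates
        self.penalty = penalty
        self.n_exact = n_exact

    # a term is a tuple of (feature, knot, sign) factors; () = intercept
    def _term_column(self, X, term):
        col = np.ones(X.shape[0])
        for j, t, s in term:
            col = col * _hinge(X[:, j], t, s)
        return col

    def _basis(self, X, terms):
        return np.column_stack([self._term_column(X, t) for t in terms])

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        q = np.linspace(0, 1, self.n_knot_candidates + 2)[1:-1]
        knots = [np.unique(np.quantile(X[:, j], q)) for j in range(p)]

        # precompute hinge columns for all (feature, knot, sign)
        cand_meta, cand_cols = [], []
        for j in range(p):
            for t in knots[j]:
                for s in (+1.0, -1.0):
                    cand_meta.append((j, float(t), s))
                    cand_cols.append(_hinge(X[:, j], t, s))
        H = np.column_stack(cand_cols) if cand_cols else np.empty((n, 0))
        H2 = H * H

        terms = [()]
        B = np.ones((n, 1))
        coef, *_ = np.linalg.lstsq(B, y, rcond=None)
        resid = y - B @ coef
        sst = max(float(resid @ resid), 1e-12)

        while len(terms) + 2 <= self.max_terms and H.shape[1]:
            # screen (parent, hinge) candidates by squared correlation of
            # the residual with the product column
            scores, pool = [], []
            for ti, term in enumerate(terms):
                if len(term) >= self.max_degree:
                    continue
                used = {f[0] for f in term}
                b = self._term_column(X, term)
                rb = resid * b
                num = rb @ H
                den = (b * b) @ H2 + 1e-12
                sc = num * num / den
                for ci, meta in enumerate(cand_meta):
                    if meta[0] in used:
                        sc[ci] = -np.inf
                scores.append(sc)
                pool.append(ti)
            if not pool:
                break
            S = np.vstack(scores)
            flat = np.argsort(S, axis=None)[::-1][:self.n_exact]
            best = None
            for f in flat:
                ti, ci = np.unravel_index(f, S.shape)
                if not np.isfinite(S[ti, ci]):
                    continue
                parent = terms[pool[ti]]
                j, t, s = cand_meta[ci]
                pair = [parent + ((j, t, +1.0),), parent + ((j, t, -1.0),)]
                Bc = np.column_stack([B] + [self._term_column(X, tm)
                                            for tm in pair])
                c, res_ss, rank, _ = np.linalg.lstsq(Bc, y, rcond=None)
                r = y - Bc @ c
                ss = float(r @ r)
                if best is None or ss < best[0]:
                    best = (ss, pair, Bc)
            if best is None:
                break
            ss, pair, Bc = best
            if (float(resid @ resid) - ss) < 1e-8 * sst:
                break
            terms = terms + pair
            B = Bc
            coef, *_ = np.linalg.lstsq(B, y, rcond=None)
            resid = y - B @ coef

        terms, coef = self._prune(B, y, terms)
        self.terms_ = terms
        self.coef_ = coef
        self.n_features_in_ = p
        return self

    def _gcv(self, rss, n, m):
        c = m + self.penalty * (m - 1) / 2.0
        denom = (1.0 - c / n) ** 2 if c < n else np.inf
        return rss / n / denom if np.isfinite(denom) else np.inf

    def _prune(self, B, y, terms):
        n = B.shape[0]
        active = list(range(len(terms)))

        def _fit(idx):
            c, *_ = np.linalg.lstsq(B[:, idx], y, rcond=None)
            r = y - B[:, idx] @ c
            return c, float(r @ r)

        coef, rss = _fit(active)
        best = (self._gcv(rss, n, len(active)), list(active), coef)
        while len(active) > 1:
            trial = None
            for drop in active:
                if drop == 0:  # keep intercept
                    continue
                idx = [i for i in active if i != drop]
                c, rss = _fit(idx)
                g = self._gcv(rss, n, len(idx))
                if trial is None or g < trial[0]:
                    trial = (g, idx, c)
            if trial is None:
                break
            active = trial[1]
            if trial[0] < best[0]:
                best = trial
        _, idx, coef = best
        return [terms[i] for i in idx], coef

    def predict(self, X):
        check_is_fitted(self, "terms_")
        X = np.asarray(X, dtype=float)
        return self._basis(X, self.terms_) @ self.coef_


class MARSClassifier(BaseEstimator, ClassifierMixin):
    """One-vs-rest MARS: a regression fit per class indicator, with
    clipped and renormalized scores as probabilities."""

    def __init__(self, max_terms=21, max_degree=2, n_knot_candidates=15,
                 penalty=3.0):
        self.max_terms = max_terms
        self.max_degree = max_degree
        self.n_knot_candidates = n_knot_candidates
        self.penalty = penalty

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.estimators_ = []
        for cls in self.classes_:
            est = MARSRegressor(max_terms=self.max_terms,
                                max_degree=self.max_degree,
                                n_knot_candidates=self.n_knot_candidates,
                                penalty=self.penalty)
            est.fit(X, (y == cls).astype(float))
            self.estimators_.append(est)
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "estimators_")
        scores = np.column_stack([np.clip(e.predict(X), 1e-6, None)
                                  for e in self.estimators_])
        return scores / scores.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]
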