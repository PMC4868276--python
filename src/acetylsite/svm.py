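"""RBF-SVM plumbing: [-1,1] feature scaling, fixed fold plans, cross-validated
accuracy and cost/gamma grid search.

Scaling statistics are always computed on training folds only; a per-fold
pipeline refits the scaler inside each fold so validation data never leaks
into the scaling.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .errors import ContractError

#: The published lattice of the libsvm grid tool: cost 2^-5..2^15, gamma
#: 2^-15..2^3, both in steps of 2^2.
DEFAULT_COST_GRID = tuple(2.0 ** e for e in range(-5, 16, 2))
DEFAULT_GAMMA_GRID = tuple(2.0 ** e for e in range(-15, 4, 2))

#: A 3x3 coarsening for desk-scale runs (selection sweeps, simulations).
COARSE_COST_GRID = (2.0 ** -1, 2.0 ** 1, 2.0 ** 3)
COARSE_GAMMA_GRID = (2.0 ** -7, 2.0 ** -5, 2.0 ** -3)


class SymmetricMinMaxScaler(BaseEstimator, TransformerMixin):
    """Scale each feature to [-1, 1] by its training min/max (the libsvm
    convention); a feature constant in training maps to 0 everywhere,
    including at test time."""

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.min_ = X.min(axis=0)
        self.max_ = X.max(axis=0)
        span = self.max_ - self.min_
        self.constant_ = span == 0
        self.scale_ = np.where(self.constant_, 1.0, span)
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        out = 2.0 * (X - self.min_) / self.scale_ - 1.0
        out[:, self.constant_] = 0.0
        return out


def make_fold_plan(labels, n_splits: int = 5, seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """A fixed, stratified, shuffled K-fold plan: list of (train, test) index
    arrays, fully determined by the labels and the seed."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ContractError("fold plan requires both classes present")
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    return [(tr.copy(), te.copy()) for tr, te in skf.split(np.zeros(len(labels)), labels)]


def _fit_fold(X_tr, y_tr, cost: float, gamma: float):
    scaler = SymmetricMinMaxScaler().fit(X_tr)
    clf = SVC(C=cost, gamma=gamma, kernel="rbf")
    clf.fit(scaler.transform(X_tr), y_tr)
    return scaler, clf

def cv_accuracy(X, y, folds, cost: float, gamma: float) -> float:
    """Mean validation accuracy over a fixed fold plan, scaling per fold."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    accs = []
    for tr, te in folds:
        if len(np.unique(y[tr])) < 2:
            raise ContractError("degenerate fold: single-class training split")
        scaler, clf = _fit_fold(X[tr], y[tr], cost, gamma)
        accs.append(float(np.mean(clf.predict(scaler.transform(X[te])) == y[te])))
    return float(np.mean(accs))


def grid_search(
    X,
    y,
    folds,
    cost_grid: tuple[float, ...] = DEFAULT_COST_GRID,
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID,
) -> tuple[float, float, float]:
    """Exhaustive cost/gamma lattice search maximizing mean CV accuracy.

    Ties break toward smaller cost, then smaller gamma. Returns
    (cost, gamma, best_accuracy).
    """
    best = None
    for cost in sorted(cost_grid):
        for gamma in sorted(gamma_grid):
            acc = cv_accuracy(X, y, folds, cost, gamma)
            if best is None or acc > best[2]:
                best = (cost, gamma, acc)
    assert best is not None
    return best
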