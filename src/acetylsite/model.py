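"""RBF-SVM modelling surface.

``AcetylationSiteModel`` is built from a labelled FeatureMatrix; ``fit()``
runs per-subtype stepwise feature selection, tunes cost/gamma on the combined
selected set, trains the final SVM and returns an ``AcetylationFitResults``
carrying the selection manifest, the fitted classifier, a cross-validated
evaluation report and a ``summary()`` table. ``SvmModel`` is the lower-level
fitted classifier (scaling statistics + support vectors + feature-name list).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import joblib
import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .errors import ContractError
from .io import FeatureMatrix
from .metrics import ConfusionCounts, EvalReport, compute_auc, compute_metrics, evaluate
from .selection import SelectionResult, select_all_subtypes
from .svm import (
    COARSE_COST_GRID,
    COARSE_GAMMA_GRID,
    DEFAULT_COST_GRID,
    DEFAULT_GAMMA_GRID,
    SymmetricMinMaxScaler,
    grid_search,
    make_fold_plan,
)

__all__ = [
    "SvmModel",
    "AcetylationSiteModel",
    "AcetylationFitResults",
    "grid_search",
    "ConfusionCounts",
    "EvalReport",
    "compute_metrics",
    "compute_auc",
]


@dataclass
class SvmModel:
    """A fitted RBF-SVM with its scaling statistics and feature list.

    Prediction aligns columns by name (order-independent) and labels by the
    sign of the decision value.
    """

    cost: float
    gamma: float
    feature_names: list[str]
    scaler: SymmetricMinMaxScaler
    svc: SVC
    seed: int = 0

    @classmethod
    def fit(
        cls, fm: FeatureMatrix, cost: float, gamma: float, seed: int = 0
    ) -> "SvmModel":
        if fm.labels is None:
            raise ContractError("feature matrix has no labels")
        y = fm.labels.to_numpy()
        counts = np.bincount(y, minlength=2)
        if counts.min() < 2 or len(np.unique(y)) < 2:
            raise ContractError("fit requires at least 2 samples per class")
        X = fm.values.to_numpy(dtype=float)
        scaler = SymmetricMinMaxScaler().fit(X)
        svc = SVC(C=cost, gamma=gamma, kernel="rbf")
        svc.fit(scaler.transform(X), y)
        return cls(
            cost=cost, gamma=gamma, feature_names=list(fm.feature_names),
            scaler=scaler, svc=svc, seed=seed,
        )

    def decision_values(self, fm: FeatureMatrix) -> np.ndarray:
        missing = [n for n in self.feature_names if n not in fm.values.columns]
        if missing:
            raise ContractError(f"feature column(s) missing: {missing[:5]}")
        X = fm.values[self.feature_names].to_numpy(dtype=float)
        return self.svc.decision_function(self.scaler.transform(X))

    def predict(self, fm: FeatureMatrix) -> pd.DataFrame:
        """Per-site predicted label (decision value > 0) and decision value."""
        if fm.n_sites == 0:
            return pd.DataFrame(columns=["label", "decision"], index=fm.values.index)
        d = self.decision_values(fm)
        return pd.DataFrame(
            {"label": (d > 0).astype(int), "decision": d}, index=fm.values.index
        )

    def save(self, path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path) -> "SvmModel":
        obj = joblib.load(path)
        if not isinstance(obj, cls):
            raise ContractError(f"{path}: not a saved SvmModel")
        return obj


def cross_validated_report(
    fm: FeatureMatrix, cost: float, gamma: float, folds
) -> EvalReport:
    """Pooled K-fold evaluation: per fold, scale and fit on the training
    split only, then collect validation predictions and decision values;
    metrics are computed on the pooled out-of-fold predictions."""
    if fm.labels is None:
        raise ContractError("feature matrix has no labels")
    y = fm.labels.to_numpy()
    X = fm.values.to_numpy(dtype=float)
    y_pred = np.empty_like(y)
    decisions = np.empty(len(y), dtype=float)
    for tr, te in folds:
        scaler = SymmetricMinMaxScaler().fit(X[tr])
        svc = SVC(C=cost, gamma=gamma, kernel="rbf")
        svc.fit(scaler.transform(X[tr]), y[tr])
        d = svc.decision_function(scaler.transform(X[te]))
        decisions[te] = d
        y_pred[te] = (d > 0).astype(int)
    return evaluate(y, y_pred, decisions)


@dataclass
class AcetylationFitResults:
    """Estimates and diagnostics from a fitted acetylation-site model."""

    selection: SelectionResult
    model: SvmModel
    cv_report: EvalReport
    seed: int
    config: dict

    def predict(self, fm: FeatureMatrix) -> pd.DataFrame:
        return self.model.predict(fm)

    def summary(self) -> str:
        lines = []
        lines.append("Acetylation-site RBF-SVM model")
        lines.append("=" * 46)
        lines.append(f"{'selected features':<28}{len(self.model.feature_names):>18}")
        lines.append(f"{'cost (C)':<28}{self.model.cost:>18.6g}")
        lines.append(f"{'gamma':<28}{self.model.gamma:>18.6g}")
        lines.append(f"{'seed':<28}{self.seed:>18}")
        lines.append("-" * 46)
        lines.append("accepted features per subtype")
        for st, n in self.selection.counts.items():
            lines.append(f"  {st:<26}{n:>18}")
        lines.append("-" * 46)
        lines.append("5-fold cross-validated performance")
        for k, v in self.cv_report.to_dict().items():
            lines.append(f"  {k:<26}{v:>18.3f}")
        lines.append("=" * 46)
        return "\n".join(lines)

    def save(self, path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path) -> "AcetylationFitResults":
        obj = joblib.load(path)
        if not isinstance(obj, cls):
            raise ContractError(f"{path}: not a saved AcetylationFitResults")
        return obj


class AcetylationSiteModel:
    """Species-specific lysine-acetylation site model.

    Parameters
    ----------
    features : FeatureMatrix
        Encoded training sites with 0/1 labels (1 = acetylated).
    cost_grid, gamma_grid : tuple of float
        The cost/gamma lattice searched at each tuning step. The default is
        a 3x3 coarsening of the published libsvm lattice; pass
        ``svm.DEFAULT_COST_GRID`` / ``svm.DEFAULT_GAMMA_GRID`` for the full
        11x10 search.
    max_evaluations : int, optional
        Cap on stepwise candidates per subtype (guards runtime on the
        largest subtypes); default none.
    n_splits : int
        Cross-validation folds (default 5).
    """

    def __init__(
        self,
        features: FeatureMatrix,
        cost_grid: tuple[float, ...] = COARSE_COST_GRID,
        gamma_grid: tuple[float, ...] = COARSE_GAMMA_GRID,
        max_evaluations: int | None = None,
        n_splits: int = 5,
    ):
        if features.labels is None:
            raise ContractError("training features must carry labels")
        self.features = features
        self.cost_grid = tuple(cost_grid)
        self.gamma_grid = tuple(gamma_grid)
        self.max_evaluations = max_evaluations
        self.n_splits = n_splits

    @classmethod
    def from_dataset(
        cls, proteins, sites, config=None, profiles=None, knn_reference=None, **kwargs
    ) -> "AcetylationSiteModel":
        """Encode (proteins, sites, profiles) and construct the model."""
        from .encode import encode_sites

        fm = encode_sites(
            proteins, sites, config=config, profiles=profiles, knn_reference=knn_reference
        )
        return cls(fm, **kwargs)

    def fit(self, seed: int = 0) -> AcetylationFitResults:
        """Select features, tune cost/gamma, train, and cross-validate.

        The stepwise pass shares one stratified fold plan derived from
        ``seed``; the final cross-validated report uses a fold plan with a
        different seed, so the reported performance is not inflated by the
        selection's own fold reuse.
        """
        selection = select_all_subtypes(
            self.features,
            seed=seed,
            cost_grid=self.cost_grid,
            gamma_grid=self.gamma_grid,
            max_evaluations=self.max_evaluations,
            n_splits=self.n_splits,
        )
        fm_sel = self.features.subset(selection.combined)
        y = fm_sel.labels.to_numpy()
        folds = make_fold_plan(y, n_splits=self.n_splits, seed=seed)
        cost, gamma, _ = grid_search(
            fm_sel.values.to_numpy(), y, folds,
            cost_grid=self.cost_grid, gamma_grid=self.gamma_grid,
        )
        model = SvmModel.fit(fm_sel, cost=cost, gamma=gamma, seed=seed)
        eval_folds = make_fold_plan(y, n_splits=self.n_splits, seed=seed + 10007)
        cv_report = cross_validated_report(fm_sel, cost, gamma, eval_folds)
        config = {
            "cost_grid": list(self.cost_grid),
            "gamma_grid": list(self.gamma_grid),
            "max_evaluations": self.max_evaluations,
            "n_splits": self.n_splits,
        }
        return AcetylationFitResults(
            selection=selection, model=model, cv_report=cv_report, seed=seed,
            config=config,
        )


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    canon = json.dumps(config, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
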