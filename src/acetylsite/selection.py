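"""Per-subtype feature selection: Pearson-correlation ranking followed by a
greedy stepwise pass under 5-fold cross-validated SVM accuracy.

Each of the 14 feature subtypes is ranked by |PCC| between the feature column
and the 0/1 class labels, then traversed once: a candidate is kept iff adding
it strictly increases the CV accuracy of the incumbent set (the first-ranked
feature is always kept — the empty set's baseline accuracy is defined as 0,
so the procedure is well-founded). The per-subtype accepted lists are finally
concatenated in the fixed subtype order to form the feature set the model is
trained on.

One fold plan, fixed before iteration, is shared by every candidate
evaluation in a run, so selection is deterministic given (matrix, seed,
SVM parameters).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from .encode import SUBTYPES
from .errors import ContractError
from .io import FeatureMatrix
from .svm import COARSE_COST_GRID, COARSE_GAMMA_GRID, cv_accuracy, grid_search, make_fold_plan


@dataclass
class RankedList:
    """One subtype's features ordered by descending |PCC| (ties by name,
    then original column order)."""

    subtype: str
    names: list[str]
    pcc: list[float]


@dataclass
class SubtypeSelection:
    subtype: str
    accepted: list[str]
    trajectory: list[float]  # CV accuracy after each accepted feature
    cost: float
    gamma: float


@dataclass
class SelectionResult:
    """The assembled outcome of per-subtype stepwise selection."""

    per_subtype: dict[str, SubtypeSelection]
    combined: list[str]
    seed: int

    @property
    def counts(self) -> dict[str, int]:
        """Accepted features per subtype (the feature-contribution table)."""
        return {st: len(sel.accepted) for st, sel in self.per_subtype.items()}

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "combined": self.combined,
            "per_subtype": {
                st: {
                    "accepted": sel.accepted,
                    "trajectory": sel.trajectory,
                    "cost": sel.cost,
                    "gamma": sel.gamma,
                }
                for st, sel in self.per_subtype.items()
            },
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "SelectionResult":
        with open(path) as fh:
            d = json.load(fh)
        per = {
            st: SubtypeSelection(
                subtype=st,
                accepted=list(v["accepted"]),
                trajectory=list(v["trajectory"]),
                cost=float(v["cost"]),
                gamma=float(v["gamma"]),
            )
            for st, v in d["per_subtype"].items()
        }
        return cls(per_subtype=per, combined=list(d["combined"]), seed=int(d["seed"]))


def pearson_with_labels(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """PCC of each feature column with the 0/1 label vector; constant
    columns (and a constant label vector) yield 0 rather than NaN."""
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=float)
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((xc ** 2).sum(axis=0))
    sy = np.sqrt((yc ** 2).sum())
    denom = sx * sy
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, (xc * yc[:, None]).sum(axis=0) / np.where(denom > 0, denom, 1.0), 0.0)
    return np.clip(r, -1.0, 1.0)


def rank_by_pcc(fm: FeatureMatrix) -> list[RankedList]:
    """One |PCC|-descending RankedList per subtype present in the matrix."""
    if fm.labels is None:
        raise ContractError("feature matrix has no labels")
    y = fm.labels.to_numpy()
    if len(np.unique(y)) < 2:
        raise ContractError("labels are single-class; ranking undefined")
    r = pearson_with_labels(fm.values.to_numpy(), y)
    by_name = dict(zip(fm.feature_names, r))
    ranked: list[RankedList] = []
    for st in fm.subtypes():
        cols = fm.columns_for(st)
        order = sorted(
            range(len(cols)), key=lambda i: (-abs(by_name[cols[i]]), cols[i], i)
        )
        ranked.append(
            RankedList(
                subtype=st,
                names=[cols[i] for i in order],
                pcc=[float(by_name[cols[i]]) for i in order],
            )
        )
    return ranked


def stepwise_select(
    fm: FeatureMatrix,
    ranked: RankedList,
    folds,
    cost: float,
    gamma: float,
    max_evaluations: int | None = None,
) -> SubtypeSelection:
    """Single greedy pass over a PCC-ranked list.

    The first feature is accepted unconditionally; each later candidate is
    accepted iff CV accuracy strictly increases over the incumbent set.
    ``max_evaluations`` optionally caps the number of candidates examined
    (guards runtime on the largest subtypes).
    """
    if not ranked.names:
        raise ContractError(f"subtype {ranked.subtype}: empty ranked list")
    if fm.labels is None:
        raise ContractError("feature matrix has no labels")
    y = fm.labels.to_numpy()
    candidates = ranked.names
    if max_evaluations is not None:
        candidates = candidates[:max_evaluations]
    accepted: list[str] = []
    trajectory: list[float] = []
    best = 0.0  # baseline accuracy of the empty set
    for name in candidates:
        trial = accepted + [name]
        acc = cv_accuracy(fm.values[trial].to_numpy(), y, folds, cost, gamma)
        if acc > best:
            accepted.append(name)
            trajectory.append(acc)
            best = acc
    return SubtypeSelection(
        subtype=ranked.subtype, accepted=accepted, trajectory=trajectory,
        cost=cost, gamma=gamma,
    )


def select_all_subtypes(
    fm: FeatureMatrix,
    seed: int = 0,
    cost_grid: tuple[float, ...] = COARSE_COST_GRID,
    gamma_grid: tuple[float, ...] = COARSE_GAMMA_GRID,
    max_evaluations: int | None = None,
    n_splits: int = 5,
) -> SelectionResult:
    """Run ranking + stepwise selection for every subtype in the matrix.

    SVM hyperparameters are tuned once per subtype by grid search on the full
    subtype matrix, then held fixed through that subtype's stepwise pass; the
    same fold plan is shared by all subtypes and all candidate evaluations.
    """
    if fm.labels is None:
        raise ContractError("feature matrix has no labels")
    folds = make_fold_plan(fm.labels.to_numpy(), n_splits=n_splits, seed=seed)
    per: dict[str, SubtypeSelection] = {}
    for ranked in rank_by_pcc(fm):
        X = fm.values[fm.columns_for(ranked.subtype)].to_numpy()
        cost, gamma, _ = grid_search(
            X, fm.labels.to_numpy(), folds, cost_grid=cost_grid, gamma_grid=gamma_grid
        )
        per[ranked.subtype] = stepwise_select(
            fm, ranked, folds, cost, gamma, max_evaluations=max_evaluations
        )
    return assemble_final_set(per, seed=seed)


def assemble_final_set(
    per_subtype: dict[str, SubtypeSelection], seed: int = 0
) -> SelectionResult:
    """Concatenate per-subtype accepted lists in the fixed subtype order."""
    if not per_subtype:
        raise ContractError("no subtype selections to assemble")
    combined: list[str] = []
    ordered: dict[str, SubtypeSelection] = {}
    for st in SUBTYPES:
        if st not in per_subtype:
            continue
        sel = per_subtype[st]
        if not sel.accepted:
            warnings.warn(f"subtype {st}: no accepted features; omitted", stacklevel=2)
            continue
        ordered[st] = sel
        combined.extend(sel.accepted)
    return SelectionResult(per_subtype=ordered, combined=combined, seed=seed)
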