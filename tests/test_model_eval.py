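"""Grid search, SVM fitting/prediction, and the evaluation metrics."""

import numpy as np
import pandas as pd
import pytest

from acetylsite.errors import ContractError
from acetylsite.io import FeatureMatrix
from acetylsite.metrics import (
    ConfusionCounts,
    compute_auc,
    compute_metrics,
    evaluate,
)
from acetylsite.model import SvmModel, cross_validated_report
from acetylsite.svm import (
    SymmetricMinMaxScaler,
    cv_accuracy,
    grid_search,
    make_fold_plan,
)


def fm_from(arrays, labels):
    n = len(labels)
    index = pd.MultiIndex.from_tuples(
        [(f"p{i}", 1) for i in range(n)], names=["protein_id", "position"]
    )
    return FeatureMatrix(pd.DataFrame(arrays, index=index), pd.Series(labels, index=index))


def separable_fm(n=40, seed=0):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    x1 = y * 4.0 + rng.normal(0, 0.2, n)
    x2 = rng.normal(0, 1, n)
    return fm_from({"LC.x1": x1, "LC.x2": x2}, y), y


class TestScaler:
    def test_maps_training_extremes_to_pm_one(self):
        X = np.array([[0.0, 10.0], [5.0, 20.0], [10.0, 30.0]])
        s = SymmetricMinMaxScaler().fit(X)
        out = s.transform(X)
        assert out.min(axis=0).tolist() == [-1.0, -1.0]
        assert out.max(axis=0).tolist() == [1.0, 1.0]

    def test_constant_training_feature_maps_to_zero_even_at_test(self):
        X = np.array([[1.0, 2.0], [1.0, 3.0]])
        s = SymmetricMinMaxScaler().fit(X)
        test = np.array([[99.0, 2.5]])
        out = s.transform(test)
        assert out[0, 0] == 0.0
        assert out[0, 1] == 0.0  # midpoint of [2,3]


class TestGridSearch:
    def test_separable_data_reaches_accuracy_one(self):
        fm, y = separable_fm()
        folds = make_fold_plan(y, seed=0)
        cost, gamma, acc = grid_search(
            fm.values.to_numpy(), y, folds, cost_grid=(1.0, 8.0), gamma_grid=(0.1, 1.0)
        )
        assert acc == pytest.approx(1.0)

    def test_tie_breaks_toward_smallest_cost_then_gamma(self):
        # symmetric random labels: every lattice point scores about the same;
        # strict-improvement scanning from the smallest point keeps it on ties
        rng = np.random.default_rng(1)
        y = np.repeat([0, 1], 15)
        X = rng.normal(size=(30, 2))
        folds = make_fold_plan(y, seed=0)
        accs = {}
        grid_c, grid_g = (0.5, 1.0, 2.0), (0.1, 0.2)
        for c in grid_c:
            for g in grid_g:
                accs[(c, g)] = cv_accuracy(X, y, folds, c, g)
        cost, gamma, best = grid_search(X, y, folds, cost_grid=grid_c, gamma_grid=grid_g)
        expected = min(
            [(c, g) for (c, g), a in accs.items() if a == max(accs.values())]
        )
        assert (cost, gamma) == expected

    def test_matches_exhaustive_brute_force_on_3x3_lattice(self):
        rng = np.random.default_rng(2)
        y = (rng.random(40) < 0.5).astype(int)
        X = np.column_stack([y + rng.normal(0, 1.2, 40), rng.normal(size=40)])
        folds = make_fold_plan(y, seed=1)
        grid_c = (0.25, 1.0, 4.0)
        grid_g = (0.05, 0.2, 0.8)
        best_acc = -1.0
        best_pt = None
        for c in sorted(grid_c):
            for g in sorted(grid_g):
                a = cv_accuracy(X, y, folds, c, g)
                if a > best_acc:
                    best_acc, best_pt = a, (c, g)
        cost, gamma, acc = grid_search(X, y, folds, cost_grid=grid_c, gamma_grid=grid_g)
        assert (cost, gamma) == best_pt and acc == pytest.approx(best_acc)


class TestSvmModel:
    def test_training_accuracy_one_on_separable_data(self):
        fm, y = separable_fm()
        model = SvmModel.fit(fm, cost=4.0, gamma=0.5)
        preds = model.predict(fm)
        assert (preds["label"].to_numpy() == y).all()

    def test_save_load_round_trip(self, tmp_path):
        fm, _ = separable_fm(seed=3)
        model = SvmModel.fit(fm, cost=2.0, gamma=0.2)
        path = tmp_path / "model.joblib"
        model.save(path)
        back = SvmModel.load(path)
        a = model.predict(fm)
        b = back.predict(fm)
        assert (a["decision"].to_numpy() == b["decision"].to_numpy()).all()

    def test_column_order_irrelevant_at_prediction(self):
        fm, _ = separable_fm(seed=4)
        model = SvmModel.fit(fm, cost=2.0, gamma=0.2)
        permuted = FeatureMatrix(fm.values[["LC.x2", "LC.x1"]].copy(), fm.labels)
        a = model.predict(fm)["decision"].to_numpy()
        b = model.predict(permuted)["decision"].to_numpy()
        assert (a == b).all()

    def test_missing_feature_column_named_in_error(self):
        fm, _ = separable_fm(seed=5)
        model = SvmModel.fit(fm, cost=2.0, gamma=0.2)
        dropped = FeatureMatrix(fm.values[["LC.x1"]].copy(), fm.labels)
        with pytest.raises(ContractError, match="LC.x2"):
            model.predict(dropped)

    def test_empty_site_list_gives_empty_output(self):
        fm, _ = separable_fm(seed=6)
        model = SvmModel.fit(fm, cost=2.0, gamma=0.2)
        empty = FeatureMatrix(fm.values.iloc[:0].copy())
        assert len(model.predict(empty)) == 0

    def test_single_class_fit_rejected(self):
        fm, _ = separable_fm(seed=7)
        bad = FeatureMatrix(fm.values, pd.Series(np.ones(len(fm.values), dtype=int),
                                                 index=fm.values.index))
        with pytest.raises(ContractError):
            SvmModel.fit(bad, cost=1.0, gamma=0.1)


class TestMetrics:
    def test_perfect_confusion(self):
        m = compute_metrics(ConfusionCounts(tp=5, tn=5, fp=0, fn=0))
        assert m == {"MCC": 1.0, "ACC": 1.0, "SEN": 1.0, "SPE": 1.0, "PRE": 1.0}

    def test_chance_confusion(self):
        m = compute_metrics(ConfusionCounts(tp=25, tn=25, fp=25, fn=25))
        assert m["MCC"] == 0.0 and m["ACC"] == 0.5

    def test_hand_evaluated_table(self):
        m = compute_metrics(ConfusionCounts(tp=40, fn=10, tn=30, fp=20))
        assert m["SEN"] == pytest.approx(0.8)
        assert m["SPE"] == pytest.approx(0.6)
        assert m["PRE"] == pytest.approx(2 / 3)
        assert m["ACC"] == pytest.approx(0.7)
        expected_mcc = (40 * 30 - 20 * 10) / np.sqrt((40 + 20) * (40 + 10) * (30 + 20) * (30 + 10))
        assert m["MCC"] == pytest.approx(expected_mcc)
        assert m["MCC"] == pytest.approx(0.408, abs=5e-4)

    def test_zero_denominator_mcc_is_zero(self):
        with pytest.warns(UserWarning):
            m = compute_metrics(ConfusionCounts(tp=0, tn=5, fp=0, fn=5))
        assert m["MCC"] == 0.0

    def test_undefined_precision_warns_and_reports_zero(self):
        with pytest.warns(UserWarning, match="precision"):
            m = compute_metrics(ConfusionCounts(tp=0, tn=5, fp=0, fn=5))
        assert m["PRE"] == 0.0


def mann_whitney_auc(y, s):
    """Brute-force pair counting: P(score_pos > score_neg) + half ties."""
    pos = [si for yi, si in zip(y, s) if yi == 1]
    neg = [si for yi, si in zip(y, s) if yi == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_separation(self):
        auc, roc = compute_auc([0, 0, 1, 1], [-2.0, -1.0, 1.0, 2.0])
        assert auc == pytest.approx(1.0)
        assert roc[0] == (0.0, 0.0) and roc[-1] == (1.0, 1.0)

    def test_constant_scores_give_half(self):
        auc, roc = compute_auc([0, 1, 0, 1], [0.3] * 4)
        assert auc == pytest.approx(0.5)

    def test_equals_mann_whitney_on_random_instances(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            n = int(rng.integers(10, 200))
            y = (rng.random(n) < 0.5).astype(int)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            s = np.round(rng.normal(size=n), 1)  # rounding forces ties
            auc, _ = compute_auc(y, s)
            assert auc == pytest.approx(mann_whitney_auc(y, s), abs=1e-12)

    def test_negation_and_monotone_invariance(self):
        rng = np.random.default_rng(11)
        y = (rng.random(50) < 0.4).astype(int)
        y[:2] = [0, 1]
        s = rng.normal(size=50)
        auc, _ = compute_auc(y, s)
        neg_auc, _ = compute_auc(y, -s)
        assert auc == pytest.approx(1.0 - neg_auc)
        warped, _ = compute_auc(y, np.exp(3 * s))
        assert warped == pytest.approx(auc)

    def test_roc_monotone(self):
        rng = np.random.default_rng(12)
        y = (rng.random(30) < 0.5).astype(int)
        y[:2] = [0, 1]
        s = np.round(rng.normal(size=30), 1)
        _, roc = compute_auc(y, s)
        fprs = [p[0] for p in roc]
        tprs = [p[1] for p in roc]
        assert fprs == sorted(fprs) and tprs == sorted(tprs)

    def test_single_class_rejected(self):
        with pytest.raises(ContractError):
            compute_auc([1, 1, 1], [0.1, 0.2, 0.3])


class TestCrossValidation:
    def test_fold_plan_reproducible(self):
        y = np.repeat([0, 1], 25)
        a = make_fold_plan(y, seed=3)
        b = make_fold_plan(y, seed=3)
        for (tr1, te1), (tr2, te2) in zip(a, b):
            assert (tr1 == tr2).all() and (te1 == te2).all()

    def test_report_fields_in_range(self):
        fm, y = separable_fm(n=60, seed=8)
        folds = make_fold_plan(y, seed=2)
        report = cross_validated_report(fm, cost=2.0, gamma=0.2, folds=folds)
        d = report.to_dict()
        for k in ("ACC", "SEN", "SPE", "PRE", "AUC"):
            assert 0.0 <= d[k] <= 1.0
        assert -1.0 <= d["MCC"] <= 1.0
        assert d["AUC"] > 0.9  # separable data
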