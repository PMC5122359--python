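import math

import numpy as np
import pandas as pd
import pytest

from ppdt import (
    auc,
    build_features,
    consistency_check,
    cv_classify,
    metrics,
    select_consistent_pairs,
)
from ppdt.efficiency_eval import FeatureMatrix, roc_points
from ppdt.network_io import ExpressionMatrix


def _expr(values, statuses, probe_to_gene=None, pair_id=None):
    samples = list(values.columns)
    return ExpressionMatrix(
        values=values,
        status=pd.Series(statuses, index=samples, name="status"),
        probe_to_gene=probe_to_gene,
        pair_id=None if pair_id is None else pd.Series(pair_id, index=samples, dtype=object),
    )


class TestBuildFeatures:
    def _simple_expr(self):
        values = pd.DataFrame(
            {
                "S1": [1.0, 3.0, 9.0],
                "S2": [2.0, 4.0, 8.0],
                "S3": [0.0, 2.0, 7.0],
                "S4": [1.0, 5.0, 6.0],
            },
            index=["p1", "p2", "p3"],
        )
        p2g = {"p1": "G1", "p2": "G1", "p3": "G2"}
        return _expr(values, ["normal", "normal", "disease", "disease"], p2g)

    def test_probe_averaging(self):
        fm = build_features(self._simple_expr(), {"G1", "G2"}, "normal_vs_disease")
        assert fm.X.loc["S1", "G1"] == pytest.approx(2.0)  # mean of 1 and 3
        assert fm.X.loc["S2", "G2"] == pytest.approx(8.0)  # single probe

    def test_unmapped_gene_dropped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            fm = build_features(self._simple_expr(), {"G1", "NOPE"}, "normal_vs_disease")
        assert list(fm.X.columns) == ["G1"]
        assert any("no expression rows" in r.message for r in caplog.records)

    def test_no_mappable_gene_is_error(self):
        with pytest.raises(ValueError, match="no gene"):
            build_features(self._simple_expr(), {"NOPE"}, "normal_vs_disease")

    def test_labels_follow_task_positive_status(self):
        fm = build_features(self._simple_expr(), {"G1"}, "normal_vs_disease")
        assert fm.y.tolist() == [0, 0, 1, 1]


class TestMetrics:
    def test_perfect(self):
        assert metrics(5, 5, 0, 0) == (1.0, 1.0, 1.0, 1.0)

    def test_hand_computed_mcc(self):
        sens, spec, acc, mcc = metrics(3, 2, 1, 2)
        assert mcc == pytest.approx(4 / math.sqrt(240))
        assert sens == pytest.approx(0.6)
        assert spec == pytest.approx(2 / 3)
        assert acc == pytest.approx(5 / 8)

    def test_all_predicted_positive_gives_zero_mcc(self):
        sens, spec, acc, mcc = metrics(4, 0, 4, 0)
        assert mcc == 0.0

    def test_requires_both_classes(self):
        with pytest.raises(ValueError):
            metrics(3, 0, 0, 0)

    def test_symmetric_under_class_flip(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            tp, tn, fp, fn = (int(x) for x in rng.integers(1, 20, size=4))
            _, _, _, mcc = metrics(tp, tn, fp, fn)
            _, _, _, flipped = metrics(tn, tp, fn, fp)
            assert mcc == pytest.approx(flipped)


class TestAUC:
    def test_pair_counting_example(self):
        assert auc([0.9, 0.8, 0.4, 0.3], [1, 0, 1, 0]) == pytest.approx(0.75)

    def test_separable(self):
        assert auc([5, 6, 1, 2], [1, 1, 0, 0]) == 1.0

    def test_all_ties(self):
        assert auc([3, 3, 3, 3], [1, 1, 0, 0]) == 0.5

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            auc([1, 2], [1, 1])

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_trapezoidal_area_under_empirical_roc(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        if labels.sum() in (0, 40):
            labels[0] = 1 - labels[0]
        pts = roc_points(scores, labels)
        trapezoid = float(np.trapezoid(pts["tpr"], pts["fpr"]))
        assert auc(scores, labels) == pytest.approx(trapezoid)


class TestCVClassify:
    def _gaussian_fm(self, effect, n=20, d=5, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, d))
        y = np.array([0] * (n // 2) + [1] * (n // 2))
        X[y == 1] += effect
        return FeatureMatrix(
            X=pd.DataFrame(X, index=[f"S{i}" for i in range(n)]),
            y=y,
            task="normal_vs_disease",
        )

    def test_separable_classes_near_perfect(self):
        fm = self._gaussian_fm(effect=5.0)
        report = cv_classify(fm, repeats=10, seed=3)
        assert report.means["auc"] == pytest.approx(1.0, abs=0.01)
        assert report.means["accuracy"] == pytest.approx(1.0, abs=0.02)

    def test_deterministic(self):
        fm = self._gaussian_fm(effect=1.0)
        a = cv_classify(fm, repeats=5, seed=7)
        b = cv_classify(fm, repeats=5, seed=7)
        assert a.per_repeat.equals(b.per_repeat)
        assert a.roc_points.equals(b.roc_points)

    def test_fold_reduction_warns_on_tiny_class(self, caplog):
        fm = self._gaussian_fm(effect=2.0, n=8)  # 4 per class < 5 folds
        with caplog.at_level("WARNING"):
            report = cv_classify(fm, folds=5, repeats=3, seed=1)
        assert report.folds == 4
        assert any("reducing folds" in r.message for r in caplog.records)

    def test_metrics_in_range(self):
        fm = self._gaussian_fm(effect=0.5, seed=4)
        report = cv_classify(fm, repeats=8, seed=2)
        pr = report.per_repeat
        for m in ("sensitivity", "specificity", "auc", "accuracy"):
            assert ((pr[m] >= 0) & (pr[m] <= 1)).all()
        assert ((pr["mcc"] >= -1) & (pr["mcc"] <= 1)).all()


class TestConsistency:
    def _group_expr(self, n_samples=10, n_genes=200, seed=0, shifted=None, shift=3.0):
        rng = np.random.default_rng(seed)
        vals = rng.normal(0, 1, size=(n_genes, n_samples))
        samples = [f"S{i:02d}" for i in range(n_samples)]
        if shifted is not None:
            vals[:, shifted] += shift
        values = pd.DataFrame(vals, index=[f"g{i}" for i in range(n_genes)], columns=samples)
        return _expr(values, ["normal"] * n_samples)

    def test_sample_equal_to_group_median_is_consistent(self):
        values = pd.DataFrame(
            np.zeros((50, 5)), index=[f"g{i}" for i in range(50)],
            columns=[f"S{i}" for i in range(5)],
        )
        expr = _expr(values, ["normal"] * 5)
        cr = consistency_check(expr)
        assert cr.table["consistent"].all()
        assert (cr.table["p_value"] == 1.0).all()

    def test_globally_shifted_sample_flagged(self):
        expr = self._group_expr(n_genes=500, shifted=3)
        cr = consistency_check(expr)
        assert not cr.table.loc["S03", "consistent"]
        assert cr.table.drop("S03")["consistent"].all()

    def test_fdr_never_flags_more_than_raw(self):
        expr = self._group_expr(seed=5)
        cr = consistency_check(expr)
        raw = (cr.table["p_value"] < cr.alpha).sum()
        adjusted = (~cr.table["consistent"]).sum()
        assert adjusted <= raw

    def test_small_group_is_error(self):
        expr = self._group_expr(n_samples=2)
        with pytest.raises(ValueError, match="< 3"):
            consistency_check(expr)


class TestSelectConsistentPairs:
    def _paired_expr(self, inconsistent_treated):
        rng = np.random.default_rng(1)
        samples = (
            [f"N{i}" for i in range(4)]
            + [f"D{i}" for i in range(4)]
            + [f"T{i}" for i in range(4)]
        )
        vals = rng.normal(0, 1, size=(300, 12))
        for i in inconsistent_treated:
            vals[:, 8 + i] += 4.0
        values = pd.DataFrame(vals, index=[f"g{i}" for i in range(300)], columns=samples)
        pair_id = [None] * 4 + [f"P{i}" for i in range(4)] * 2
        return _expr(values, ["normal"] * 4 + ["disease"] * 4 + ["treated"] * 4,
                     pair_id=pair_id)

    def test_inconsistent_treated_drops_its_pair(self):
        expr = self._paired_expr(inconsistent_treated=[1])
        cr = consistency_check(expr)
        sub = select_consistent_pairs(cr, expr)
        assert "T1" not in sub.samples and "D1" not in sub.samples
        assert {"T0", "D0", "T2", "D2", "T3", "D3"} <= set(sub.samples)

    def test_missing_pair_ids_rejected(self):
        expr = self._paired_expr(inconsistent_treated=[])
        expr = ExpressionMatrix(
            values=expr.values, status=expr.status, probe_to_gene=None, pair_id=None
        )
        cr = consistency_check(expr)
        with pytest.raises(ValueError, match="pair ids"):
            select_consistent_pairs(cr, expr)
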