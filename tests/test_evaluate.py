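"""Metrics, metric composition, paired comparison, chance levels, sweeps."""

import numpy as np
import pandas as pd
import pytest

import hievox as hv
from hievox.balance import BalanceRecipe

from _oracles import auc_all_pairs, make_gaussian_features, wilcoxon_exact_p


class TestPerClassMetrics:
    def test_hand_counted_confusion(self):
        """Confusion [[8,2],[1,9]]: precision(A) = 8/9, recall(A) = 0.8,
        accuracy = 0.85."""
        y_true = ["A"] * 10 + ["B"] * 10
        y_pred = ["A"] * 8 + ["B"] * 2 + ["A"] * 1 + ["B"] * 9
        rep = hv.per_class_metrics(y_true, y_pred)
        np.testing.assert_array_equal(rep.confusion, [[8, 2], [1, 9]])
        assert rep.per_class.loc["A", "precision"] == pytest.approx(8 / 9)
        assert rep.per_class.loc["A", "recall"] == pytest.approx(0.8)
        assert rep.accuracy == pytest.approx(0.85)

    def test_perfect_predictions(self):
        y = ["a", "b", "c"] * 5
        rep = hv.per_class_metrics(y, y)
        assert rep.accuracy == 1.0
        assert (rep.per_class[["precision", "recall"]] == 1.0).all().all()

    def test_balanced_mean_recall_equals_accuracy(self, rng):
        y_true = np.repeat(["a", "b", "c", "d"], 25)
        y_pred = rng.choice(["a", "b", "c", "d"], size=100)
        rep = hv.per_class_metrics(y_true, y_pred)
        assert rep.per_class["recall"].mean() == pytest.approx(rep.accuracy)

    def test_never_predicted_class_flagged_zero_precision(self):
        rep = hv.per_class_metrics(["a", "a", "b", "b", "b"],
                                   ["b", "b", "b", "b", "b"])
        assert rep.per_class.loc["a", "precision"] == 0.0
        assert any("never predicted" in f for f in rep.flags)

    def test_disjoint_label_sets_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            hv.per_class_metrics(["a", "a", "b"], ["x", "y", "x"])


class TestRocAuc:
    def test_one_hot_scores_give_auc_one(self):
        y = np.array(["a", "b", "a", "b"])
        scores = np.array([[1, 0], [0, 1], [1, 0], [0, 1]], dtype=float)
        auc = hv.roc_auc_ovr(scores, y)
        assert auc["a"] == 1.0 and auc["b"] == 1.0

    def test_four_call_concordance_example(self):
        """Scores 0.9, 0.8, 0.4, 0.2 with positives in 1st and 3rd place:
        3 of 4 pos/neg pairs concordant, AUC = 0.75."""
        y = np.array(["p", "n", "p", "n"])
        s_pos = np.array([0.9, 0.8, 0.4, 0.2])
        scores = np.column_stack([1 - s_pos, s_pos])  # classes sorted: n, p
        auc = hv.roc_auc_ovr(scores, y)
        assert auc["p"] == pytest.approx(0.75)

    def test_random_scores_near_half(self, rng):
        n = 2000
        y = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
        scores = rng.random((n, 2))
        auc = hv.roc_auc_ovr(scores, y)
        sd = np.sqrt((n + 1) / (12 * (n / 2) ** 2))
        assert abs(auc["a"] - 0.5) < 3 * sd

    def test_matches_all_pairs_oracle_with_ties(self, rng):
        y = rng.choice(["a", "b", "c"], size=40)
        scores = np.round(rng.random((40, 3)), 1)  # coarse -> ties
        auc = hv.roc_auc_ovr(scores, y)
        for j, cls in enumerate(["a", "b", "c"]):
            expected = auc_all_pairs(scores[:, j], y == cls)
            assert auc[cls] == pytest.approx(expected)

    def test_class_without_positives_flagged(self, rng):
        y = np.array(["a"] * 10)
        scores = rng.random((10, 2))
        with pytest.warns(UserWarning, match="no positives"):
            auc = hv.roc_auc_ovr(scores, y, classes=["a", "b"])
        assert auc["b"] is None


class TestCombineHierarchical:
    def _report(self, y_true, y_pred):
        return hv.per_class_metrics(y_true, y_pred)

    def test_product_composition(self):
        """Sex precision 1.0 with id precision 0.9 composes to 0.9; sex
        recall 0.8 with id recall 0.5 composes to 0.4."""
        sex = self._report(["F"] * 5 + ["M"] * 5,
                           ["F"] * 4 + ["M"] * 6)  # F: prec 1.0, recall 0.8
        idF = self._report(["f1"] * 10 + ["f2"] * 10,
                           ["f1"] * 9 + ["f2"] * 1 + ["f1"] * 1 + ["f2"] * 9)
        idM = self._report(["m1"] * 2 + ["m2"] * 2, ["m1", "m1", "m1", "m2"])
        combined = hv.combine_hierarchical_metrics(sex, {"F": idF, "M": idM})
        assert combined.loc["f1", "precision"] == pytest.approx(
            1.0 * sexp(idF, "f1"))
        assert combined.loc["f1", "recall"] == pytest.approx(0.8 * 0.9)

    def test_bounded_by_both_layers(self, rng):
        """Y_final <= min(Y_sex, Y_id) over 1000 random value pairs."""
        for _ in range(1000):
            a, b = rng.random(2)
            assert a * b <= min(a, b) + 1e-12
        # and on actual reports
        sex = self._report(rng.choice(["F", "M"], 60).tolist(),
                           rng.choice(["F", "M"], 60).tolist())
        idF = self._report(rng.choice(["f1", "f2"], 40).tolist(),
                           rng.choice(["f1", "f2"], 40).tolist())
        idM = self._report(rng.choice(["m1", "m2"], 40).tolist(),
                           rng.choice(["m1", "m2"], 40).tolist())
        combined = hv.combine_hierarchical_metrics(sex, {"F": idF, "M": idM})
        for ind, row in combined.iterrows():
            id_rep = idF if row["sex"] == "F" else idM
            assert row["precision"] <= min(
                sex.per_class.loc[row["sex"], "precision"],
                id_rep.per_class.loc[ind, "precision"]) + 1e-12

    def test_missing_sex_class_rejected(self):
        sex = self._report(["F"] * 5 + ["M"] * 5, ["F"] * 5 + ["M"] * 5)
        idX = self._report(["x1", "x2"] * 3, ["x1", "x2"] * 3)
        with pytest.raises(ValueError, match="missing"):
            hv.combine_hierarchical_metrics(sex, {"X": idX})


def sexp(report, cls):
    return report.per_class.loc[cls, "precision"]


class TestPairedCompare:
    def test_systematic_shift_detected(self, rng):
        a = rng.random(16)
        res = hv.paired_compare(a, a + 0.05)
        assert res["p_value"] < 0.01
        assert res["median_difference"] > 0

    def test_equal_vectors_flagged_p_one(self):
        a = np.linspace(0, 1, 10)
        res = hv.paired_compare(a, a)
        assert res["p_value"] == 1.0
        assert res["flag"] is not None

    @pytest.mark.parametrize("n", [6, 7, 8])
    def test_matches_exact_enumeration(self, n, rng):
        """For n <= 8 distinct pairs the p-value equals a brute-force
        enumeration over all 2^n sign assignments."""
        for trial in range(5):
            a = rng.random(n)
            d = rng.normal(0, 1, n)
            d = np.where(np.abs(d) < 1e-3, 0.1, d)  # no zeros
            b = a + d
            res = hv.paired_compare(a, b)
            w, p = wilcoxon_exact_p(b - a)
            assert res["p_value"] == pytest.approx(p)
            assert res["statistic"] == pytest.approx(w)

    def test_null_rejection_rate_calibrated(self, rng):
        """Under the symmetric null, rejections at alpha = 0.05 stay within
        3 binomial sd over 200 simulations."""
        rejections = 0
        n_sim = 200
        for _ in range(n_sim):
            a = rng.random(12)
            b = a + rng.normal(0, 0.1, 12)
            if hv.paired_compare(a, b)["p_value"] < 0.05:
                rejections += 1
        rate = rejections / n_sim
        assert rate < 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_sim)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            hv.paired_compare([1, 2], [2, 3])


class TestChanceLevel:
    def test_printed_chance_probabilities(self):
        assert hv.chance_level_pct(16) == pytest.approx(6.25)
        assert hv.chance_level_pct(10) == pytest.approx(10.0)
        assert round(hv.chance_level_pct(18), 2) == pytest.approx(5.56)


class TestSweep:
    def test_sweep_bookkeeping(self):
        fm = make_gaussian_features({c: 30 for c in
                                     ("F1", "F2", "M1", "M2")}, seed=0)
        df = hv.sample_size_sweep(
            {"trill": fm}, caps=(15, None),
            config={"n_trees_sex": 10, "n_trees_id": 10, "max_depth": 1,
                    "n_folds": 4},
            recipe=BalanceRecipe(min_calls=10),
            random_state=0)
        assert len(df) == 4  # 2 caps x 2 approaches
        assert set(df["approach"]) == {"flat", "hierarchical"}
        assert set(df["sample_size_per_class"]) == {15, 30}
        assert (df["chance_pct"] == 25.0).all()
        assert df["precision_mean"].between(0, 1).all()
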