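"""Boosted CV ensembles and the sex-then-identity hierarchy."""

import numpy as np
import pandas as pd
import pytest

import hievox as hv
from hievox.balance import BalanceRecipe

from _oracles import make_gaussian_features

FAST = dict(n_trees=15, max_depth=1, n_folds=5)


def _blobs(n_per_class=30, sep=16.0, n_classes=2, n_features=4, seed=0):
    rng = np.random.default_rng(seed)
    X, y = [], []
    for k in range(n_classes):
        mu = np.zeros(n_features)
        mu[0] = k * sep
        X.append(rng.normal(mu, 1.0, size=(n_per_class, n_features)))
        y += [f"c{k}"] * n_per_class
    return pd.DataFrame(np.vstack(X), columns=[f"f{j}" for j in range(n_features)]), \
        np.array(y)


class TestBoostedTreesCV:
    def test_separable_classes_near_perfect(self):
        """Two classes 16 sd apart on one feature: a single threshold
        suffices, so CV accuracy must exceed 0.99."""
        X, y = _blobs(sep=16.0)
        m = hv.BoostedTreesCV(random_state=0, **FAST).fit(X, y)
        assert m.mean_cv_accuracy_ > 0.99

    def test_shuffled_labels_at_chance(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(400, 5)))
        y = rng.permutation(np.repeat([f"c{k}" for k in range(4)], 100))
        m = hv.BoostedTreesCV(random_state=0, **FAST).fit(X, y)
        sd = np.sqrt(0.25 * 0.75 / 400)
        assert abs(m.oof_accuracy_ - 0.25) < 3 * sd

    def test_staged_loss_shape_and_improvement(self):
        X, y = _blobs(sep=16.0)
        m = hv.BoostedTreesCV(random_state=0, **FAST).fit(X, y)
        assert m.staged_loss_.shape == (5, 15)
        run_min = np.minimum.accumulate(m.staged_loss_, axis=1)
        assert np.all(np.diff(run_min, axis=1) <= 1e-12)
        assert np.all(m.staged_loss_[:, -1] <= m.staged_loss_[:, 0] + 1e-12)

    def test_fold_missing_class_is_error(self):
        X, y = _blobs(n_per_class=30)
        y = y.copy()
        y[:3] = "rare"
        y[3:30] = "c1"
        with pytest.raises(ValueError, match="n_folds"):
            hv.BoostedTreesCV(random_state=0, **FAST).fit(X, y)

    def test_best_fold_is_accuracy_argmax(self):
        X, y = _blobs(sep=2.0, seed=5)
        m = hv.BoostedTreesCV(random_state=1, **FAST).fit(X, y)
        assert m.best_fold_ == int(np.argmax(m.fold_accuracies_))

    def test_oof_predictions_come_from_out_of_fold_models(self):
        X, y = _blobs(sep=3.0, seed=6)
        m = hv.BoostedTreesCV(random_state=2, **FAST).fit(X, y)
        for fold, model in enumerate(m.fold_models_):
            rows = np.flatnonzero(m.fold_assignments_ == fold)
            np.testing.assert_array_equal(
                m.oof_pred_[rows], model.predict(X.to_numpy()[rows]))

    def test_constant_test_matrix_predicts_single_class(self):
        X, y = _blobs(sep=16.0)
        m = hv.BoostedTreesCV(random_state=0, **FAST).fit(X, y)
        pred = m.predict(pd.DataFrame(np.zeros((7, 4)), columns=X.columns))
        assert len(set(pred.tolist())) == 1

    def test_feature_mismatch_lists_missing_names(self):
        X, y = _blobs()
        m = hv.BoostedTreesCV(random_state=0, **FAST).fit(X, y)
        bad = X.rename(columns={"f2": "other"})
        with pytest.raises(ValueError, match="f2"):
            m.predict(bad)

    def test_determinism_under_fixed_seed(self):
        X, y = _blobs(sep=2.0, seed=8)
        m1 = hv.BoostedTreesCV(random_state=9, **FAST).fit(X, y)
        m2 = hv.BoostedTreesCV(random_state=9, **FAST).fit(X, y)
        np.testing.assert_array_equal(m1.fold_accuracies_, m2.fold_accuracies_)
        np.testing.assert_array_equal(m1.importances_, m2.importances_)


class TestRankFeatures:
    def test_planted_informative_feature_ranks_first(self):
        rng = np.random.default_rng(10)
        X = pd.DataFrame(rng.normal(size=(120, 10)),
                         columns=[f"f{j}" for j in range(10)])
        y = np.where(X["f7"] > 0, "a", "b")
        m = hv.BoostedTreesCV(random_state=0, **FAST).fit(X, y)
        assert m.rank_features(top_k=3).index[0] == "f7"

    def test_top_k_all_is_permutation(self):
        X, y = _blobs(sep=2.0, seed=11)
        m = hv.BoostedTreesCV(random_state=0, **FAST).fit(X, y)
        ranked = m.rank_features(top_k=4)
        assert sorted(ranked.index) == sorted(X.columns)
        assert (np.diff(ranked.to_numpy()) <= 1e-15).all()

    def test_top_k_overflow_truncates_with_warning(self):
        X, y = _blobs(sep=2.0, seed=12)
        m = hv.BoostedTreesCV(random_state=0, **FAST).fit(X, y)
        with pytest.warns(UserWarning, match="exceeds"):
            ranked = m.rank_features(top_k=99)
        assert len(ranked) == 4


def _hier_dataset(sex_sep=8.0, ind_sep=4.0, n_per=20, seed=0,
                  n_f=3, n_m=3):
    """Gaussian features where one axis encodes sex and others identity."""
    rng = np.random.default_rng(seed)
    rows, inds, sexes = [], [], []
    ids = [f"F{i}" for i in range(n_f)] + [f"M{i}" for i in range(n_m)]
    for ind in ids:
        sex = ind[0]
        mu = rng.normal(0, ind_sep, size=6)
        mu[0] = (sex_sep / 2) * (1 if sex == "F" else -1)
        rows.append(rng.normal(mu, 1.0, size=(n_per, 6)))
        inds += [ind] * n_per
        sexes += [sex] * n_per
    X = pd.DataFrame(np.vstack(rows), columns=[f"f{j}" for j in range(6)])
    return X, np.array(inds), np.array(sexes)


class TestHierarchical:
    def test_class_lists_partition_individuals(self):
        X, y, sex = _hier_dataset()
        clf = hv.HierarchicalBoostedClassifier(
            n_trees_sex=10, n_trees_id=10, max_depth=1, n_folds=4,
            random_state=0).fit(X, y, sex=sex)
        all_ids = sorted(clf.class_lists_["F"] + clf.class_lists_["M"])
        assert all_ids == sorted(set(y.tolist()))
        assert not set(clf.class_lists_["F"]) & set(clf.class_lists_["M"])

    def test_constant_sex_labels_rejected(self):
        X, y, sex = _hier_dataset()
        with pytest.raises(ValueError, match="both sexes"):
            hv.HierarchicalBoostedClassifier(random_state=0).fit(
                X, y, sex=np.full_like(sex, "F"))

    def test_sex_with_one_individual_rejected(self):
        X, y, sex = _hier_dataset(n_f=1, n_m=3)
        with pytest.raises(ValueError, match="at least 2"):
            hv.HierarchicalBoostedClassifier(
                n_trees_sex=5, n_trees_id=5, n_folds=4,
                random_state=0).fit(X, y, sex=sex)

    def test_misrouted_call_cannot_be_correct(self):
        """Routing a call to the wrong sex guarantees a wrong individual:
        the per-sex class lists are disjoint."""
        X, y, sex = _hier_dataset()
        clf = hv.HierarchicalBoostedClassifier(
            n_trees_sex=10, n_trees_id=10, max_depth=1, n_folds=4,
            random_state=0).fit(X, y, sex=sex)
        wrong = np.where(sex == "F", "M", "F")
        _, ids = clf.predict(X, routing="true_sex", true_sex=wrong)
        assert np.all(ids != y)

    def test_perfect_sex_layer_matches_true_sex_routing(self):
        X, y, sex = _hier_dataset(sex_sep=20.0)
        clf = hv.HierarchicalBoostedClassifier(
            n_trees_sex=10, n_trees_id=10, max_depth=1, n_folds=4,
            random_state=0).fit(X, y, sex=sex)
        assert np.all(clf.sex_model_.predict(X) == sex)
        _, ids_pred = clf.predict(X, routing="predicted_sex")
        _, ids_true = clf.predict(X, routing="true_sex", true_sex=sex)
        np.testing.assert_array_equal(ids_pred, ids_true)

    def test_routing_fractions_track_sex_base_rates(self):
        X, y, sex = _hier_dataset(sex_sep=20.0, n_per=30)
        clf = hv.HierarchicalBoostedClassifier(
            n_trees_sex=10, n_trees_id=10, max_depth=1, n_folds=4,
            random_state=0).fit(X, y, sex=sex)
        routed, _ = clf.predict(X, routing="predicted_sex")
        frac_f = np.mean(routed == "F")
        assert abs(frac_f - 0.5) < 0.05

    def test_true_sex_routing_requires_labels(self):
        X, y, sex = _hier_dataset()
        clf = hv.HierarchicalBoostedClassifier(
            n_trees_sex=5, n_trees_id=5, max_depth=1, n_folds=4,
            random_state=0).fit(X, y, sex=sex)
        with pytest.raises(ValueError, match="true_sex"):
            clf.predict(X, routing="true_sex")

    @staticmethod
    def _hier_gain(seed: int, sex_cue: bool) -> float:
        """Composed-hierarchical minus flat mean precision on Gaussian
        features; ``sex_cue`` controls whether one axis separates the
        sexes."""
        from hievox.core import FeatureMatrix

        rng = np.random.default_rng(seed)
        ids = [f"F{i}" for i in range(3)] + [f"M{i}" for i in range(3)]
        rows, inds = [], []
        for ind in ids:
            mu = rng.normal(0, 2.0, size=6)
            mu[0] = 2.0 * (1 if ind[0] == "F" else -1) if sex_cue else 0.0
            rows.append(rng.normal(mu, 1.0, size=(20, 6)))
            inds += [ind] * 20
        values = pd.DataFrame(
            np.vstack(rows), columns=[f"f{j}" for j in range(6)],
            index=pd.Index([f"c{k}" for k in range(120)], name="call_id"))
        labels = pd.DataFrame(
            {"individual_id": inds, "sex": [i[0] for i in inds],
             "call_type": ["trill"] * 120}, index=values.index)
        ds = hv.build_balanced_dataset(
            FeatureMatrix(values=values, labels=labels), "individual",
            BalanceRecipe(min_calls=5, seed=seed))
        cfg = dict(n_trees=40, max_depth=2, n_folds=4)
        flat, _ = hv.evaluate_flat(ds, config=cfg, random_state=seed)
        hier = hv.evaluate_hierarchical(ds, config_sex=cfg, config_id=cfg,
                                        random_state=seed)
        return float(hier["composed"]["precision"].mean()
                     - flat.per_class["precision"].mean())

    def test_hierarchy_gain_requires_a_sex_cue(self):
        """Ablation: the hierarchical advantage over the flat classifier is
        larger when the sexes are acoustically separable than when the sex
        label carries no signal of its own (majority over seeds)."""
        wins = sum(self._hier_gain(seed, True) > self._hier_gain(seed, False)
                   for seed in range(5))
        assert wins >= 3
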