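"""Cross-validated boosted decision trees and the sex-then-identity hierarchy.

:class:`BoostedTreesCV` wraps sequential adaptive boosting of depth-limited
decision trees (SAMME reweighting, binary or multi-class) in stratified
k-fold cross-validation: it trains one boosted ensemble per fold and records
each fold's held-out accuracy, staged held-out loss versus number of trees,
and impurity-gain feature importances. Prediction uses the designated fold
model (the most accurate fold, lowest index on ties) by default, or a vote
of all fold models.

:class:`HierarchicalBoostedClassifier` stacks two such layers: a binary sex
classifier trained on all calls, and one identity classifier per sex trained
on the calls of that sex only. Because the per-sex class lists are disjoint,
a call routed to the wrong sex can never receive a correct identity. Both
estimators follow sklearn conventions (``get_params``/``set_params``,
fitted attributes with a trailing underscore).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import AdaBoostClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

from .balance import BalancedDataset


def _as_frame(X) -> pd.DataFrame:
    return X if isinstance(X, pd.DataFrame) else pd.DataFrame(X)


class BoostedTreesCV(BaseEstimator, ClassifierMixin):
    """Boosted decision trees under stratified k-fold cross-validation.

    Parameters
    ----------
    n_trees:
        Number of boosting rounds per fold. Defaults to 500, the point where
        the staged loss plateaus for the binary sex task; identity tasks use
        larger ensembles (see :class:`HierarchicalBoostedClassifier`).
    learning_rate:
        Shrinkage applied to each weak learner's contribution.
    max_depth:
        Depth of the decision-tree weak learners.
    n_folds:
        Cross-validation folds (stratified so every class appears in every
        fold).
    prediction:
        ``"best_fold"`` predicts with the most accurate fold's ensemble
        (ties broken toward the lowest fold index); ``"vote"`` majority-votes
        all fold ensembles.
    """

    def __init__(self, n_trees: int = 500, learning_rate: float = 0.1,
                 max_depth: int = 3, n_folds: int = 10,
                 prediction: str = "best_fold",
                 random_state: int | None = None):
        self.n_trees = n_trees
        self.learning_rate = learning_rate
        self.max_depth = max_depth
        self.n_folds = n_folds
        self.prediction = prediction
        self.random_state = random_state

    def fit(self, X, y):
        X = _as_frame(X)
        y = np.asarray(y)
        if len(X) != y.size:
            raise ValueError("X and y length mismatch")
        classes, counts = np.unique(y, return_counts=True)
        if classes.size < 2:
            raise ValueError("need at least 2 classes")
        if counts.min() < self.n_folds:
            raise ValueError(
                f"class {classes[np.argmin(counts)]!r} has {counts.min()} rows, "
                f"fewer than n_folds={self.n_folds}: every fold would miss it; "
                "collect more calls or reduce n_folds")
        self.classes_ = classes
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]

        rng = np.random.default_rng(self.random_state)
        cv_seed = int(rng.integers(2**31))
        skf = StratifiedKFold(n_splits=self.n_folds, shuffle=True,
                              random_state=cv_seed)
        Xv = X.to_numpy(dtype=np.float64)
        n = len(X)
        self.fold_models_ = []
        self.fold_assignments_ = np.empty(n, dtype=int)
        self.fold_accuracies_ = np.empty(self.n_folds)
        self.staged_loss_ = np.empty((self.n_folds, self.n_trees))
        self.importances_ = np.empty((self.n_folds, X.shape[1]))
        self.oof_pred_ = np.empty(n, dtype=object)
        self.oof_proba_ = np.empty((n, classes.size))
        for fold, (tr, te) in enumerate(skf.split(Xv, y)):
            model = AdaBoostClassifier(
                estimator=DecisionTreeClassifier(
                    max_depth=self.max_depth,
                    random_state=int(rng.integers(2**31))),
                n_estimators=self.n_trees,
                learning_rate=self.learning_rate,
                random_state=int(rng.integers(2**31)))
            model.fit(Xv[tr], y[tr])
            self.fold_models_.append(model)
            self.fold_assignments_[te] = fold
            pred = model.predict(Xv[te])
            self.oof_pred_[te] = pred
            self.oof_proba_[te] = model.predict_proba(Xv[te])
            self.fold_accuracies_[fold] = np.mean(pred == y[te])
            # held-out misclassification after each boosting round; boosting
            # may stop early, in which case the loss curve is held flat
            stage_loss = [np.mean(p != y[te]) for p in model.staged_predict(Xv[te])]
            if len(stage_loss) < self.n_trees:
                stage_loss += [stage_loss[-1]] * (self.n_trees - len(stage_loss))
            self.staged_loss_[fold] = stage_loss
            self.importances_[fold] = model.feature_importances_
        self.best_fold_ = int(np.argmax(self.fold_accuracies_))  # ties -> lowest
        self.mean_cv_accuracy_ = float(self.fold_accuracies_.mean())
        self.oof_accuracy_ = float(np.mean(self.oof_pred_ == y))
        return self

    def _check_X(self, X) -> np.ndarray:
        check_is_fitted(self, "fold_models_")
        X = _as_frame(X)
        if isinstance(X.columns, pd.RangeIndex) or not len(X.columns):
            return X.to_numpy(dtype=np.float64)
        missing = [c for c in self.feature_names_in_ if c not in X.columns]
        if missing:
            raise ValueError(f"X is missing model feature(s): {missing[:10]}")
        return X[list(self.feature_names_in_)].to_numpy(dtype=np.float64)

    def predict(self, X) -> np.ndarray:
        Xv = self._check_X(X)
        if self.prediction == "vote":
            votes = np.stack([m.predict(Xv) for m in self.fold_models_])
            out = []
            for col in votes.T:
                vals, cnts = np.unique(col, return_counts=True)
                out.append(vals[np.argmax(cnts)])
            return np.asarray(out)
        return self.fold_models_[self.best_fold_].predict(Xv)

    def predict_proba(self, X) -> np.ndarray:
        Xv = self._check_X(X)
        if self.prediction == "vote":
            return np.mean([m.predict_proba(Xv) for m in self.fold_models_], axis=0)
        return self.fold_models_[self.best_fold_].predict_proba(Xv)

    def rank_features(self, top_k: int = 20) -> pd.Series:
        """Features ranked by the most accurate fold's importances.

        Descending by importance, ties stable by feature name; returns the
        top ``top_k`` as a name-indexed series of scores.
        """
        check_is_fitted(self, "importances_")
        imp = self.importances_[self.best_fold_]
        names = list(self.feature_names_in_)
        if top_k > len(names):
            import warnings

            warnings.warn(
                f"top_k={top_k} exceeds the {len(names)} available features; "
                "returning all", stacklevel=2)
            top_k = len(names)
        order = sorted(range(len(names)), key=lambda i: (-imp[i], names[i]))
        top = order[:top_k]
        return pd.Series(imp[top], index=[names[i] for i in top])


def train_boosted_cv(ds: BalancedDataset | tuple, target_labels=None,
                     **config) -> BoostedTreesCV:
    """Train a :class:`BoostedTreesCV` on a balanced dataset (or X, y)."""
    if isinstance(ds, BalancedDataset):
        X, y = ds.X, ds.y if target_labels is None else np.asarray(target_labels)
    else:
        X, y = ds
        y = np.asarray(y if target_labels is None else target_labels)
    return BoostedTreesCV(**config).fit(X, y)


def predict_boosted(cvm: BoostedTreesCV, X) -> tuple[np.ndarray, int]:
    """Predict with the designated fold model; returns (labels, fold used)."""
    return cvm.predict(X), cvm.best_fold_


def rank_features(cvm: BoostedTreesCV, top_k: int = 20) -> pd.Series:
    return cvm.rank_features(top_k=top_k)


class HierarchicalBoostedClassifier(BaseEstimator, ClassifierMixin):
    """Two-layer classifier: sex first, then identity within the sex.

    The sex layer is a binary :class:`BoostedTreesCV` on all calls
    (``n_trees_sex``, default 500); each identity layer is a multi-class
    :class:`BoostedTreesCV` trained on the calls whose *true* source is of
    that sex (``n_trees_id``, default 2500). Each component ranks its own
    features independently. Prediction can route calls by the predicted sex
    (deployable end-to-end mode) or by the provided true sex (per-component
    evaluation mode).
    """

    def __init__(self, n_trees_sex: int = 500, n_trees_id: int = 2500,
                 learning_rate: float = 0.1, max_depth: int = 3,
                 n_folds: int = 10, prediction: str = "best_fold",
                 random_state: int | None = None):
        self.n_trees_sex = n_trees_sex
        self.n_trees_id = n_trees_id
        self.learning_rate = learning_rate
        self.max_depth = max_depth
        self.n_folds = n_folds
        self.prediction = prediction
        self.random_state = random_state

    def fit(self, X, y, sex=None):
        """Fit on individual labels ``y`` with per-call ``sex`` labels."""
        X = _as_frame(X)
        y = np.asarray(y)
        if sex is None:
            raise ValueError("per-call sex labels are required: fit(X, y, sex=...)")
        sex = np.asarray(sex)
        if not (len(X) == y.size == sex.size):
            raise ValueError("X, y and sex must have equal lengths")
        sex_values = np.unique(sex)
        if sex_values.size < 2:
            raise ValueError("both sexes must be present to train the sex layer")
        # every individual must map to exactly one sex
        mapping = pd.DataFrame({"ind": y, "sex": sex}).drop_duplicates()
        dupes = mapping["ind"][mapping["ind"].duplicated()].tolist()
        if dupes:
            raise ValueError(f"individual(s) with more than one sex label: {dupes}")
        self.sex_of_ = dict(zip(mapping["ind"], mapping["sex"]))
        rng = np.random.default_rng(self.random_state)
        self.sex_model_ = BoostedTreesCV(
            n_trees=self.n_trees_sex, learning_rate=self.learning_rate,
            max_depth=self.max_depth, n_folds=self.n_folds,
            prediction=self.prediction,
            random_state=int(rng.integers(2**31))).fit(X, sex)
        self.id_models_: dict[str, BoostedTreesCV] = {}
        self.class_lists_: dict[str, list] = {}
        self.id_row_index_: dict[str, np.ndarray] = {}
        for s in sex_values:
            rows = np.flatnonzero(sex == s)
            inds = np.unique(y[rows])
            if inds.size < 2:
                raise ValueError(
                    f"sex {s!r} has {inds.size} individual(s); identity "
                    "classification needs at least 2")
            self.class_lists_[str(s)] = inds.tolist()
            self.id_row_index_[str(s)] = rows
            self.id_models_[str(s)] = BoostedTreesCV(
                n_trees=self.n_trees_id, learning_rate=self.learning_rate,
                max_depth=self.max_depth, n_folds=self.n_folds,
                prediction=self.prediction,
                random_state=int(rng.integers(2**31))).fit(X.iloc[rows], y[rows])
        self.classes_ = np.unique(y)
        return self

    def predict(self, X, routing: str = "predicted_sex", true_sex=None):
        """Route each call to one identity model; returns (sex, individual).

        ``routing="predicted_sex"`` uses the sex layer's output (end-to-end
        mode); ``routing="true_sex"`` uses the provided labels, reproducing
        per-component evaluation.
        """
        check_is_fitted(self, "sex_model_")
        X = _as_frame(X)
        if routing == "true_sex":
            if true_sex is None:
                raise ValueError("routing='true_sex' requires true_sex labels")
            route = np.asarray(true_sex)
        elif routing == "predicted_sex":
            route = self.sex_model_.predict(X)
        else:
            raise ValueError(f"unknown routing {routing!r}")
        ids = np.empty(len(X), dtype=object)
        for s, model in self.id_models_.items():
            rows = np.flatnonzero(route == s)
            if rows.size:
                ids[rows] = model.predict(X.iloc[rows])
        return route, ids

    def rank_features_per_component(self, top_k: int = 20) -> dict[str, pd.Series]:
        """Independent top-k feature rankings for the sex and identity layers."""
        check_is_fitted(self, "sex_model_")
        out = {"sex": self.sex_model_.rank_features(top_k)}
        for s, model in self.id_models_.items():
            out[f"id_{s}"] = model.rank_features(top_k)
        return out


def train_hierarchical(ds: BalancedDataset, config_sex: dict | None = None,
                       config_id: dict | None = None,
                       random_state: int | None = None) -> HierarchicalBoostedClassifier:
    """Train the hierarchy on a dataset balanced on the individual target."""
    config_sex = config_sex or {}
    config_id = config_id or {}
    clf = HierarchicalBoostedClassifier(
        n_trees_sex=config_sex.get("n_trees", 500),
        n_trees_id=config_id.get("n_trees", 2500),
        learning_rate=config_sex.get("learning_rate", 0.1),
        max_depth=config_sex.get("max_depth", 3),
        n_folds=config_sex.get("n_folds", 10),
        random_state=random_state)
    sex = ds.matrix.labels["sex"].to_numpy()
    return clf.fit(ds.X, ds.y, sex=sex)


def predict_hierarchical(hm: HierarchicalBoostedClassifier, X,
                         routing: str = "predicted_sex", true_sex=None):
    return hm.predict(X, routing=routing, true_sex=true_sex)
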