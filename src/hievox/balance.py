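"""Dataset balancing: minimum-call filtering, random undersampling, SMOTE.

Caller-identification datasets are naturally imbalanced (calls per
individual vary widely), which biases classifiers toward majority callers.
The recipe used here is: drop classes with fewer than ``min_calls`` (default
25) calls, optionally undersample classes above a cap to exactly the cap,
then SMOTE-oversample every class up to the (post-cap) majority count.

SMOTE synthesizes a minority-class point by picking an observation, one of
its k nearest same-class neighbours in feature space (Euclidean distance on
z-scored features), and placing a point a uniform random fraction of the way
along the segment between them: ``x_new = x + u * (x_nn - x)`` with one
``u ~ U(0, 1)`` per synthetic row. Synthetic rows are flagged so they can
never be re-undersampled or mistaken for recorded calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.neighbors import NearestNeighbors

from .core import FeatureMatrix, check_labels


@dataclass
class BalanceRecipe:
    """Parameters of the balancing pipeline, recorded with every dataset."""

    min_calls: int = 25
    cap: int | None = None
    smote_k: int = 5
    seed: int = 0
    scale_for_knn: bool = True
    cross_class_neighbours: bool = False
    per_feature_u: bool = False


@dataclass
class BalancedDataset:
    """A balanced feature matrix with its target labels and provenance."""

    matrix: FeatureMatrix
    class_labels: np.ndarray
    origin: np.ndarray  # per-row: "original" | "synthetic"
    recipe: BalanceRecipe
    target: str = "individual"
    class_counts_before: dict = field(default_factory=dict)
    class_counts_after: dict = field(default_factory=dict)
    dropped_classes: list = field(default_factory=list)

    def __post_init__(self) -> None:
        n = self.matrix.n_calls
        if len(self.class_labels) != n or len(self.origin) != n:
            raise ValueError("labels/origin must align with the matrix rows")

    @property
    def X(self) -> pd.DataFrame:
        return self.matrix.values

    @property
    def y(self) -> np.ndarray:
        return np.asarray(self.class_labels)

    @property
    def n_synthetic(self) -> int:
        return int(np.sum(self.origin == "synthetic"))


def design_imbalanced_counts(n_classes: int, total: int, majority: int,
                             min_count: int = 25) -> list[int]:
    """A deterministic per-class call-count vector with the given shape.

    Builds an imbalanced class profile with exactly ``total`` calls over
    ``n_classes`` classes, a single majority class of exactly ``majority``
    calls and every class at least ``min_count``: the canonical input shape
    for exercising the min-call/undersample/SMOTE recipe arithmetic.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    rest = n_classes - 1
    spare = total - majority - rest * min_count
    if spare < 0 or majority < min_count:
        raise ValueError(
            f"infeasible: total={total}, majority={majority}, "
            f"min_count={min_count}, n_classes={n_classes}")
    counts = [min_count + spare // rest] * rest
    for i in range(spare % rest):
        counts[i] += 1
    if max(counts) >= majority:
        raise ValueError("majority class would not be the unique maximum")
    counts.append(majority)
    assert sum(counts) == total
    return counts


class RandomUndersampler(BaseEstimator):
    """Reduce every class above ``cap`` to exactly ``cap`` rows.

    Rows are chosen uniformly without replacement; classes at or below the
    cap are untouched. ``fit_resample`` returns positional row indices so the
    caller can subset matrices and metadata consistently.
    """

    def __init__(self, cap: int | None = None, random_state: int | None = None):
        self.cap = cap
        self.random_state = random_state

    def fit_resample_indices(self, y) -> np.ndarray:
        y = check_labels(y)
        if self.cap is None:
            self.sample_indices_ = np.arange(y.size)
            return self.sample_indices_
        if self.cap < 1:
            raise ValueError("cap must be >= 1")
        rng = np.random.default_rng(self.random_state)
        keep: list[np.ndarray] = []
        for cls in pd.unique(y):
            idx = np.flatnonzero(y == cls)
            if idx.size > self.cap:
                idx = np.sort(rng.choice(idx, size=self.cap, replace=False))
            keep.append(idx)
        self.sample_indices_ = np.sort(np.concatenate(keep))
        return self.sample_indices_

    def fit_resample(self, X, y):
        idx = self.fit_resample_indices(y)
        X = pd.DataFrame(X)
        return X.iloc[idx], np.asarray(y)[idx]


class SmoteOversampler(BaseEstimator):
    """SMOTE: raise every class to the majority count with convex
    interpolates of same-class neighbour pairs.

    Neighbour search uses Euclidean distance on z-scored features (scaler
    fit on the input data and recorded); the interpolation itself happens in
    the original feature space. ``k_neighbors`` is reduced per class (with a
    warning) for classes smaller than k+1; a class with a single row is an
    error. Set ``cross_class_neighbours=True`` to draw neighbours from all
    classes (off by default: interpolating across classes synthesizes
    mislabelled points).
    """

    def __init__(self, k_neighbors: int = 5, random_state: int | None = None,
                 scale: bool = True, cross_class_neighbours: bool = False,
                 per_feature_u: bool = False):
        self.k_neighbors = k_neighbors
        self.random_state = random_state
        self.scale = scale
        self.cross_class_neighbours = cross_class_neighbours
        self.per_feature_u = per_feature_u

    def fit_resample(self, X, y):
        X = pd.DataFrame(X)
        y = check_labels(y)
        if len(X) != y.size:
            raise ValueError("X and y length mismatch")
        counts = pd.Series(y).value_counts()
        singletons = counts[counts < 2]
        if not singletons.empty:
            raise ValueError(
                f"SMOTE needs >= 2 rows per class; class(es) with one row: "
                f"{sorted(singletons.index.tolist())}")
        majority = int(counts.max())
        rng = np.random.default_rng(self.random_state)
        values = X.to_numpy(dtype=np.float64)
        if self.scale:
            mu = values.mean(axis=0)
            sd = values.std(axis=0)
            sd[sd == 0] = 1.0
            self.scaler_mean_, self.scaler_sd_ = mu, sd
            scaled = (values - mu) / sd
        else:
            self.scaler_mean_ = self.scaler_sd_ = None
            scaled = values

        syn_rows, syn_labels = [], []
        # iterate classes in first-appearance order for determinism
        for cls in pd.unique(y):
            idx = np.flatnonzero(y == cls)
            deficit = majority - idx.size
            if deficit <= 0:
                continue
            pool = np.arange(y.size) if self.cross_class_neighbours else idx
            k = min(self.k_neighbors, pool.size - 1)
            if k < self.k_neighbors:
                warnings.warn(
                    f"class {cls!r} has {idx.size} rows; reducing SMOTE "
                    f"k from {self.k_neighbors} to {k}", stacklevel=2)
            nn = NearestNeighbors(n_neighbors=k + 1).fit(scaled[pool])
            _, nbr = nn.kneighbors(scaled[idx])
            nbr = pool[nbr[:, 1:]]  # drop self, map back to row space
            obs_choice = rng.integers(0, idx.size, size=deficit)
            nbr_choice = rng.integers(0, k, size=deficit)
            if self.per_feature_u:
                u = rng.uniform(0.0, 1.0, size=(deficit, values.shape[1]))
            else:
                u = rng.uniform(0.0, 1.0, size=(deficit, 1))
            x_obs = values[idx[obs_choice]]
            x_nn = values[nbr[obs_choice, nbr_choice]]
            syn_rows.append(x_obs + u * (x_nn - x_obs))
            syn_labels.extend([cls] * deficit)

        origin = np.array(["original"] * y.size, dtype=object)
        if syn_rows:
            syn = np.vstack(syn_rows)
            syn_index = [f"smote_{i:06d}" for i in range(syn.shape[0])]
            X_res = pd.concat(
                [X, pd.DataFrame(syn, columns=X.columns,
                                 index=pd.Index(syn_index, name=X.index.name))])
            y_res = np.concatenate([y, np.array(syn_labels, dtype=y.dtype)])
            origin = np.concatenate([origin, np.array(["synthetic"] * syn.shape[0],
                                                      dtype=object)])
        else:
            X_res, y_res = X, y
        self.sampling_counts_ = counts.to_dict()
        return X_res, y_res, origin


def undersample_classes(m: FeatureMatrix, labels, cap: int, rng_state):
    """Functional form of :class:`RandomUndersampler` on a feature matrix."""
    seed = rng_state if not isinstance(rng_state, np.random.Generator) else None
    sampler = RandomUndersampler(cap=cap, random_state=seed)
    if isinstance(rng_state, np.random.Generator):
        sampler.random_state = int(rng_state.integers(2**31))
    idx = sampler.fit_resample_indices(labels)
    return m.subset(m.values.index[idx]), np.asarray(labels)[idx]


def smote_oversample(m: FeatureMatrix, labels, k: int, rng_state,
                     target: str = "individual") -> BalancedDataset:
    """Functional form of :class:`SmoteOversampler` on a feature matrix."""
    seed = (int(rng_state.integers(2**31))
            if isinstance(rng_state, np.random.Generator) else rng_state)
    sampler = SmoteOversampler(k_neighbors=k, random_state=seed)
    labels = check_labels(labels)
    X_res, y_res, origin = sampler.fit_resample(m.values, labels)
    matrix = _extend_matrix(m, X_res, y_res, origin, target)
    before = pd.Series(labels).value_counts().to_dict()
    after = pd.Series(y_res).value_counts().to_dict()
    return BalancedDataset(
        matrix=matrix, class_labels=y_res, origin=origin,
        recipe=BalanceRecipe(smote_k=k, seed=seed), target=target,
        class_counts_before=before, class_counts_after=after)


def _extend_matrix(m: FeatureMatrix, X_res: pd.DataFrame, y_res: np.ndarray,
                   origin: np.ndarray, target: str) -> FeatureMatrix:
    """Rebuild a FeatureMatrix with labels for synthetic rows attached."""
    n_orig = m.n_calls
    labels = m.labels.copy()
    n_syn = len(X_res) - n_orig
    if n_syn > 0:
        if target == "individual":
            # synthetic rows inherit their class's individual id and its sex
            sex_of = (m.labels.groupby(m.labels["individual_id"])["sex"]
                      .agg(lambda s: s.iloc[0]).to_dict())
            syn_ind = y_res[n_orig:]
            syn_sex = [sex_of.get(i, "F") for i in syn_ind]
        else:  # balanced on sex: synthetic rows have no single source caller
            syn_ind = ["synthetic"] * n_syn
            syn_sex = list(y_res[n_orig:])
        call_type = m.labels["call_type"].iloc[0]
        syn_labels = pd.DataFrame(
            {"individual_id": syn_ind, "sex": syn_sex,
             "call_type": [call_type] * n_syn},
            index=X_res.index[n_orig:])
        labels = pd.concat([labels, syn_labels])
    return FeatureMatrix(values=X_res, labels=labels,
                         bank_version=m.bank_version,
                         provenance=dict(m.provenance))


def build_balanced_dataset(
    m: FeatureMatrix, target: str, recipe: BalanceRecipe | None = None
) -> BalancedDataset:
    """Full balancing pipeline: min-call filter -> cap undersample -> SMOTE.

    ``target`` is ``"individual"`` or ``"sex"`` and selects the class label
    column. The matrix must already be common-feature filtered (all finite).
    Per-class before/after counts and dropped classes are recorded.
    """
    recipe = recipe or BalanceRecipe()
    if target not in ("individual", "sex"):
        raise ValueError(f"target must be 'individual' or 'sex', got {target!r}")
    if not m.is_finite():
        raise ValueError("matrix contains non-finite values; run "
                         "filter_common_features first")
    col = "individual_id" if target == "individual" else "sex"
    labels = m.labels[col].to_numpy()
    counts = pd.Series(labels).value_counts()
    keep_classes = counts[counts >= recipe.min_calls].index
    dropped = sorted(counts[counts < recipe.min_calls].index.tolist())
    if len(keep_classes) < 2:
        raise ValueError(
            f"fewer than 2 classes have >= {recipe.min_calls} calls "
            f"(dropped: {dropped})")
    mask = np.isin(labels, keep_classes)
    m_kept = m.subset(m.values.index[mask])
    labels_kept = labels[mask]
    before = pd.Series(labels_kept).value_counts().to_dict()

    rng = np.random.default_rng(recipe.seed)
    under_seed = int(rng.integers(2**31))
    smote_seed = int(rng.integers(2**31))
    if recipe.cap is not None:
        if recipe.cap < recipe.min_calls:
            raise ValueError(
                f"cap ({recipe.cap}) below min_calls ({recipe.min_calls})")
        m_kept, labels_kept = undersample_classes(
            m_kept, labels_kept, recipe.cap, under_seed)

    sampler = SmoteOversampler(
        k_neighbors=recipe.smote_k, random_state=smote_seed,
        scale=recipe.scale_for_knn,
        cross_class_neighbours=recipe.cross_class_neighbours,
        per_feature_u=recipe.per_feature_u)
    X_res, y_res, origin = sampler.fit_resample(m_kept.values, labels_kept)
    matrix = _extend_matrix(m_kept, X_res, y_res, origin, target)
    after = pd.Series(y_res).value_counts().to_dict()
    return BalancedDataset(
        matrix=matrix, class_labels=y_res, origin=origin, recipe=recipe,
        target=target, class_counts_before=before, class_counts_after=after,
        dropped_classes=dropped)
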