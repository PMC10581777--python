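"""t-SNE embedding, silhouette scoring and the random-feature null test.

How good is the boosted ensemble's feature selection? The check used here
embeds the calls in 2-D with Barnes-Hut t-SNE restricted to the selected
top-k features and scores how well the embedding clusters by caller with
the mean silhouette. A null distribution comes from repeating the embedding
with k features drawn uniformly at random; a Gaussian is fitted to the null
scores (by sample mean and sd) and the upper-tail probability of the
observed top-k score under that Gaussian is the reported p-value.

t-SNE hyperparameters follow the large-dataset heuristics used throughout
this pipeline: perplexity n/100, learning rate n/12, early exaggeration 4,
Barnes-Hut trade-off 0.5, squared-Euclidean affinities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_samples

from .core import check_labels


@dataclass
class EmbeddingResult:
    coords: np.ndarray  # n x 2
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be n x 2")
        if not np.isfinite(self.coords).all():
            raise ValueError("embedding produced non-finite coordinates")


@dataclass
class NullTestResult:
    """Observed top-k silhouette against the random-k Gaussian null."""

    observed_score: float
    null_scores: np.ndarray
    mu: float
    sigma: float
    z: float
    p: float
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sigma > 0:
            if not np.isclose(self.z, (self.observed_score - self.mu) / self.sigma):
                raise ValueError("z must equal (observed - mu)/sigma")
            if not np.isclose(self.p, float(stats.norm.sf(self.z))):
                raise ValueError("p must be the Gaussian upper-tail probability")

    def to_dict(self) -> dict:
        return {
            "observed_score": self.observed_score,
            "null_scores": [float(s) for s in self.null_scores],
            "mu": self.mu, "sigma": self.sigma, "z": self.z, "p": self.p,
            "flags": list(self.flags),
        }


def tsne_embed(X, seed: int = 0, *, perplexity: float | None = None,
               learning_rate: float | None = None, exaggeration: float = 4.0,
               theta: float = 0.5, min_n: int = 300) -> EmbeddingResult:
    """2-D Barnes-Hut t-SNE with data-size-scaled hyperparameters.

    Defaults: perplexity = n/100 and learning rate = n/12, which require
    n >= ``min_n`` calls; pass explicit values to embed smaller sets.
    Deterministic for a fixed seed. Affinities use squared Euclidean
    distances.
    """
    X = np.asarray(pd.DataFrame(X), dtype=np.float64)
    n = X.shape[0]
    if perplexity is None or learning_rate is None:
        if n < min_n:
            raise ValueError(
                f"n = {n} is too small for the perplexity = n/100 rule "
                f"(needs n >= {min_n}); pass perplexity= and learning_rate= "
                "explicitly to override")
        perplexity = n / 100.0 if perplexity is None else perplexity
        learning_rate = n / 12.0 if learning_rate is None else learning_rate
    tsne = TSNE(n_components=2, perplexity=perplexity,
                learning_rate=learning_rate, early_exaggeration=exaggeration,
                metric="euclidean",  # affinities use squared distances
                method="barnes_hut", angle=theta, init="pca",
                random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coords = tsne.fit_transform(X)
    return EmbeddingResult(
        coords=coords,
        params={"perplexity": perplexity, "learn_rate": learning_rate,
                "exaggeration": exaggeration, "barnes_hut_theta": theta,
                "metric": "squared Euclidean", "seed": seed})


def mean_silhouette(coords, labels, metric: str = "euclidean") -> float:
    """Mean over points of (b - a) / max(a, b) on the 2-D embedding.

    Points in singleton classes contribute silhouette 0 (with a warning).
    Distances on the coords are plain Euclidean by default; pass
    ``metric='sqeuclidean'`` for squared distances.
    """
    coords = np.asarray(coords, dtype=np.float64)
    labels = check_labels(labels)
    if coords.shape[0] != labels.size:
        raise ValueError("coords and labels must have equal length")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("need at least 2 distinct labels")
    if (counts == 1).any():
        warnings.warn("singleton class(es) present; their points get "
                      "silhouette 0", stacklevel=2)
    vals = silhouette_samples(coords, labels, metric=metric)
    return float(np.mean(vals))


def silhouette_null_test(X_full, labels, ranked_features, k: int = 20,
                         n_draws: int = 100, seed: int = 0,
                         tsne_kwargs: dict | None = None) -> NullTestResult:
    """Top-k versus random-k feature-selection quality test.

    The observed score embeds the calls on the top-``k`` ranked features and
    takes the mean silhouette over ``labels``; the null repeats this
    ``n_draws`` times with k features sampled uniformly without replacement
    from all columns (no exclusions — the top features may be redrawn by
    chance). Each embedding gets a fresh seed derived from the master seed.
    A Gaussian (moment fit) to the null scores gives z and the upper-tail p.
    """
    X_full = pd.DataFrame(X_full)
    labels = check_labels(labels)
    if len(X_full.columns) <= k:
        raise ValueError(f"need more than k = {k} features, have "
                         f"{len(X_full.columns)}")
    ranked = list(ranked_features)
    missing = [f for f in ranked[:k] if f not in X_full.columns]
    if missing:
        raise ValueError(f"ranked feature(s) not in the table: {missing[:5]}")
    tsne_kwargs = dict(tsne_kwargs or {})
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31, size=n_draws + 1)

    emb = tsne_embed(X_full[ranked[:k]], seed=int(seeds[0]), **tsne_kwargs)
    observed = mean_silhouette(emb.coords, labels)

    cols = np.asarray(X_full.columns, dtype=object)
    null_scores = np.empty(n_draws)
    for i in range(n_draws):
        draw = rng.choice(cols, size=k, replace=False)
        e = tsne_embed(X_full[list(draw)], seed=int(seeds[i + 1]), **tsne_kwargs)
        null_scores[i] = mean_silhouette(e.coords, labels)

    mu = float(null_scores.mean())
    sigma = float(null_scores.std(ddof=1))
    flags = []
    if sigma > 0:
        z = float((observed - mu) / sigma)
        p = float(stats.norm.sf(z))
    else:
        z = np.inf if observed > mu else (-np.inf if observed < mu else 0.0)
        p = 0.0 if observed > mu else (1.0 if observed < mu else 0.5)
        flags.append("null distribution has zero variance")
    return NullTestResult(observed_score=observed, null_scores=null_scores,
                          mu=mu, sigma=sigma, z=z, p=p, flags=flags)
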