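"""Independent brute-force oracles used by the test suite.

These are deliberately naive O(n^2) / enumeration implementations kept
separate from the package code paths they check.
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pandas as pd


def auc_all_pairs(scores: np.ndarray, positives: np.ndarray) -> float:
    """One-vs-rest AUC as the concordance fraction over all pos/neg pairs
    (ties count 1/2)."""
    pos = scores[positives]
    neg = scores[~positives]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def wilcoxon_exact_p(diffs: np.ndarray) -> tuple[float, float]:
    """Two-sided exact signed-rank p by enumerating all sign assignments.

    Assumes no zero differences and no tied absolute values. Returns
    (W = min one-sided statistic, p).
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = pd.Series(np.abs(d)).rank().to_numpy()
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w_obs = min(w_plus, w_minus)
    count = 0
    for signs in product((0, 1), repeat=n):
        wp = float(sum(r for r, s in zip(ranks, signs) if s))
        wm = ranks.sum() - wp
        if min(wp, wm) <= w_obs:
            count += 1
    return w_obs, count / 2**n


def silhouette_bruteforce(coords: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette via explicit pairwise Euclidean distances."""
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(labels)
    n = len(labels)
    dist = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    vals = np.zeros(n)
    for i in range(n):
        same = (labels == labels[i]) & (np.arange(n) != i)
        if same.sum() == 0:
            vals[i] = 0.0
            continue
        a = dist[i, same].mean()
        b = min(dist[i, labels == other].mean()
                for other in set(labels.tolist()) if other != labels[i])
        vals[i] = (b - a) / max(a, b)
    return float(vals.mean())


def make_gaussian_features(class_counts: dict[str, int], n_features: int = 10,
                           class_sep: float = 3.0, seed: int = 0,
                           sex_of=None):
    """A labelled Gaussian-blob FeatureMatrix (no audio involved).

    Each class gets its own mean vector at distance ~class_sep; ``sex_of``
    maps class -> 'F'/'M' (default: alternating).
    """
    from hievox.core import FeatureMatrix

    rng = np.random.default_rng(seed)
    rows, inds = [], []
    classes = list(class_counts)
    means = {c: rng.normal(0.0, class_sep, size=n_features) for c in classes}
    for c in classes:
        rows.append(means[c] + rng.normal(0.0, 1.0,
                                          size=(class_counts[c], n_features)))
        inds += [c] * class_counts[c]
    values = pd.DataFrame(
        np.vstack(rows),
        index=pd.Index([f"call_{i:05d}" for i in range(len(inds))],
                       name="call_id"),
        columns=[f"f{j}" for j in range(n_features)])
    if sex_of is None:
        sex_of = {c: ("F" if i % 2 == 0 else "M")
                  for i, c in enumerate(classes)}
    labels = pd.DataFrame(
        {"individual_id": inds,
         "sex": [sex_of[c] for c in inds],
         "call_type": ["trill"] * len(inds)},
        index=values.index)
    return FeatureMatrix(values=values, labels=labels,
                         bank_version="synthetic-gaussian")
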