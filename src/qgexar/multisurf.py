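"""MultiSURF relief-based feature weighting and the weight > 0 retention rule.

MultiSURF assigns each feature a weight by contrasting feature-value
differences between each target instance and its *near* neighbors.
Nearness is instance-specific: for target ``i`` the threshold ``T_i`` is
the mean of ``i``'s distances to all other instances, and a dead-band of
half the standard deviation of those distances excludes ambiguous
neighbors, so ``near(i) = { j : d_ij < T_i - D_i }``. Near neighbors of
the same class (hits) decrease a feature's weight by the normalized
value difference; near neighbors of a different class (misses) increase
it, with miss contributions weighted by class priors (a no-op for the
binary case). Weights are averaged within each target's hit and miss
sets and then over targets, which makes the result independent of
instance order.

Distances are Manhattan over range-normalized features: the algorithm's
literature convention for continuous features. Constant features drop
out exactly (zero diffs). Features with positive final weight are
retained; everything at or below zero is discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted

from qgexar.util import check_finite

DISTANCE_METRIC = "manhattan_range_normalized"


def _range_normalize(X: np.ndarray) -> np.ndarray:
    """Scale each feature by its observed range; constant features -> zeros."""
    span = X.max(axis=0) - X.min(axis=0)
    span[span == 0] = 1.0
    return X / span


def pairwise_distances(X: np.ndarray) -> np.ndarray:
    """Symmetric Manhattan distance matrix over range-normalized features."""
    X = check_finite(X)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 1:
        raise ValueError("need at least 2 instances and 1 feature")
    return squareform(pdist(_range_normalize(X), metric="cityblock"))


def neighbor_sets(distances: np.ndarray) -> list[np.ndarray]:
    """Near-neighbor index set for each target instance.

    ``T_i`` = mean distance from ``i`` to all others, dead band
    ``D_i`` = half the SD of those distances; ``near(i)`` collects every
    ``j != i`` with ``d_ij < T_i - D_i``.
    """
    D = np.asarray(distances, dtype=float)
    n = D.shape[0]
    if n < 3:
        raise ValueError("need at least 3 instances to define near neighbors")
    near = []
    idx = np.arange(n)
    for i in range(n):
        d = D[i, idx != i]
        cut = d.mean() - d.std() / 2.0
        others = idx[idx != i]
        near.append(others[d < cut])
    return near


def multisurf_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Raw MultiSURF weight per feature column (vectorized)."""
    X = check_finite(X)
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    n, p = X.shape
    Xn = _range_normalize(X)
    D = squareform(pdist(Xn, metric="cityblock"))
    near = neighbor_sets(D)

    classes, counts = np.unique(y, return_counts=True)
    prior = dict(zip(classes.tolist(), (counts / n).tolist()))

    W = np.zeros(p)
    for i in range(n):
        nbrs = near[i]
        if nbrs.size == 0:
            continue
        same = nbrs[y[nbrs] == y[i]]
        if same.size:
            W -= np.abs(Xn[i] - Xn[same]).mean(axis=0)
        # miss contributions, prior-weighted per opposing class
        # (sums to a plain mean in the binary case)
        denom = 1.0 - prior[y[i]]
        for c in classes:
            if c == y[i]:
                continue
            miss = nbrs[y[nbrs] == c]
            if miss.size:
                W += (prior[c] / denom) * np.abs(Xn[i] - Xn[miss]).mean(axis=0)
    return W / n


@dataclass
class FeatureWeightVector:
    """Named MultiSURF weights for a gene catalog."""

    weights: pd.Series  # gene_id -> weight
    n_instances_used: int
    distance_metric: str = DISTANCE_METRIC

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.weights.to_numpy(dtype=float))):
            raise ValueError("feature weights must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.weights.index,
                "weight": self.weights.to_numpy(),
                "selected": (self.weights.to_numpy() > 0).astype(int),
            }
        )


def multisurf_weights(X, y, gene_ids=None) -> FeatureWeightVector:
    """MultiSURF weights as a named vector; selection rule is weight > 0."""
    X = np.asarray(X, dtype=float)
    if gene_ids is None:
        gene_ids = [f"f{j}" for j in range(X.shape[1])]
    scores = multisurf_scores(X, np.asarray(y))
    return FeatureWeightVector(
        weights=pd.Series(scores, index=list(gene_ids)),
        n_instances_used=X.shape[0],
    )


def select_features(weights: FeatureWeightVector) -> list[str]:
    """Gene ids with weight strictly above 0, by descending weight.

    Equal weights keep catalog order. May be empty — callers must handle
    an empty selection (typically by falling back to all features).
    """
    w = weights.weights
    positive = w[w > 0]
    return positive.sort_values(ascending=False, kind="stable").index.tolist()


class MultiSURF(SelectorMixin, BaseEstimator):
    """Scikit-learn selector: keep features with positive MultiSURF weight.

    Attributes
    ----------
    feature_weights_ : ndarray of shape (n_features,)
        MultiSURF weight per input column.
    """

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        self.feature_weights_ = multisurf_scores(X, np.asarray(y))
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "feature_weights_")
        mask = self.feature_weights_ > 0
        if not mask.any():
            # nothing survives the strict rule: degrade to identity so a
            # downstream model still has inputs
            mask = np.ones_like(mask, dtype=bool)
        return mask

    def ranking(self) -> np.ndarray:
        """Column indices ordered by descending weight (stable)."""
        check_is_fitted(self, "feature_weights_")
        return np.argsort(-self.feature_weights_, kind="stable")
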