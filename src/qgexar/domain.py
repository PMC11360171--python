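"""Cosine-similarity 3-NN applicability domain and coverage curves.

A prediction is considered reliable when the query chemical's
expression signature resembles the training chemicals the model learned
from. Resemblance is the mean cosine similarity to the query's three
most similar training profiles; the in-domain cutoff is

    Dc = <y> - Z * sigma,

where <y> and sigma are the mean and SD of the training chemicals' own
leave-self-out mean top-3 similarities and Z (default 0.5) sets the
strictness. Signed z-score profiles can produce negative cosine
similarities; these are kept as-is, and thresholds in [0, 1] simply
exclude them.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.metrics.pairwise import cosine_similarity as _sk_cosine
from sklearn.utils.validation import check_is_fitted

from qgexar.metrics import confusion, metric_set
from qgexar.util import check_finite


def cosine_similarity_profiles(u, v) -> float:
    """Cosine similarity of two expression profiles, in [-1, 1]."""
    u = check_finite(u, "u").ravel()
    v = check_finite(v, "v").ravel()
    if u.shape != v.shape:
        raise ValueError("profiles must have equal length")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for a zero-norm profile")
    return float(np.dot(u, v) / (nu * nv))


def _topk_mean(sims: np.ndarray, k: int) -> np.ndarray:
    """Row-wise mean of the k largest entries."""
    part = np.partition(sims, -k, axis=1)[:, -k:]
    return part.mean(axis=1)


def mean_topk_similarity(query, training, k: int = 3, exclude_index: int | None = None) -> float:
    """Mean cosine similarity of the query to its k nearest training profiles.

    ``exclude_index`` removes one training row (used when the query *is*
    a training chemical, so self-similarity never counts).
    """
    training = check_finite(training, "training")
    if exclude_index is not None:
        training = np.delete(training, exclude_index, axis=0)
    if k > training.shape[0]:
        raise ValueError(f"k={k} exceeds the {training.shape[0]} available training chemicals")
    sims = _sk_cosine(np.atleast_2d(np.asarray(query, dtype=float)), training)
    return float(_topk_mean(sims, k)[0])


def dc_from_stats(mean_similarity: float, sd_similarity: float, z: float = 0.5) -> float:
    """Threshold arithmetic: Dc = <y> - Z * sigma."""
    return mean_similarity - z * sd_similarity


class CosineKNNApplicabilityDomain(BaseEstimator):
    """k-NN cosine-similarity applicability domain.

    Fit on the training signature matrix (typically landmark plus
    best-inferred genes); ``assess`` flags queries whose mean top-k
    similarity reaches the fitted threshold ``threshold_``.

    Attributes
    ----------
    training_similarities_ : per-training-chemical leave-self-out mean
        top-k cosine similarity.
    mean_, sd_ : their mean <y> and population SD sigma.
    threshold_ : Dc = <y> - Z * sigma.
    """

    def __init__(self, k: int = 3, z: float = 0.5):
        self.k = k
        self.z = z

    def fit(self, X, y=None):
        X = check_finite(X)
        n = X.shape[0]
        if n < self.k + 1:
            raise ValueError(
                f"need at least k+1={self.k + 1} training chemicals for leave-self-out top-{self.k}"
            )
        S = _sk_cosine(X)
        np.fill_diagonal(S, -np.inf)  # self never counts as a neighbor
        self.training_similarities_ = _topk_mean(S, self.k)
        self.mean_ = float(self.training_similarities_.mean())
        self.sd_ = float(self.training_similarities_.std())  # population SD
        if self.sd_ == 0:
            warnings.warn("degenerate training set: all top-k similarities identical; Dc = <y>")
        self.threshold_ = dc_from_stats(self.mean_, self.sd_, self.z)
        self.training_profiles_ = X
        return self

    def score_samples(self, X) -> np.ndarray:
        """Mean top-k cosine similarity of each query to the training set."""
        check_is_fitted(self, "threshold_")
        X = check_finite(X)
        sims = _sk_cosine(X, self.training_profiles_)
        return _topk_mean(sims, self.k)

    def assess(self, X, chemical_ids=None) -> pd.DataFrame:
        """Per-query AD table: similarity, threshold, in-domain flag."""
        sims = self.score_samples(X)
        if chemical_ids is None:
            chemical_ids = [f"Q{i}" for i in range(len(sims))]
        return pd.DataFrame(
            {
                "chemical_id": list(chemical_ids),
                "mean_top3_cosine": sims,
                "Dc": self.threshold_,
                "in_domain": sims >= self.threshold_,
            }
        )


def domain_threshold(training, k: int = 3, z: float = 0.5) -> float:
    """Dc for a training matrix (thin wrapper over the estimator)."""
    return CosineKNNApplicabilityDomain(k=k, z=z).fit(training).threshold_


def coverage_curve(similarities, probabilities, labels, thresholds) -> pd.DataFrame:
    """Balanced accuracy vs coverage as the similarity cutoff rises.

    At each threshold only chemicals with similarity >= threshold are
    scored; coverage is the retained fraction. BA is NaN when the
    retained subset misses a class (undefined, not zero).
    """
    sims = np.asarray(similarities, dtype=float)
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    rows = []
    for t in np.asarray(thresholds, dtype=float):
        mask = sims >= t
        coverage = float(mask.mean()) if sims.size else 0.0
        ba = float("nan")
        if mask.any():
            ms = metric_set(confusion(p[mask], y[mask]))
            ba = ms.ba
        rows.append({"threshold": float(t), "balanced_accuracy": ba, "coverage": coverage})
    return pd.DataFrame(rows)
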