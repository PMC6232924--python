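"""Laplacian-score ranking of connectional features.

The score of a feature column f (one value per subject) against a learned
subject-similarity matrix S is

    LS(f) = f' S f / (f' f)

i.e. the concordance between the feature and the similarity structure: a
feature varying smoothly over strongly similar subjects scores high.  S is
symmetrized before scoring.  Features are mean-centered across subjects by
default: under a row-stochastic S a constant offset alone scores 1.0, so
centering removes that artifact (a raw mode is provided).  Features are
ranked in descending score order, i.e. most concordant first; ties break to
the lower feature index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

from .networks import describe_feature


@dataclass
class RankedFeature:
    position: int
    score: float
    description: str


def laplacian_score(f: np.ndarray, S: np.ndarray, center: bool = True) -> float:
    """Concordance f'Sf / f'f of one feature with the similarity S."""
    f = np.asarray(f, dtype=float).ravel()
    S = np.asarray(S, dtype=float)
    Ssym = (S + S.T) / 2.0
    if center:
        f = f - f.mean()
    denom = float(f @ f)
    if denom == 0.0:
        warnings.warn("feature has zero variance; Laplacian score set to 0",
                      RuntimeWarning, stacklevel=2)
        return 0.0
    return float(f @ Ssym @ f) / denom


def laplacian_scores(feature_matrix: np.ndarray, S: np.ndarray,
                     center: bool = True) -> np.ndarray:
    """Vectorized Laplacian score of every column of an n x d matrix."""
    X = check_array(feature_matrix, dtype=float)
    S = np.asarray(S, dtype=float)
    Ssym = (S + S.T) / 2.0
    if center:
        X = X - X.mean(axis=0, keepdims=True)
    denom = np.einsum("nd,nd->d", X, X)
    num = np.einsum("nd,nm,md->d", X, Ssym, X, optimize=True)
    zero = denom == 0.0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-variance feature(s); scores set to 0",
            RuntimeWarning, stacklevel=2,
        )
    out = np.zeros_like(denom)
    np.divide(num, denom, out=out, where=~zero)
    return out


def rank_features(feature_matrix: np.ndarray, S: np.ndarray, top_k: int,
                  index_map: list | None = None,
                  roi_names: list[str] | None = None,
                  attribute_names: list[str] | None = None,
                  center: bool = True, ascending: bool = False) -> list[RankedFeature]:
    """Top-k features by Laplacian score (descending by default).

    Ties break toward the lower feature index.  When an ``index_map`` (from
    the network feature extraction) and ROI names are given, each feature is
    described by its named ROI pair(s)/attribute.
    """
    scores = laplacian_scores(feature_matrix, S, center=center)
    d = scores.shape[0]
    if top_k > d:
        raise ValueError(f"top_k={top_k} exceeds the number of features {d}")
    key = scores if ascending else -scores
    order = np.argsort(key, kind="stable")
    out = []
    for pos in order[:top_k]:
        pos = int(pos)
        if index_map is not None and roi_names is not None:
            desc = describe_feature(index_map[pos], roi_names, attribute_names)
        else:
            desc = f"feature[{pos}]"
        out.append(RankedFeature(position=pos, score=float(scores[pos]),
                                 description=desc))
    return out


class LaplacianScoreRanker(BaseEstimator):
    """Scores features against a subject-similarity matrix.

    ``fit(X, similarity=S)`` computes the score of every column of X; the
    fitted ``ranking_`` orders feature indices from most to least
    concordant.  ``transform`` keeps the ``top_k`` highest-scoring columns.
    """

    def __init__(self, top_k: int = 3, *, center: bool = True,
                 ascending: bool = False):
        self.top_k = top_k
        self.center = center
        self.ascending = ascending

    def fit(self, X, y=None, *, similarity):
        X = check_array(X, dtype=float)
        self.scores_ = laplacian_scores(X, similarity, center=self.center)
        key = self.scores_ if self.ascending else -self.scores_
        self.ranking_ = np.argsort(key, kind="stable")
        return self

    def transform(self, X):
        check_is_fitted(self, "ranking_")
        X = check_array(X, dtype=float)
        return X[:, self.ranking_[: self.top_k]]
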