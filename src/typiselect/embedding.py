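"""Low-dimensional embedding of staining patterns by multidimensional scaling.

The N×N Hamming distance matrix is embedded into M dimensions (default M=3)
with metric MDS: stress majorization (SMACOF) initialized from classical
(Torgerson) scaling, which makes the result effectively deterministic and
exact whenever the distances are realizable in M dimensions.  Distances enter
raw, with no transform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.manifold import smacof
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

__all__ = ["EmbeddedPoints", "HammingMDS", "embed_mds", "stress", "classical_mds"]

_MAX_ITER = 3000
_TOL = 1e-9


@dataclass
class EmbeddedPoints:
    """MDS coordinates for all cases: ``coords`` is N×M, centered at the origin."""

    coords: np.ndarray
    M: int
    stress: float
    seed: int


def _check_distance_matrix(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(D < 0):
        raise ValueError("distance matrix must be nonnegative")
    if not np.allclose(np.diag(D), 0):
        raise ValueError("distance matrix must have zero diagonal")
    return D


def classical_mds(D: np.ndarray, M: int) -> np.ndarray:
    """Torgerson scaling: eigendecomposition of the double-centered squared distances.

    Exact when ``D`` is Euclidean and realizable in ``M`` dimensions; otherwise a
    good deterministic initialization for stress majorization.
    """
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:M]
    lam = np.clip(vals[order], 0.0, None)
    X = vecs[:, order] * np.sqrt(lam)[None, :]
    return X


def stress(D: np.ndarray, pts: EmbeddedPoints | np.ndarray) -> float:
    """Normalized raw stress: sum of squared distance residuals over sum of squared D.

    Zero iff the embedded Euclidean distances reproduce ``D`` exactly; equals 1
    when all points collapse to one location and ``D`` is nonzero.
    """
    D = np.asarray(D, dtype=float)
    X = pts.coords if isinstance(pts, EmbeddedPoints) else np.asarray(pts)
    if X.shape[0] != D.shape[0]:
        raise ValueError("coordinate/distance shape mismatch")
    diff = X[:, None, :] - X[None, :, :]
    E = np.sqrt((diff**2).sum(-1))
    denom = (D**2).sum()
    if denom == 0:
        return 0.0
    return float(((E - D) ** 2).sum() / denom)


def embed_mds(D: np.ndarray, M: int = 3, seed: int = 0) -> EmbeddedPoints:
    """Embed a distance matrix into ``M`` dimensions by metric MDS.

    SMACOF majorization from a classical-scaling start; coordinates are
    centered at the origin.  Deterministic given ``(D, M, seed)``.
    """
    D = _check_distance_matrix(D)
    n = D.shape[0]
    if not 1 <= M < max(n, 2):
        raise ValueError(f"require 1 <= M < N (got M={M}, N={n})")
    init = classical_mds(D, M)
    if np.allclose(D, 0):
        X = np.zeros((n, M))
    else:
        X, _ = smacof(
            D,
            n_components=M,
            init=init,
            n_init=1,
            metric=True,
            max_iter=_MAX_ITER,
            eps=_TOL,
            random_state=seed,
            normalized_stress=False,
        )
    X = X - X.mean(axis=0, keepdims=True)
    pts = EmbeddedPoints(coords=X, M=M, stress=0.0, seed=seed)
    pts.stress = stress(D, pts)
    logger.info("MDS: N=%d, M=%d, normalized raw stress %.3e", n, M, pts.stress)
    return pts


class HammingMDS(BaseEstimator, TransformerMixin):
    """Metric-MDS embedder for precomputed (Hamming) distance matrices.

    Parameters
    ----------
    n_components : int, default=3
        Target dimension ``M``.
    random_state : int, default=0
        Seed for any residual randomness in the majorization.

    Attributes
    ----------
    embedding_ : ndarray of shape (N, n_components)
        Origin-centered coordinates.
    stress_ : float
        Normalized raw stress of the fit.
    """

    def __init__(self, n_components: int = 3, random_state: int = 0):
        self.n_components = n_components
        self.random_state = random_state

    def fit(self, X: np.ndarray, y=None) -> "HammingMDS":
        pts = embed_mds(X, M=self.n_components, seed=self.random_state)
        self.embedding_ = pts.coords
        self.stress_ = pts.stress
        return self

    def fit_transform(self, X: np.ndarray, y=None) -> np.ndarray:
        self.fit(X)
        return self.embedding_

    def transform(self, X: np.ndarray) -> np.ndarray:
        # MDS has no out-of-sample map; transform re-embeds the given matrix.
        check_is_fitted(self, "embedding_")
        return embed_mds(X, M=self.n_components, seed=self.random_state).coords
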