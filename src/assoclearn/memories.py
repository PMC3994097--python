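"""Foundational associative memories: Lernmatrix and Linear Associator.

The Lernmatrix (Steinbuch, 1961) is a heteroassociative memory over binary
input patterns x in {0,1}^n.  Learning starts from the zero matrix M (m x n)
and, for each association of x with class k, updates row k by +eps where
x_j = 1 and -eps where x_j = 0; rows of other classes are untouched.  Recall
of a pattern flags every class whose row score  sum_j M[i,j] x_j  attains
the maximum - the result is a binary class vector, possibly with ties.

The Linear Associator accumulates outer products: M = sum_mu y^mu (x^mu)^T.
Recall is the plain matrix-vector product M x, with no thresholding.  When
the inputs are mutually orthonormal, recall of a stored input reproduces its
stored output exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "LernmatrixMemory",
    "LinearAssociatorMemory",
    "LernmatrixClassifier",
    "lernmatrix_learn",
    "lernmatrix_recall",
    "linear_associator_learn",
    "linear_associator_recall",
]


def _check_binary(X: np.ndarray) -> None:
    bad = np.argwhere((X != 0) & (X != 1))
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"Lernmatrix requires binary inputs; component ({r}, {c}) = {X[r, c]!r}"
        )


@dataclass
class LernmatrixMemory:
    """Learned Lernmatrix: an m x n matrix of integer multiples of eps."""

    weights: np.ndarray  # (m, n)
    eps: float

    @property
    def m(self) -> int:
        return self.weights.shape[0]

    @property
    def n(self) -> int:
        return self.weights.shape[1]

    def recall(self, x) -> np.ndarray:
        """Binary class vector flagging all maximal-score rows."""
        x = np.asarray(x, dtype=float)
        if x.shape != (self.n,):
            raise ValueError(f"pattern has shape {x.shape}, memory expects ({self.n},)")
        scores = self.weights @ x
        # scores are exact integer multiples of eps: exact comparison is safe
        return (scores == scores.max()).astype(int)


@dataclass
class LinearAssociatorMemory:
    """Linear Associator: the accumulated outer-product matrix (q x n)."""

    weights: np.ndarray

    def recall(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.shape != (self.weights.shape[1],):
            raise ValueError(
                f"pattern has shape {x.shape}, memory expects "
                f"({self.weights.shape[1]},)"
            )
        return self.weights @ x


def lernmatrix_learn(patterns, labels, m: int, eps: float = 1.0) -> LernmatrixMemory:
    """Learn a Lernmatrix from binary patterns and class indices.

    For each association (x, k), row k of the matrix receives +eps where the
    pattern component is 1 and -eps where it is 0.  The result is order
    independent (the updates are a sum).

    Parameters
    ----------
    patterns : sequence of binary vectors, each of length n
    labels : sequence of class indices in ``[0, m)``
    m : number of classes
    eps : positive learning constant (the rule only fixes its sign)
    """
    if len(patterns) == 0:
        raise ValueError("empty pattern list")
    X = np.atleast_2d(np.asarray(patterns, dtype=float))
    _check_binary(X)
    y = np.asarray(labels, dtype=int)
    if y.shape != (X.shape[0],):
        raise ValueError("patterns and labels differ in length")
    if y.min() < 0 or y.max() >= m:
        bad = int(np.argwhere((y < 0) | (y >= m))[0, 0])
        raise ValueError(f"label {y[bad]} at position {bad} outside [0, {m})")
    if eps <= 0:
        raise ValueError("eps must be positive")

    # Vectorized sum of the per-association updates: row k accumulates
    # eps * (2 x - 1) for every pattern x of class k.
    W = np.zeros((m, X.shape[1]))
    np.add.at(W, y, eps * (2.0 * X - 1.0))
    return LernmatrixMemory(weights=W, eps=float(eps))


def lernmatrix_recall(memory: LernmatrixMemory, x) -> np.ndarray:
    return memory.recall(x)


def linear_associator_learn(inputs, outputs) -> LinearAssociatorMemory:
    """M = sum over associations of  y^mu (x^mu)^T."""
    X = np.atleast_2d(np.asarray(inputs, dtype=float))
    Y = np.atleast_2d(np.asarray(outputs, dtype=float))
    if X.shape[0] != Y.shape[0] or X.shape[0] == 0:
        raise ValueError(
            f"need equally many inputs and outputs (>= 1); got {X.shape[0]} "
            f"and {Y.shape[0]}"
        )
    return LinearAssociatorMemory(weights=Y.T @ X)


def linear_associator_recall(memory: LinearAssociatorMemory, x) -> np.ndarray:
    return memory.recall(x)


class LernmatrixClassifier(ClassifierMixin, BaseEstimator):
    """Lernmatrix used as a single-label classifier over binary features.

    The raw recall is a binary class vector with 1s at all maximal rows;
    ``predict`` collapses it to the smallest flagged class index, the
    deterministic tie rule used throughout the package.  The full vector is
    available through :meth:`recall`.

    Parameters
    ----------
    eps : float, default=1.0
        Positive learning constant.  Predictions are invariant to its value.
    """

    def __init__(self, eps: float = 1.0):
        self.eps = eps

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, yi = np.unique(y, return_inverse=True)
        self.memory_ = lernmatrix_learn(X, yi, m=len(self.classes_), eps=self.eps)
        return self

    def recall(self, x) -> np.ndarray:
        check_is_fitted(self, "memory_")
        return self.memory_.recall(x)

    def predict(self, X):
        check_is_fitted(self, "memory_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        scores = X @ self.memory_.weights.T
        return self.classes_[np.argmax(scores, axis=1)]
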