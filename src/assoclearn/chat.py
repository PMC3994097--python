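"""CHA / CHAT: hybrid associative classifier with centroid translation.

CHA combines Linear-Associator learning (class one-hot output vectors of
size m) with Lernmatrix recall (arg-max over class scores).  CHAT adds a
translation of the coordinate axes: the origin is moved to the centroid
(mean vector) of the training inputs, and both training and query patterns
are expressed in the translated frame before learning/recall.  With class
one-hot outputs the learned m x n matrix has, as row k, the sum of the
translated training patterns of class k; the recall score of class k for a
query x is then the inner product of that row with the translated query.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .dataset import FundamentalSet
from .memories import linear_associator_learn

__all__ = [
    "compute_centroid",
    "translate",
    "argmax_set",
    "ChatClassifier",
    "chat_fit",
    "chat_predict",
]

#: relative tolerance for declaring two real-valued scores tied
SCORE_RTOL = 1e-9


def compute_centroid(X) -> np.ndarray:
    """Mean vector of a nonempty set of patterns (rows of X)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 0:
        raise ValueError("cannot compute the centroid of an empty set")
    return X.mean(axis=0)


def translate(X, centroid) -> np.ndarray:
    """Subtract the centroid from every row (or from a single vector)."""
    X = np.asarray(X, dtype=float)
    centroid = np.asarray(centroid, dtype=float)
    if X.shape[-1] != centroid.shape[0]:
        raise ValueError(
            f"dimension mismatch: patterns have {X.shape[-1]} components, "
            f"centroid has {centroid.shape[0]}"
        )
    return X - centroid


def argmax_set(scores: np.ndarray) -> np.ndarray:
    """Binary vector flagging every score within tolerance of the maximum.

    A score belongs to the arg-max set iff
    ``max(u) - u_i <= SCORE_RTOL * max(1, |max(u)|)`` - a sign-aware
    relative tolerance that treats exact symmetric ties as ties while
    keeping distinct floating-point scores apart.
    """
    scores = np.asarray(scores, dtype=float)
    top = scores.max()
    return (top - scores <= SCORE_RTOL * max(1.0, abs(top))).astype(int)


class ChatClassifier(ClassifierMixin, BaseEstimator):
    """Hybrid associative classifier (CHAT; CHA when translation is off).

    Parameters
    ----------
    translate_axes : bool, default=True
        Move the origin to the training centroid before learning and
        recall (CHAT).  ``False`` keeps the raw frame (CHA).

    Attributes
    ----------
    classes_ : ndarray of shape (m,)
        Labels seen during fit; predictions never leave this set.
    centroid_ : ndarray of shape (n,)
        Training mean vector (all-zero when ``translate_axes=False``).
    weights_ : ndarray of shape (m, n)
        Row k = sum of translated training patterns of class k.

    Ties in recall (several class scores within relative tolerance of the
    maximum) resolve to the smallest class index - deterministic, matching
    the masking-vector ordering of the one-hot variant.
    """

    def __init__(self, translate_axes: bool = True):
        self.translate_axes = translate_axes

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y disagree in length")
        self.classes_, yi = np.unique(y, return_inverse=True)
        m = len(self.classes_)
        self.centroid_ = (
            compute_centroid(X) if self.translate_axes else np.zeros(X.shape[1])
        )
        Xhat = translate(X, self.centroid_)
        onehot = np.eye(m)[yi]  # class one-hot outputs of size m
        self.weights_ = linear_associator_learn(Xhat, onehot).weights
        return self

    def decision_function(self, X):
        check_is_fitted(self, "weights_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return translate(X, self.centroid_) @ self.weights_.T

    def recall(self, x) -> np.ndarray:
        """Lernmatrix-style recall: binary class vector of all maxima."""
        return argmax_set(self.decision_function(np.atleast_2d(x))[0])

    def predict(self, X):
        scores = self.decision_function(X)
        # ties -> smallest class index: argmax returns the first maximum,
        # but apply the tolerance so near-exact symmetric ties behave alike
        idx = np.array([int(np.argmax(argmax_set(u))) for u in scores])
        return self.classes_[idx]


def chat_fit(data: FundamentalSet, translate_axes: bool = True) -> ChatClassifier:
    """Fit CHAT (or CHA) on a fundamental set."""
    clf = ChatClassifier(translate_axes=translate_axes)
    clf.fit(data.X, data.labels())
    return clf


def chat_predict(model: ChatClassifier, x):
    """Single-pattern prediction."""
    return model.predict(np.atleast_2d(x))[0]
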