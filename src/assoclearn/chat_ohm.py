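"""CHAT-OHM: CHAT with per-pattern one-hot outputs and majority voting.

Instead of coding outputs per class (size m), every training pattern mu
gets its own one-hot output vector of size p (a 1 at position mu).  The
Linear-Associator learning of {(x-hat^mu, e_mu)} then reduces to simply
stacking the translated training patterns as the rows of a p x n matrix.
Recall of a query therefore scores every *training pattern* (centered inner
product), not every class.  The class is recovered by majority voting:

1. recover:  flag all training patterns whose score is maximal (binary
   recovered vector y-tilde of length p);
2. count:    AND y-tilde with each class's masking vector c^k (the binary
   indicator of which training rows belong to class k) and sum - class k's
   vote count t^k;
3. predict:  the class with the most votes; ties -> smallest class index.

When the maximal score is unique this is exactly a nearest-neighbour rule
under the centered inner-product similarity; the voting machinery matters
only at exact ties, which symmetric data can produce.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .chat import argmax_set, compute_centroid, translate
from .dataset import FundamentalSet
from .memories import linear_associator_learn

__all__ = [
    "encode_one_hot",
    "build_masking_vectors",
    "count_votes",
    "ChatOhmClassifier",
    "chat_ohm_fit",
    "chat_ohm_predict",
]


def encode_one_hot(mu: int, p: int) -> np.ndarray:
    """Size-p output code of training pattern mu: Kronecker delta at mu."""
    if not 0 <= mu < p:
        raise IndexError(f"pattern index {mu} outside [0, {p})")
    code = np.zeros(p, dtype=int)
    code[mu] = 1
    return code


def build_masking_vectors(labels, m: int) -> np.ndarray:
    """Masking vectors c^k, stacked as an m x p binary matrix.

    Row k flags the training patterns of class k; the rows sum to the
    all-ones vector (each pattern belongs to exactly one class).
    """
    y = np.asarray(labels, dtype=int)
    if y.size and (y.min() < 0 or y.max() >= m):
        bad = int(np.argwhere((y < 0) | (y >= m))[0, 0])
        raise ValueError(f"label {y[bad]} at position {bad} outside [0, {m})")
    return (np.arange(m)[:, None] == y[None, :]).astype(int)


def count_votes(recovered, masks) -> np.ndarray:
    """Vote counts per class: sum of (recovered AND mask_k) for each k."""
    recovered = np.asarray(recovered, dtype=int)
    masks = np.atleast_2d(np.asarray(masks, dtype=int))
    if masks.shape[1] != recovered.shape[0]:
        raise ValueError(
            f"recovered vector has length {recovered.shape[0]}, masks expect "
            f"{masks.shape[1]}"
        )
    return (masks & recovered).sum(axis=1)


class ChatOhmClassifier(ClassifierMixin, BaseEstimator):
    """CHAT with one-hot output coding and majority voting (CHAT-OHM).

    Attributes
    ----------
    classes_ : ndarray of shape (m,)
    centroid_ : ndarray of shape (n,)
        Training mean vector.
    weights_ : ndarray of shape (p, n)
        Row mu = translated training pattern x-hat^mu.  Equal, by
        construction, to Linear-Associator learning with the size-p
        one-hot outputs (asserted at fit time on small sets).
    masks_ : ndarray of shape (m, p)
        Masking vectors; rows partition the training patterns by class.
    """

    # materializing the outer-product sum is O(p^2 n); assert the identity
    # only where it is cheap
    _ASSERT_LIMIT = 200

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y disagree in length")
        self.classes_, yi = np.unique(y, return_inverse=True)
        p = X.shape[0]
        self.centroid_ = compute_centroid(X)
        self.weights_ = translate(X, self.centroid_)
        if p <= self._ASSERT_LIMIT:
            accumulated = linear_associator_learn(
                self.weights_, np.eye(p)
            ).weights
            assert np.array_equal(accumulated, self.weights_)
        self.masks_ = build_masking_vectors(yi, len(self.classes_))
        return self

    def scores(self, x) -> np.ndarray:
        """Centered inner products of the query with every training row."""
        check_is_fitted(self, "weights_")
        x = np.asarray(x, dtype=float)
        return self.weights_ @ translate(x, self.centroid_)

    def recover(self, x) -> np.ndarray:
        """Binary recovered vector y-tilde: 1 at every maximal score."""
        return argmax_set(self.scores(x))

    def vote_counts(self, x) -> np.ndarray:
        return count_votes(self.recover(x), self.masks_)

    def predict(self, X):
        check_is_fitted(self, "weights_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        # np.argmax takes the first maximum -> smallest class index on ties
        idx = [int(np.argmax(self.vote_counts(x))) for x in X]
        return self.classes_[idx]


def chat_ohm_fit(data: FundamentalSet) -> ChatOhmClassifier:
    clf = ChatOhmClassifier()
    clf.fit(data.X, data.labels())
    return clf


def chat_ohm_predict(model: ChatOhmClassifier, x):
    return model.predict(np.atleast_2d(x))[0]
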