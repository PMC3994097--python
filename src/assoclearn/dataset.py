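"""Labeled pattern sets.

The training material of an associative classifier is a *fundamental set*:
p input patterns x^1 .. x^p (each a real vector of length n) together with
an integer class label per pattern, drawn from m classes.  Original labels
(strings, arbitrary integers) are mapped to contiguous 0-based indices; the
original labels are kept so predictions can be reported in the user's
vocabulary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FundamentalSet"]


@dataclass
class FundamentalSet:
    """A labeled set of real-valued patterns.

    Parameters
    ----------
    X : ndarray of shape (p, n)
        One row per input pattern.
    y : ndarray of shape (p,)
        0-based class index of each pattern, in ``[0, n_classes)``.
    classes : ndarray of shape (m,)
        Original label for each class index.  Defaults to ``0..m-1``.
    """

    X: np.ndarray
    y: np.ndarray
    classes: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2:
            raise ValueError(f"X must be 2-D, got shape {self.X.shape}")
        if self.X.shape[0] < 1:
            raise ValueError("fundamental set must contain at least one pattern")
        if self.y.shape != (self.X.shape[0],):
            raise ValueError(
                f"y has shape {self.y.shape}, expected ({self.X.shape[0]},)"
            )
        if self.classes is None:
            self.classes = np.arange(int(self.y.max()) + 1 if self.y.size else 0)
        else:
            self.classes = np.asarray(self.classes)
        if self.y.min(initial=0) < 0 or (
            self.y.size and self.y.max() >= len(self.classes)
        ):
            raise ValueError("class indices out of range [0, m)")

    @property
    def p(self) -> int:
        """Number of patterns."""
        return self.X.shape[0]

    @property
    def n(self) -> int:
        """Number of features."""
        return self.X.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def labels(self) -> np.ndarray:
        """Original labels of every pattern (classes[y])."""
        return self.classes[self.y]

    @classmethod
    def from_labels(cls, X, labels) -> "FundamentalSet":
        """Build a set from raw labels, deriving the index map.

        Classes are ordered by first-seen value sorted ascending (numpy
        ``unique`` order), which keeps the index map deterministic.
        """
        labels = np.asarray(labels)
        classes, y = np.unique(labels, return_inverse=True)
        return cls(X=np.asarray(X, dtype=float), y=y, classes=classes)

    def subset(self, idx) -> "FundamentalSet":
        """Row subset keeping the full class map (folds may miss a class)."""
        idx = np.asarray(idx)
        return FundamentalSet(X=self.X[idx], y=self.y[idx], classes=self.classes)
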