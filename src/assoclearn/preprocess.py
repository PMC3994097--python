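"""Data conditioning: population z-score, Wilson editing, imputation.

Three operations condition a tabular dataset before classification:

* **population z-score** - per attribute, subtract the mean and divide by
  the population (divide-by-N) standard deviation;
* **Wilson's edition** (edited nearest neighbour, ENN) - remove every
  pattern whose class disagrees with the plurality class of its k (=3)
  nearest neighbours under Euclidean distance, judged in one simultaneous
  pass against the original set;
* **missing values** - either delete the rows that carry a missing marker,
  or impute class-conditionally: the class mean for continuous attributes,
  the class mode for categorical ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .dataset import FundamentalSet

__all__ = [
    "AttributeSchema",
    "EditResult",
    "PopulationZScore",
    "zscore_fit",
    "zscore_apply",
    "wilson_edit",
    "impute_class_conditional",
    "drop_missing_rows",
]


@dataclass
class AttributeSchema:
    """Per-attribute kinds and missing-value convention of a dataset.

    ``kinds[j]`` is ``"continuous"`` or ``"categorical"`` for feature j
    (class column excluded).  ``missing_marker`` is the token that denotes
    a missing cell in the source file (UCI convention: ``"?"``).
    """

    kinds: list[str]
    class_column: int | str = -1
    missing_marker: str = "?"

    def __post_init__(self) -> None:
        bad = [k for k in self.kinds if k not in ("continuous", "categorical")]
        if bad:
            raise ValueError(f"unknown attribute kinds: {bad}")

    @classmethod
    def all_continuous(cls, n: int) -> "AttributeSchema":
        return cls(kinds=["continuous"] * n)


class PopulationZScore(TransformerMixin, BaseEstimator):
    """Per-attribute standardization with the population (1/N) deviation.

    Constant attributes (sigma = 0) map to all-zeros rather than raising:
    they carry no information and real clinical tables do contain them.

    Attributes
    ----------
    mean_ : ndarray of shape (n,)
    scale_ : ndarray of shape (n,)
        Population standard deviation per attribute (ddof=0).
    """

    def fit(self, X, y=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] == 0:
            raise ValueError("cannot fit normalization statistics on no rows")
        self.mean_ = X.mean(axis=0)
        scale = X.std(axis=0, ddof=0)
        # a constant column stored in non-exact binary (e.g. 3.14) yields a
        # ~1e-16 std from summation error; clamp relative to the mean's
        # magnitude so such columns behave as truly constant
        tol = 1e-12 * np.maximum(1.0, np.abs(self.mean_))
        self.scale_ = np.where(scale <= tol, 0.0, scale)
        return self

    def transform(self, X):
        check_is_fitted(self, "mean_")
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != self.mean_.shape[0]:
            raise ValueError(
                f"X has {X.shape[-1]} attributes, statistics were fitted on "
                f"{self.mean_.shape[0]}"
            )
        denom = np.where(self.scale_ > 0, self.scale_, 1.0)
        Z = (X - self.mean_) / denom
        if np.any(self.scale_ == 0):
            Z = np.where(self.scale_ == 0, 0.0, Z)
        return Z

    def inverse_transform(self, Z):
        check_is_fitted(self, "mean_")
        Z = np.asarray(Z, dtype=float)
        return Z * np.where(self.scale_ > 0, self.scale_, 0.0) + self.mean_


def zscore_fit(X) -> PopulationZScore:
    """Fit per-column mean and population standard deviation."""
    return PopulationZScore().fit(X)


def zscore_apply(X, stats: PopulationZScore) -> np.ndarray:
    return stats.transform(X)


@dataclass
class EditResult:
    """Outcome of a Wilson-editing pass.

    ``kept_indices`` and ``removed_indices`` partition the original rows;
    ``removed_per_class`` counts removals by class index.
    """

    kept_indices: np.ndarray
    removed_indices: np.ndarray
    removed_per_class: dict[int, int] = field(default_factory=dict)


def wilson_edit(data: FundamentalSet, k: int = 3) -> EditResult:
    """Wilson's edition: single-pass ENN under Euclidean distance.

    Every row is judged against the *original* set (classic ENN); all
    failures are removed together, so the result does not depend on a
    removal order.  Distance ties at the k-th neighbour prefer the lower
    row index; a plurality tie among neighbour labels (impossible for
    k=3 with two classes) keeps the row.
    """
    p = data.p
    if p <= k:
        raise ValueError(f"need more than k={k} patterns, got {p}")
    if not np.isfinite(data.X).all():
        raise ValueError("Wilson editing requires finite numeric features")

    D = cdist(data.X, data.X)
    np.fill_diagonal(D, np.inf)  # a row is never its own neighbour
    # stable sort on distance == tie-break by lower row index
    order = np.argsort(D, axis=1, kind="stable")[:, :k]
    removed = []
    for i in range(p):
        votes = np.bincount(data.y[order[i]], minlength=data.n_classes)
        top = votes.max()
        winners = np.flatnonzero(votes == top)
        if len(winners) == 1 and winners[0] != data.y[i]:
            removed.append(i)
    removed = np.asarray(removed, dtype=int)
    kept = np.setdiff1d(np.arange(p), removed)
    per_class = {
        int(c): int((data.y[removed] == c).sum()) for c in np.unique(data.y[removed])
    }
    return EditResult(
        kept_indices=kept, removed_indices=removed, removed_per_class=per_class
    )


def _column_mode(values: np.ndarray):
    """Most frequent value; ties resolve to the smallest value."""
    uniq, counts = np.unique(values, return_counts=True)
    return uniq[np.argmax(counts)]


def impute_class_conditional(
    X, labels, schema: AttributeSchema, missing_mask=None
) -> np.ndarray:
    """Fill missing cells with the class mean (continuous) or mode (categorical).

    Parameters
    ----------
    X : (p, n) float array; missing cells may be NaN
    labels : per-row class indices
    schema : attribute kinds
    missing_mask : optional boolean (p, n) mask; defaults to ``isnan(X)``

    Observed cells are never altered.  A (class, attribute) pair with no
    observed value at all is an error naming the pair.
    """
    X = np.array(X, dtype=float)
    y = np.asarray(labels)
    mask = np.isnan(X) if missing_mask is None else np.asarray(missing_mask, bool)
    if len(schema.kinds) != X.shape[1]:
        raise ValueError(
            f"schema covers {len(schema.kinds)} attributes, X has {X.shape[1]}"
        )
    for c in np.unique(y):
        rows = y == c
        for j in range(X.shape[1]):
            cell = rows & mask[:, j]
            if not cell.any():
                continue
            observed = X[rows & ~mask[:, j], j]
            if observed.size == 0:
                raise ValueError(
                    f"class {c}, attribute {j}: every value missing, "
                    "nothing to impute from"
                )
            if schema.kinds[j] == "continuous":
                X[cell, j] = observed.mean()
            else:
                X[cell, j] = _column_mode(observed)
    return X


def drop_missing_rows(X, labels, missing_mask=None):
    """Remove rows containing any missing cell; survivor order preserved.

    Returns ``(X', labels', dropped_count)``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    mask = np.isnan(X) if missing_mask is None else np.asarray(missing_mask, bool)
    keep = ~mask.any(axis=1)
    dropped = int((~keep).sum())
    if not keep.any():
        warnings.warn("all rows contained missing values; result is empty")
    return X[keep], y[keep], dropped
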