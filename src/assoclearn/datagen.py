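"""Synthetic datasets exercising every pipeline path without downloads.

Generators are pure functions of their spec plus seed: class-wise isotropic
Gaussian blobs (separable or overlapping), exactly symmetric tie fixtures
for the majority-voting machinery, and corruption (planted missing cells
and label-flipped boundary "outliers" placed at foreign class means, with
ground truth returned so tests never re-derive it).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import FundamentalSet

__all__ = [
    "BlobSpec",
    "CorruptionSpec",
    "make_blobs",
    "make_tie_fixture",
    "corrupt",
]


@dataclass
class BlobSpec:
    """Class-wise isotropic Gaussian blobs.

    ``means`` is an (m, n) array-like of class centers; ``sigma`` the
    shared isotropic standard deviation; ``counts`` the per-class sizes.
    """

    means: list
    sigma: float = 1.0
    counts: list = field(default_factory=lambda: [50, 50])
    seed: int = 0

    def __post_init__(self) -> None:
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        self.counts = list(self.counts)
        if len(self.counts) != self.means.shape[0]:
            raise ValueError("one count per class mean required")
        if any(c < 1 for c in self.counts):
            raise ValueError("per-class counts must be >= 1")


@dataclass
class CorruptionSpec:
    """How to damage a clean dataset.

    ``missing_rows`` rows receive one NaN cell each; ``flipped_outliers``
    rows are *added*, drawn at a foreign class mean but labeled with the
    original class - the classic boundary outlier Wilson editing targets.
    """

    missing_rows: int = 0
    flipped_outliers: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.missing_rows < 0 or self.flipped_outliers < 0:
            raise ValueError("corruption counts must be >= 0")


def make_blobs(spec: BlobSpec) -> FundamentalSet:
    """Draw class-wise isotropic Gaussian samples; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    rows, labels = [], []
    for k, (mean, count) in enumerate(zip(spec.means, spec.counts)):
        rows.append(mean + spec.sigma * rng.standard_normal((count, len(mean))))
        labels.extend([k] * count)
    return FundamentalSet(X=np.vstack(rows), y=np.asarray(labels))


def make_tie_fixture(n_classes: int = 2) -> tuple[FundamentalSet, np.ndarray]:
    """A symmetric set plus a query whose centered scores tie exactly.

    Two classes: {(1,0) class 0, (0,1) class 1} with query (0.5, 0.5) - the
    translated query is the zero vector, so every training score is 0.
    More classes: one pattern per class at the vertices of a regular
    simplex arrangement (unit vectors), query at the centroid.
    """
    X = np.eye(n_classes)
    y = np.arange(n_classes)
    query = np.full(n_classes, 1.0 / n_classes)
    return FundamentalSet(X=X, y=y), query


def corrupt(
    data: FundamentalSet, spec: CorruptionSpec
) -> tuple[FundamentalSet, np.ndarray, np.ndarray]:
    """Plant missing cells and label-flipped outlier rows.

    Returns ``(corrupted, missing_row_indices, outlier_row_indices)``; the
    outlier indices refer to rows appended to the end of the set, each
    placed exactly at a foreign class's empirical mean so its nearest
    neighbours all carry the foreign label.
    """
    if spec.missing_rows > data.p:
        raise ValueError(
            f"cannot plant {spec.missing_rows} missing rows in {data.p} rows"
        )
    rng = np.random.default_rng(spec.seed)
    X = data.X.copy()
    y = data.y.copy()

    missing_idx = rng.choice(data.p, size=spec.missing_rows, replace=False)
    for i in missing_idx:
        X[i, rng.integers(data.n)] = np.nan

    outlier_idx = np.arange(data.p, data.p + spec.flipped_outliers)
    if spec.flipped_outliers:
        # Each flip copies the coordinates of a distinct genuine row of a
        # foreign class ("host").  Under ENN with lower-index distance
        # tie-breaking, the host (distance 0) and, for any co-ranked
        # planted row, that row's own lower-indexed host always precede
        # planted rows in the neighbour list, so at least 2 of 3
        # neighbours carry the foreign label and removal is guaranteed.
        extra_X, extra_y = [], []
        used: set[int] = set()
        for _ in range(spec.flipped_outliers):
            own = int(rng.integers(data.n_classes))
            foreign = int(
                (own + 1 + rng.integers(data.n_classes - 1)) % data.n_classes
            )
            candidates = [
                i for i in np.flatnonzero(data.y == foreign) if i not in used
            ]
            if not candidates:
                raise ValueError(
                    "not enough distinct foreign rows to host planted outliers"
                )
            host = int(candidates[rng.integers(len(candidates))])
            used.add(host)
            extra_X.append(data.X[host])
            extra_y.append(own)
        X = np.vstack([X, extra_X])
        y = np.concatenate([y, extra_y])

    return (
        FundamentalSet(X=X, y=y, classes=data.classes),
        np.sort(missing_idx),
        outlier_idx,
    )
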