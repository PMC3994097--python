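"""Success-rate computation and repeated stratified k-fold cross-validation.

The validation protocol: shuffle the patterns, deal each class round-robin
into k (=10) folds so per-class fold sizes differ by at most one, train on
k-1 folds and score classification accuracy (percentage of correct
predictions) on the held-out fold; repeat the whole procedure r (=10) times
with fresh shuffles and average all r x k success rates.

A single master seed drives the repeats: repeat i uses child i of
``numpy.random.SeedSequence(seed)``, so any individual repeat is
reproducible in isolation and the full run is bit-deterministic.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone

from .dataset import FundamentalSet
from .preprocess import (
    AttributeSchema,
    PopulationZScore,
    drop_missing_rows,
    impute_class_conditional,
    wilson_edit,
)

__all__ = [
    "CVConfig",
    "CVResult",
    "accuracy",
    "stratified_folds",
    "cross_validate",
    "apply_stages",
    "STAGES",
]

#: recognised preprocessing stage names, in the vocabulary of the pipeline
STAGES = ("drop_missing", "impute", "normalize", "wilson_edit")


@dataclass
class CVConfig:
    """Protocol parameters: k folds, r repeats, master seed, shuffling."""

    folds: int = 10
    repeats: int = 10
    seed: int = 0
    shuffle: bool = True

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("need at least 2 folds")
        if self.repeats < 1:
            raise ValueError("need at least 1 repeat")


@dataclass
class CVResult:
    """All per-repeat per-fold success rates (percentages) and their means."""

    rates: np.ndarray  # (repeats, folds)
    mean: float = field(init=False)
    per_repeat_means: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        self.per_repeat_means = self.rates.mean(axis=1)
        self.mean = float(self.rates.mean())

    def to_csv(self, path) -> None:
        """Long-format table: repeat, fold, accuracy."""
        with open(path, "w") as fh:
            fh.write("repeat,fold,accuracy\n")
            for r in range(self.rates.shape[0]):
                for f in range(self.rates.shape[1]):
                    fh.write(f"{r},{f},{self.rates[r, f]!r}\n")

    def summary(self) -> dict:
        return {
            "mean_accuracy": self.mean,
            "per_repeat_means": self.per_repeat_means.tolist(),
            "repeats": int(self.rates.shape[0]),
            "folds": int(self.rates.shape[1]),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


def accuracy(predicted, actual) -> float:
    """Success rate as a percentage: 100 * (#matches / #total)."""
    predicted = np.asarray(predicted)
    actual = np.asarray(actual)
    if predicted.shape != actual.shape:
        raise ValueError(
            f"length mismatch: {predicted.shape} predictions vs "
            f"{actual.shape} references"
        )
    if predicted.size == 0:
        raise ValueError("cannot score an empty prediction list")
    return 100.0 * float(np.mean(predicted == actual))


def stratified_folds(labels, folds: int, rng: np.random.Generator,
                     shuffle: bool = True) -> np.ndarray:
    """Assign each row a fold index, stratifying by class.

    Within each class the (shuffled) instances are dealt round-robin to the
    folds, so per-class per-fold counts differ by at most one and remainder
    instances land in the lowest-indexed folds.
    """
    y = np.asarray(labels)
    if y.shape[0] < folds:
        raise ValueError(f"{y.shape[0]} instances cannot fill {folds} folds")
    smallest = min(np.bincount(np.unique(y, return_inverse=True)[1]))
    if smallest < folds:
        warnings.warn(
            f"smallest class has {smallest} instances < {folds} folds; "
            "stratification degrades (some folds miss the class)"
        )
    assignment = np.empty(y.shape[0], dtype=int)
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        if shuffle:
            idx = rng.permutation(idx)
        assignment[idx] = np.arange(idx.size) % folds
    return assignment


def apply_stages(
    data: FundamentalSet,
    stages: list[str],
    schema: AttributeSchema | None = None,
    missing_mask: np.ndarray | None = None,
    skip: tuple[str, ...] = (),
) -> FundamentalSet:
    """Run preprocessing stages, in order, on a whole dataset.

    ``skip`` names stages to leave out (used by per-fold mode, which
    applies them inside the folds instead).
    """
    X, y = data.X, data.y
    mask = missing_mask
    for stage in stages:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
        if stage in skip:
            continue
        if stage == "drop_missing":
            X, y, _ = drop_missing_rows(X, y, mask)
            mask = None
        elif stage == "impute":
            sch = schema or AttributeSchema.all_continuous(X.shape[1])
            X = impute_class_conditional(X, y, sch, mask)
            mask = None
        elif stage == "normalize":
            X = PopulationZScore().fit(X).transform(X)
        elif stage == "wilson_edit":
            result = wilson_edit(FundamentalSet(X, y, data.classes))
            X, y = X[result.kept_indices], y[result.kept_indices]
    return FundamentalSet(X=X, y=y, classes=data.classes)


def cross_validate(
    data: FundamentalSet,
    estimator,
    config: CVConfig | None = None,
    stages: list[str] | None = None,
    per_fold_prep: bool = False,
    schema: AttributeSchema | None = None,
    missing_mask: np.ndarray | None = None,
) -> CVResult:
    """Repeated stratified k-fold CV of a classifier on a fundamental set.

    Parameters
    ----------
    data : the full labeled dataset
    estimator : an unfitted sklearn-style classifier; cloned per fold
    config : folds/repeats/seed; defaults to 10 x 10
    stages : ordered preprocessing stages from ``STAGES``
    per_fold_prep : when True, ``normalize`` (statistics from training
        rows only) and ``wilson_edit`` (training rows only) run inside each
        fold instead of once up front.  Missing-value stages always run up
        front: class-conditional imputation consumes the row's own label
        and has no leakage-free analogue for unlabeled queries.
    """
    config = config or CVConfig()
    stages = stages or []
    per_fold = tuple(
        s for s in stages if per_fold_prep and s in ("normalize", "wilson_edit")
    )
    prepped = apply_stages(data, stages, schema, missing_mask, skip=per_fold)

    children = np.random.SeedSequence(config.seed).spawn(config.repeats)
    rates = np.empty((config.repeats, config.folds))
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        assignment = stratified_folds(
            prepped.y, config.folds, rng, shuffle=config.shuffle
        )
        for f in range(config.folds):
            test = assignment == f
            train = ~test
            X_tr, y_tr = prepped.X[train], prepped.y[train]
            X_te, y_te = prepped.X[test], prepped.y[test]
            if "normalize" in per_fold:
                stats = PopulationZScore().fit(X_tr)
                X_tr, X_te = stats.transform(X_tr), stats.transform(X_te)
            if "wilson_edit" in per_fold:
                res = wilson_edit(FundamentalSet(X_tr, y_tr, prepped.classes))
                X_tr, y_tr = X_tr[res.kept_indices], y_tr[res.kept_indices]
            clf = clone(estimator)
            try:
                clf.fit(X_tr, y_tr)
                pred = clf.predict(X_te)
            except Exception as exc:  # re-raise with fold context
                raise RuntimeError(
                    f"classifier failed on repeat {r}, fold {f}: {exc}"
                ) from exc
            rates[r, f] = accuracy(pred, y_te)
    return CVResult(rates=rates)
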