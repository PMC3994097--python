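"""Dataset readers, schema configuration and model serialization.

CSV is the primary on-disk format (UCI dialect: comma-separated, optional
header, ``?`` for missing cells, class column configurable since the UCI
files disagree about its position).  ARFF is supported read-only through
``scipy.io.arff``.  Categorical columns are integer-coded against a stored
per-column dictionary; missing cells are *flagged*, never silently zeroed
or imputed - resolution of missingness belongs to the preprocessing stage.

Models serialize to a versioned JSON document.  Python's float repr is
shortest-round-trip, so a save/load cycle reproduces every weight - and
therefore every prediction - bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import arff as scipy_arff

from .chat import ChatClassifier
from .chat_ohm import ChatOhmClassifier
from .dataset import FundamentalSet
from .memories import LernmatrixClassifier
from .preprocess import AttributeSchema, PopulationZScore

__all__ = [
    "DatasetConfig",
    "read_dataset",
    "save_model",
    "load_model",
    "LoadedModel",
    "FORMAT_VERSION",
]

FORMAT_VERSION = 1


@dataclass
class DatasetConfig:
    """How to parse a tabular dataset file.

    ``class_column`` may be a header name or a 0-based index (negative
    indices count from the right; the default -1 is the UCI "class last"
    convention).  ``kinds`` optionally forces per-column kinds keyed by
    column name/index; unlisted columns are inferred (numeric ->
    continuous, otherwise categorical).
    """

    path: str
    format: str = "csv"
    class_column: int | str = -1
    kinds: dict = field(default_factory=dict)
    missing_marker: str = "?"
    header: bool = False

    @classmethod
    def from_file(cls, path) -> "DatasetConfig":
        """Load a config from a JSON or YAML file."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a JSON superset
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} does not hold a mapping")
        return cls(**data)


def _parse_frame(df: pd.DataFrame, config: DatasetConfig):
    """Common path for CSV and ARFF once a raw DataFrame exists."""
    if df.shape[0] == 0:
        raise ValueError(f"{config.path}: empty dataset")
    if isinstance(config.class_column, str):
        if config.class_column not in df.columns:
            raise ValueError(
                f"class column {config.class_column!r} not among {list(df.columns)}"
            )
        class_col = config.class_column
    else:
        class_col = df.columns[config.class_column]
    labels = df[class_col].to_numpy()
    feats = df.drop(columns=[class_col])

    kinds: list[str] = []
    columns = []
    missing = np.zeros(feats.shape, dtype=bool)
    encodings: dict = {}
    for j, name in enumerate(feats.columns):
        col = feats[name]
        is_missing = col.isna().to_numpy()
        forced = config.kinds.get(name, config.kinds.get(str(name), config.kinds.get(j)))
        numeric = pd.to_numeric(col, errors="coerce")
        parse_failed = numeric.isna().to_numpy() & ~is_missing
        if forced == "continuous" and parse_failed.any():
            r = int(np.flatnonzero(parse_failed)[0])
            raise ValueError(
                f"{config.path}: cell (row {r}, column {name!r}) = "
                f"{col.iloc[r]!r} is not numeric"
            )
        if forced == "categorical" or (forced is None and parse_failed.any()):
            kinds.append("categorical")
            observed = sorted(str(v) for v in col[~is_missing].unique())
            codes = {v: i for i, v in enumerate(observed)}
            encodings[str(name)] = observed
            values = np.array(
                [np.nan if m else codes[str(v)] for v, m in zip(col, is_missing)],
                dtype=float,
            )
        else:
            kinds.append("continuous")
            values = numeric.to_numpy(dtype=float)
        columns.append(values)
        missing[:, j] = is_missing

    X = np.column_stack(columns) if columns else np.empty((len(feats), 0))
    data = FundamentalSet.from_labels(X, labels)
    schema = AttributeSchema(
        kinds=kinds,
        class_column=config.class_column,
        missing_marker=config.missing_marker,
    )
    schema.encodings = encodings  # per-column category dictionaries
    return data, schema, missing


def read_dataset(config: DatasetConfig):
    """Parse a dataset file into ``(FundamentalSet, schema, missing_mask)``."""
    path = Path(config.path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if config.format == "csv":
        df = pd.read_csv(
            path,
            header=0 if config.header else None,
            na_values=[config.missing_marker],
            keep_default_na=False,
            skipinitialspace=True,
        )
    elif config.format == "arff":
        raw, _meta = scipy_arff.loadarff(str(path))
        df = pd.DataFrame(raw)
        for name in df.columns:  # nominal attributes arrive as bytes
            if df[name].dtype == object:
                decoded = df[name].str.decode("utf-8")
                df[name] = decoded.mask(decoded == config.missing_marker)
    else:
        raise ValueError(f"unknown dataset format {config.format!r}")
    return _parse_frame(df, config)


_FAMILIES = {
    "lernmatrix": LernmatrixClassifier,
    "chat": ChatClassifier,
    "chat-ohm": ChatOhmClassifier,
}


def _family_of(model) -> str:
    for name, cls in _FAMILIES.items():
        if type(model) is cls:
            return name
    raise TypeError(f"cannot serialize model of type {type(model).__name__}")


def save_model(model, path, zscore: PopulationZScore | None = None) -> None:
    """Write a fitted classifier (plus optional normalization stats) to JSON."""
    family = _family_of(model)
    doc: dict = {
        "format_version": FORMAT_VERSION,
        "family": family,
        "classes": np.asarray(model.classes_).tolist(),
    }
    if family == "lernmatrix":
        doc["weights"] = model.memory_.weights.tolist()
        doc["eps"] = model.memory_.eps
    elif family == "chat":
        doc["centroid"] = model.centroid_.tolist()
        doc["weights"] = model.weights_.tolist()
        doc["translate_axes"] = bool(model.translate_axes)
    else:  # chat-ohm
        doc["centroid"] = model.centroid_.tolist()
        doc["weights"] = model.weights_.tolist()
        doc["masks"] = model.masks_.tolist()
    if zscore is not None:
        doc["zscore"] = {
            "mean": zscore.mean_.tolist(),
            "scale": zscore.scale_.tolist(),
        }
    Path(path).write_text(json.dumps(doc))


@dataclass
class LoadedModel:
    """A deserialized classifier with its stored preprocessing statistics.

    ``predict`` re-applies the stored z-score (when present) before the
    classifier, so a model trained on normalized data normalizes its
    queries the same way.
    """

    family: str
    classifier: object
    zscore: PopulationZScore | None = None

    def predict(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.zscore is not None:
            X = self.zscore.transform(X)
        return self.classifier.predict(X)


def load_model(path) -> LoadedModel:
    """Read a model file; raises on version mismatch or corruption."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: corrupted or truncated model file") from exc
    if not isinstance(doc, dict) or "format_version" not in doc:
        raise ValueError(f"{path}: not an assoclearn model file")
    if doc["format_version"] != FORMAT_VERSION:
        raise ValueError(
            f"{path}: format version {doc['format_version']} unsupported "
            f"(expected {FORMAT_VERSION})"
        )
    family = doc["family"]
    classes = np.asarray(doc["classes"])
    if family == "lernmatrix":
        from .memories import LernmatrixMemory

        clf = LernmatrixClassifier(eps=doc["eps"])
        clf.classes_ = classes
        clf.memory_ = LernmatrixMemory(
            weights=np.asarray(doc["weights"], dtype=float), eps=doc["eps"]
        )
    elif family == "chat":
        clf = ChatClassifier(translate_axes=doc["translate_axes"])
        clf.classes_ = classes
        clf.centroid_ = np.asarray(doc["centroid"], dtype=float)
        clf.weights_ = np.asarray(doc["weights"], dtype=float)
    elif family == "chat-ohm":
        clf = ChatOhmClassifier()
        clf.classes_ = classes
        clf.centroid_ = np.asarray(doc["centroid"], dtype=float)
        clf.weights_ = np.asarray(doc["weights"], dtype=float)
        clf.masks_ = np.asarray(doc["masks"], dtype=int)
    else:
        raise ValueError(f"{path}: unknown model family {family!r}")
    zscore = None
    if "zscore" in doc:
        zscore = PopulationZScore()
        zscore.mean_ = np.asarray(doc["zscore"]["mean"], dtype=float)
        zscore.scale_ = np.asarray(doc["zscore"]["scale"], dtype=float)
    return LoadedModel(family=family, classifier=clf, zscore=zscore)
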