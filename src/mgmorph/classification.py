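"""Random-forest cell / non-cell object filter.

The training protocol mirrors the manual-curation design: from a pool of
manually labeled objects, a balanced training set (by default 277 cells and
277 non-cellular objects) is sampled without replacement; everything else
becomes the validation set, on which overall accuracy is reported.  The
forest is the classical algorithm — 1,500 trees, bootstrap-resampled rows,
3 candidate features per split (mtry), unlimited depth, majority vote — via
scikit-learn.  Tie votes resolve to non-cell (conservative screening).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from ._rng import stage_rng
from .config import PipelineConfig
from .errors import SamplingError, SchemaError
from .io import FEATURE_PANEL

log = logging.getLogger("mgmorph.classification")

__all__ = ["LabeledObjectSet", "ForestModel", "make_balanced_split",
           "train_forest", "classify_objects", "save_model", "load_model"]

_LABELS = ("cell", "noncell")


@dataclass(frozen=True)
class LabeledObjectSet:
    """Feature table + labels with a train / validation split assignment."""

    features: pd.DataFrame  # includes FEATURE_PANEL columns
    labels: np.ndarray      # "cell" / "noncell" per row
    split: np.ndarray       # "train" / "validation" per row

    def __post_init__(self) -> None:
        n = len(self.features)
        if len(self.labels) != n or len(self.split) != n:
            raise SchemaError("features, labels, and split must have equal length")
        bad = set(np.unique(self.labels)) - set(_LABELS)
        if bad:
            raise SchemaError(f"unknown labels {sorted(bad)}; expected {_LABELS}")

    def subset(self, which: str) -> tuple[pd.DataFrame, np.ndarray]:
        idx = self.split == which
        return self.features.loc[idx], self.labels[idx]


@dataclass(frozen=True)
class ForestModel:
    """Fitted ensemble plus its provenance (config echo, seed, accuracy)."""

    estimator: RandomForestClassifier
    n_trees: int
    features_per_split: int
    feature_names: tuple[str, ...]
    training_seed: int
    validation_accuracy: float


def make_balanced_split(
    features: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    n_per_class: int,
    seed: int = 0,
) -> LabeledObjectSet:
    """Sample exactly ``n_per_class`` objects per class (without replacement)
    into the training split; all remaining labeled objects become validation.
    """
    labels = np.asarray(labels, dtype=object)
    split = np.full(len(features), "validation", dtype=object)
    rng = stage_rng(seed, "balanced-split")
    for cls in _LABELS:
        members = np.flatnonzero(labels == cls)
        if len(members) < n_per_class:
            raise SamplingError(
                f"class {cls!r} has {len(members)} members; {n_per_class} requested"
            )
        chosen = rng.choice(members, size=n_per_class, replace=False)
        split[chosen] = "train"
    return LabeledObjectSet(features=features.reset_index(drop=True),
                            labels=labels, split=split)


def _panel_matrix(features: pd.DataFrame, names: tuple[str, ...]) -> np.ndarray:
    missing = [c for c in names if c not in features.columns]
    if missing:
        raise SchemaError(f"feature table missing columns {missing}")
    X = features[list(names)].to_numpy(dtype=np.float64)
    if np.isnan(X).any():
        raise SchemaError("feature panel contains missing values")
    return X


def train_forest(labeled: LabeledObjectSet, cfg: PipelineConfig) -> ForestModel:
    """Fit the forest on the training split; store accuracy on validation.

    Deterministic under the config seed (a namespaced stream drives both the
    row bootstrap and per-split feature subsampling).
    """
    X_train, y_train = labeled.subset("train")
    if len(X_train) == 0:
        raise SamplingError("training split is empty")
    if len(set(y_train)) < 2:
        raise SamplingError("training split must contain both classes")
    names = tuple(FEATURE_PANEL)
    Xt = _panel_matrix(X_train, names)
    sk_seed = int(stage_rng(cfg.seed, "forest-train").integers(0, 2**31 - 1))
    est = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        max_features=cfg.features_per_split,
        bootstrap=True,
        random_state=sk_seed,
        n_jobs=1,
    )
    est.fit(Xt, y_train)

    X_val, y_val = labeled.subset("validation")
    # accuracy on held-out objects only; disjointness is structural (split array)
    if len(X_val):
        pred = _predict(est, _panel_matrix(X_val, names))
        acc = float(np.mean(pred == y_val))
    else:
        acc = float("nan")
    log.info("train_forest: %d trees, mtry=%d, validation accuracy %.4f on %d objects",
             cfg.n_trees, cfg.features_per_split, acc, len(X_val))
    return ForestModel(
        estimator=est,
        n_trees=cfg.n_trees,
        features_per_split=cfg.features_per_split,
        feature_names=names,
        training_seed=sk_seed,
        validation_accuracy=acc,
    )


def _predict(est: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    """Majority vote with ties resolved to 'noncell'."""
    proba = est.predict_proba(X)
    cell_idx = list(est.classes_).index("cell")
    return np.where(proba[:, cell_idx] > 0.5, "cell", "noncell").astype(object)


def classify_objects(
    model: ForestModel, features: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Annotate each object with ``is_cell`` and screen out non-cells.

    Returns ``(cells_only, annotated)`` — the screened table and the full
    table carrying the ``is_cell`` column.  Row order is preserved and the
    prediction for an object depends only on its own features.
    """
    annotated = features.reset_index(drop=True).copy()
    if len(annotated) == 0:
        annotated["is_cell"] = pd.Series(dtype=bool)
        return annotated.copy(), annotated
    X = _panel_matrix(annotated, model.feature_names)
    pred = _predict(model.estimator, X)
    annotated["is_cell"] = pred == "cell"
    cells = annotated.loc[annotated["is_cell"]].reset_index(drop=True)
    log.info("classify_objects: %d of %d objects retained as cells",
             len(cells), len(annotated))
    return cells, annotated


def save_model(model: ForestModel, path) -> None:
    """Serialize the model with version, config echo, feature names, and seed."""
    from . import __version__

    joblib.dump(
        {
            "format_version": 1,
            "mgmorph_version": __version__,
            "n_trees": model.n_trees,
            "features_per_split": model.features_per_split,
            "feature_names": list(model.feature_names),
            "training_seed": model.training_seed,
            "validation_accuracy": model.validation_accuracy,
            "estimator": model.estimator,
        },
        path,
    )


def load_model(path) -> ForestModel:
    payload = joblib.load(path)
    return ForestModel(
        estimator=payload["estimator"],
        n_trees=payload["n_trees"],
        features_per_split=payload["features_per_split"],
        feature_names=tuple(payload["feature_names"]),
        training_seed=payload["training_seed"],
        validation_accuracy=payload["validation_accuracy"],
    )
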