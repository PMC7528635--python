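"""Diagnosis classifiers and accuracy-based permutation importance.

The prediction function maps test performance (the four CPT index z-scores),
optionally together with the control variables (age, gender, day of week,
time of day), to p(diagnosis = ADHD):

    p(diagnosis = ADHD) = f(test performance, controls)

Two families of f are provided:

* a **random forest** — a bagged ensemble of CART trees with sqrt-features
  per split.  It is built here as an explicit bagging loop over scikit-learn
  decision trees so that every tree's out-of-bag (OOB) index set is recorded;
  the accuracy-based importance below needs those sets.
* a **feed-forward neural network** — one hidden layer of 8 logistic units,
  with the weight-decay (L2) parameter selected by k-fold cross-validation
  (100 folds by default).

Feature importance follows the classic OOB permutation scheme: for each tree,
the accuracy on its OOB sample is compared with the accuracy after randomly
shuffling one feature in that sample, all other features kept unchanged; the
mean decrease in accuracy across trees is reported, unnormalized.  Values are
relative, not absolute, importances.  For the network-style one-hot encoding
of categorical controls, importances are re-aggregated per original variable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .cohort import FACTOR_COLUMNS, INDEX_COLUMNS

__all__ = [
    "ModelSpec",
    "FittedModel",
    "fit_model",
    "predict",
    "permutation_importance",
    "feature_columns",
]

POSITIVE = "ADHD"

_FOREST_DEFAULTS = {"n_trees": 500, "max_features": "sqrt", "max_depth": None}
_NN_DEFAULTS = {"hidden_units": 8, "cv_folds": 100, "alphas": (1e-4, 1e-3, 1e-2, 1e-1, 1.0)}


@dataclass(frozen=True)
class ModelSpec:
    """Which f to fit and on which feature set.

    feature_set ``"cpt_only"`` uses exactly the four index z-scores;
    ``"cpt_plus_controls"`` adds age, gender, DoW and ToD.
    """

    family: str = "random_forest"  # "random_forest" | "neural_network"
    feature_set: str = "cpt_plus_controls"  # "cpt_only" | "cpt_plus_controls"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("random_forest", "neural_network"):
            raise ValueError(f"unknown model family '{self.family}'")
        if self.feature_set not in ("cpt_only", "cpt_plus_controls"):
            raise ValueError(f"unknown feature_set '{self.feature_set}'")

    def resolved_hyperparameters(self) -> dict:
        base = dict(_FOREST_DEFAULTS if self.family == "random_forest" else _NN_DEFAULTS)
        base.update(self.hyperparameters)
        return base


def feature_columns(feature_set: str) -> list[str]:
    cols = list(INDEX_COLUMNS)
    if feature_set == "cpt_plus_controls":
        cols += list(FACTOR_COLUMNS)
    return cols


@dataclass
class FittedModel:
    """A trained f; predicts p(ADHD) for feature-complete records."""

    spec: ModelSpec
    feature_names: list[str]
    trees: list[DecisionTreeClassifier] = field(default_factory=list)
    oob_masks: list[np.ndarray] = field(default_factory=list)  # per-tree OOB row masks
    train_X: np.ndarray | None = None
    train_y: np.ndarray | None = None
    net: MLPClassifier | None = None
    scaler: StandardScaler | None = None
    onehot_map: dict[str, list[int]] | None = None  # variable -> matrix column indices

    @property
    def is_forest(self) -> bool:
        return self.spec.family == "random_forest"


def _design_matrix(
    records: pd.DataFrame, feature_names: Sequence[str], one_hot: bool
) -> tuple[np.ndarray, dict[str, list[int]]]:
    """Feature matrix + map from original variable to its column indices.

    The forest consumes ordinal integer codes for the categorical controls;
    the network consumes one-hot columns (all observed levels are fixed by
    the schema, so train/predict matrices align).
    """
    blocks, colmap, j = [], {}, 0
    levels = {"gender": (0, 1), "dow": tuple(range(1, 8)), "tod": (1, 2, 3)}
    for name in feature_names:
        x = records[name].to_numpy()
        if one_hot and name in levels:
            block = np.column_stack([(x == lv).astype(float) for lv in levels[name]])
        else:
            block = x.astype(float).reshape(-1, 1)
        blocks.append(block)
        colmap[name] = list(range(j, j + block.shape[1]))
        j += block.shape[1]
    return np.hstack(blocks), colmap


def _labels(records: pd.DataFrame) -> np.ndarray:
    return (records["diagnosis"] == POSITIVE).to_numpy(dtype=int)


def fit_model(spec: ModelSpec, training: pd.DataFrame) -> FittedModel:
    """Fit f on the (typically rebalanced) training table.

    Deterministic given spec.seed.  Raises if only one diagnosis class is
    present.
    """
    if training.empty:
        raise ValueError("training table is empty")
    y = _labels(training)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contain a single diagnosis class")
    names = feature_columns(spec.feature_set)
    missing = [c for c in names if c not in training.columns]
    if missing:
        raise ValueError(f"training table lacks feature columns {missing}")
    hp = spec.resolved_hyperparameters()
    if spec.family == "random_forest":
        return _fit_forest(spec, training, y, names, hp)
    return _fit_network(spec, training, y, names, hp)


def _fit_forest(
    spec: ModelSpec, training: pd.DataFrame, y: np.ndarray, names: list[str], hp: dict
) -> FittedModel:
    X, colmap = _design_matrix(training, names, one_hot=False)
    rng = np.random.default_rng(spec.seed)
    n = len(y)
    trees, oob_masks = [], []
    for _ in range(hp["n_trees"]):
        idx = rng.integers(n, size=n)
        mask = np.ones(n, dtype=bool)
        mask[idx] = False  # OOB = rows never drawn
        tree = DecisionTreeClassifier(
            max_features=hp["max_features"],
            max_depth=hp["max_depth"],
            random_state=int(rng.integers(2**31)),
        )
        tree.fit(X[idx], y[idx])
        trees.append(tree)
        oob_masks.append(mask)
    return FittedModel(
        spec=spec, feature_names=names, trees=trees, oob_masks=oob_masks,
        train_X=X, train_y=y, onehot_map=colmap,
    )


def _fit_network(
    spec: ModelSpec, training: pd.DataFrame, y: np.ndarray, names: list[str], hp: dict
) -> FittedModel:
    X, colmap = _design_matrix(training, names, one_hot=True)
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    folds = min(hp["cv_folds"], len(y))
    net = MLPClassifier(
        hidden_layer_sizes=(hp["hidden_units"],),
        activation="logistic",
        solver="lbfgs",
        max_iter=500,
        random_state=spec.seed,
    )
    alphas = list(hp["alphas"])
    if len(alphas) > 1 and folds >= 2:
        search = GridSearchCV(
            net,
            {"alpha": alphas},
            cv=KFold(n_splits=folds, shuffle=True, random_state=spec.seed),
            scoring="accuracy",
            n_jobs=None,
        )
        search.fit(Xs, y)
        net = search.best_estimator_
    else:
        net.set_params(alpha=alphas[0])
        net.fit(Xs, y)
    return FittedModel(
        spec=spec, feature_names=names, net=net, scaler=scaler, onehot_map=colmap,
    )


def _forest_proba(model: FittedModel, X: np.ndarray, trees=None) -> np.ndarray:
    trees = model.trees if trees is None else trees
    votes = np.zeros(len(X))
    for tree in trees:
        p = tree.predict_proba(X)
        votes += p[:, 1] if p.shape[1] == 2 else float(tree.classes_[0]) * np.ones(len(X))
    return votes / len(trees)


def predict(model: FittedModel, records: pd.DataFrame) -> pd.DataFrame:
    """p(ADHD) and hard class per record; ties at 0.5 go to ADHD (positive)."""
    missing = [c for c in model.feature_names if c not in records.columns]
    if missing:
        raise ValueError(f"records lack feature columns {missing}")
    if model.is_forest:
        X, _ = _design_matrix(records, model.feature_names, one_hot=False)
        proba = _forest_proba(model, X)
    else:
        X, _ = _design_matrix(records, model.feature_names, one_hot=True)
        proba = model.net.predict_proba(model.scaler.transform(X))[:, 1]
    cls = np.where(proba >= 0.5, POSITIVE, "control")
    return pd.DataFrame({"p_adhd": proba, "predicted": cls}, index=records.index)


def permutation_importance(
    model: FittedModel, seed: int = 0, data: pd.DataFrame | None = None
) -> pd.Series:
    """Out-of-bag permutation importance (mean decrease in accuracy).

    For every tree and feature: accuracy on the tree's OOB sample minus
    accuracy on the same sample with that feature's values shuffled, other
    features unchanged; averaged over trees.  Raw (unnormalized) values.
    Only defined for forests, whose OOB sets were recorded at fit time; pass
    ``data`` to evaluate on an external labelled table instead of the OOB
    samples (then each tree uses the full table).
    """
    if not model.is_forest:
        raise ValueError("permutation importance requires a random forest model")
    rng = np.random.default_rng(seed)
    if data is not None:
        X, _ = _design_matrix(data, model.feature_names, one_hot=False)
        y = _labels(data)
        masks = [np.ones(len(y), dtype=bool)] * len(model.trees)
    else:
        X, y = model.train_X, model.train_y
        masks = model.oob_masks

    drops = {name: [] for name in model.feature_names}
    for tree, mask in zip(model.trees, masks):
        if mask.sum() == 0:
            continue
        Xo, yo = X[mask], y[mask]
        base_acc = float((tree.predict(Xo) == yo).mean())
        for name in model.feature_names:
            cols = model.onehot_map[name]
            Xp = Xo.copy()
            perm = rng.permutation(len(yo))
            Xp[:, cols] = Xo[perm][:, cols]
            drops[name].append(base_acc - float((tree.predict(Xp) == yo).mean()))
    return pd.Series({k: float(np.mean(v)) for k, v in drops.items()}, name="importance")
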