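"""Sparse gradient-boosted tree models over persistence features.

Two tasks share one machinery: affinity regression on 10-component
persistence fingerprints (labels in kcal/mol), and binder/decoy scoring on
the flattened 72-vector discretized-IPC stack of a 15 Å-truncated complex
(labels in {0, 1}, higher score = more binder-like). The default ensemble is
deliberately tiny — 13 trees of depth 3 — because interpretability is the
point: the fitted model is stored as explicit tree structures, serialized to
human-readable JSON, and predictions are computed by traversing those stored
trees (``base + learning_rate * sum(tree outputs)``), not by an opaque
estimator object.

scikit-learn's ``GradientBoostingRegressor`` performs the least-squares
boosting fit; its trees are extracted immediately after fitting and the
sklearn object is discarded.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .config import (
    DEFAULT_LEARNING_RATE,
    DEFAULT_MAX_DEPTH,
    DEFAULT_N_TREES,
    DEFAULT_TEMPERATURE,
    GAS_CONSTANT_KCAL,
)

__all__ = [
    "FeatureContractError",
    "TrainingTable",
    "TreeEnsembleModel",
    "kd_to_dg",
    "fit_gbr",
    "predict_affinity",
    "score_binder",
    "select_features",
    "export_trees",
    "import_trees",
]


class FeatureContractError(ValueError):
    """Model and input disagree about the feature vector."""


def kd_to_dg(kd: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Binding free energy from a dissociation constant: dG = R*T*ln(Kd).

    Kd in molar, temperature in kelvin, result in kcal/mol (negative for
    sub-molar Kd, i.e. for anything that actually binds).
    """
    if kd <= 0:
        raise ValueError("kd must be positive")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return GAS_CONSTANT_KCAL * temperature * math.log(kd)


@dataclass
class TrainingTable:
    """Labeled feature rows: one complex per row."""

    ids: list[str]
    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n, f = self.X.shape
        if len(self.ids) != n or self.y.shape != (n,):
            raise ValueError("inconsistent row counts")
        if len(self.feature_names) != f:
            raise ValueError("feature_names length must match X columns")
        if not np.all(np.isfinite(self.X)) or not np.all(np.isfinite(self.y)):
            raise ValueError("features and labels must be finite")

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df.insert(0, "id", self.ids)
        df["label"] = self.y
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TrainingTable":
        df = pd.read_csv(path)
        names = [c for c in df.columns if c not in ("id", "label")]
        return cls(df["id"].astype(str).tolist(), df[names].to_numpy(), df["label"].to_numpy(), names)


# ---------------------------------------------------------------------------
# tree ensemble


def _extract_tree(sk_tree) -> dict:
    """Nested-dict form of an sklearn decision tree (x[f] <= t goes left)."""
    t = sk_tree.tree_

    def node(i: int) -> dict:
        if t.children_left[i] == -1:
            return {"value": float(t.value[i, 0, 0])}
        return {
            "feature": int(t.feature[i]),
            "threshold": float(t.threshold[i]),
            "left": node(t.children_left[i]),
            "right": node(t.children_right[i]),
        }

    return node(0)


def _tree_predict(node: dict, x: np.ndarray) -> float:
    while "value" not in node:
        node = node["left"] if x[node["feature"]] <= node["threshold"] else node["right"]
    return node["value"]


def _count_leaves(node: dict) -> int:
    if "value" in node:
        return 1
    return _count_leaves(node["left"]) + _count_leaves(node["right"])


@dataclass
class TreeEnsembleModel:
    """An explicit, serializable gradient-boosted tree ensemble.

    prediction(x) = base_prediction + learning_rate * sum_i tree_i(x)
    """

    trees: list[dict]
    learning_rate: float
    base_prediction: float
    feature_names: list[str]
    task: str  # "affinity" | "binder_score"
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.task not in ("affinity", "binder_score"):
            raise ValueError(f"unknown task {self.task!r}")

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def n_leaves(self) -> list[int]:
        return [_count_leaves(t) for t in self.trees]

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise FeatureContractError(
                f"model expects {self.n_features} features "
                f"({self.feature_names[:3]}...), got {X.shape[1]}"
            )
        out = np.full(X.shape[0], self.base_prediction)
        for tree in self.trees:
            out += self.learning_rate * np.array(
                [_tree_predict(tree, row) for row in X]
            )
        return out

    def predict_one(self, x: Sequence[float]) -> float:
        return float(self.predict(np.asarray(x, dtype=float).reshape(1, -1))[0])

    # serialization -----------------------------------------------------

    def to_json(self, indent: int = 2) -> str:
        payload = {
            "format": "persfp-tree-ensemble-v1",
            "task": self.task,
            "learning_rate": self.learning_rate,
            "base_prediction": self.base_prediction,
            "feature_names": self.feature_names,
            "hyperparameters": self.hyperparameters,
            "trees": self.trees,
        }
        return json.dumps(payload, indent=indent)

    @classmethod
    def from_json(cls, text: str) -> "TreeEnsembleModel":
        payload = json.loads(text)
        return cls(
            payload["trees"],
            payload["learning_rate"],
            payload["base_prediction"],
            payload["feature_names"],
            payload["task"],
            payload.get("hyperparameters", {}),
        )

    def to_ruleset(self) -> str:
        """Indented if/else text, one block per tree, for reading by hand."""
        lines = [
            f"task: {self.task}",
            f"base prediction: {self.base_prediction:.6g}",
            f"learning rate: {self.learning_rate:.6g}",
        ]

        def walk(node: dict, depth: int) -> None:
            pad = "  " * depth
            if "value" in node:
                lines.append(f"{pad}-> {node['value']:.6g}")
            else:
                fname = self.feature_names[node["feature"]]
                lines.append(f"{pad}if {fname} <= {node['threshold']:.6g}:")
                walk(node["left"], depth + 1)
                lines.append(f"{pad}else:")
                walk(node["right"], depth + 1)

        for i, tree in enumerate(self.trees):
            lines.append(f"tree {i}:")
            walk(tree, 1)
        return "\n".join(lines) + "\n"


def fit_gbr(
    table: TrainingTable,
    n_trees: int = DEFAULT_N_TREES,
    max_depth: int = DEFAULT_MAX_DEPTH,
    learning_rate: float = DEFAULT_LEARNING_RATE,
    seed: int = 0,
    task: str = "affinity",
) -> TreeEnsembleModel:
    """Least-squares gradient boosting; deterministic given the seed.

    Degenerate labels (all equal) produce a base-only model with a warning.
    """
    if len(table.ids) < 2:
        raise ValueError("need at least 2 training rows")
    if n_trees <= 0 or max_depth <= 0 or learning_rate <= 0:
        raise ValueError("hyperparameters must be positive")

    hyper = {
        "n_trees": n_trees,
        "max_depth": max_depth,
        "learning_rate": learning_rate,
        "seed": seed,
        "loss": "squared_error",
    }
    if float(np.ptp(table.y)) == 0.0:
        warnings.warn("degenerate labels (all equal): base-only model", stacklevel=2)
        return TreeEnsembleModel(
            [], learning_rate, float(table.y[0]), list(table.feature_names), task, hyper
        )

    from sklearn.ensemble import GradientBoostingRegressor

    gbr = GradientBoostingRegressor(
        n_estimators=n_trees,
        max_depth=max_depth,
        learning_rate=learning_rate,
        loss="squared_error",
        random_state=seed,
    )
    gbr.fit(table.X, table.y)
    trees = [_extract_tree(est[0]) for est in gbr.estimators_]
    model = TreeEnsembleModel(
        trees,
        learning_rate,
        float(np.mean(table.y)),
        list(table.feature_names),
        task,
        hyper,
    )
    model.hyperparameters["mdi_importances"] = [
        float(v) for v in gbr.feature_importances_
    ]
    return model


def predict_affinity(model: TreeEnsembleModel, fingerprint) -> float:
    """Predicted binding free energy in kcal/mol for one fingerprint.

    Accepts a PersistenceFingerprint or a plain vector. The output set is
    finite by construction (an ensemble of trees takes finitely many values).
    """
    if model.task != "affinity":
        raise FeatureContractError(f"model task is {model.task!r}, not affinity")
    x = getattr(fingerprint, "values", fingerprint)
    x = np.asarray(x, dtype=float)
    if x.shape != (model.n_features,):
        raise FeatureContractError(
            f"fingerprint length {x.shape} does not match model features "
            f"({model.n_features}: {model.feature_names[:3]}...)"
        )
    return model.predict_one(x)


def score_binder(model: TreeEnsembleModel, stack) -> float:
    """Binder-likeness score for a discretized-IPC stack (higher = binder).

    ``stack`` may be the list of DiscretizedIPC vectors in canonical order or
    the already-flattened feature vector.
    """
    if model.task != "binder_score":
        raise FeatureContractError(f"model task is {model.task!r}, not binder_score")
    if isinstance(stack, (list, tuple)) and stack and hasattr(stack[0], "densities"):
        from .ipc import stack_to_vector

        x = stack_to_vector(stack)
    else:
        x = np.asarray(stack, dtype=float)
    if x.shape != (model.n_features,):
        raise FeatureContractError(
            f"stack length {x.shape} does not match model features ({model.n_features})"
        )
    return model.predict_one(x)


# ---------------------------------------------------------------------------
# feature selection: impurity ranking + iterative ablation


def select_features(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: Sequence[str],
    *,
    top_k: int = 77,
    ablation_tolerance: float = 0.01,
    val_fraction: float = 0.1,
    seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
    max_depth: int = DEFAULT_MAX_DEPTH,
    learning_rate: float = DEFAULT_LEARNING_RATE,
) -> list[str]:
    """Two-stage selection over named feature columns.

    Stage 1 fits one boosted ensemble on all columns and keeps the ``top_k``
    by mean decrease in impurity (skipped when there are fewer columns than
    ``top_k``). Stage 2 repeatedly drops the least-important surviving column
    and refits on a seeded train/validation split, stopping when validation
    RMSE degrades by more than ``ablation_tolerance`` (relative) over the best
    split seen. Returns surviving names ranked by importance.
    """
    from sklearn.ensemble import GradientBoostingRegressor

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    names = list(feature_names)
    if X.shape[1] != len(names):
        raise ValueError("feature_names must match X columns")

    rng = np.random.default_rng(seed)
    n = X.shape[0]
    perm = rng.permutation(n)
    n_val = max(1, int(round(val_fraction * n)))
    val_idx, train_idx = perm[:n_val], perm[n_val:]

    def fit_eval(cols: list[int]) -> tuple[np.ndarray, float]:
        gbr = GradientBoostingRegressor(
            n_estimators=n_trees,
            max_depth=max_depth,
            learning_rate=learning_rate,
            loss="squared_error",
            random_state=seed,
        )
        gbr.fit(X[np.ix_(train_idx, cols)], y[train_idx])
        pred = gbr.predict(X[np.ix_(val_idx, cols)])
        rmse = float(np.sqrt(np.mean((pred - y[val_idx]) ** 2)))
        return gbr.feature_importances_, rmse

    cols = list(range(len(names)))
    # stage 1: impurity ranking
    if len(cols) >= top_k:
        imp, _ = fit_eval(cols)
        order = np.argsort(imp)[::-1]
        cols = [cols[i] for i in order[:top_k]]

    # stage 2: iterative ablation
    imp, rmse = fit_eval(cols)
    best_rmse = rmse
    while len(cols) > 1:
        drop = int(np.argmin(imp))
        candidate = cols[:drop] + cols[drop + 1 :]
        cand_imp, cand_rmse = fit_eval(candidate)
        if cand_rmse > best_rmse * (1.0 + ablation_tolerance):
            break
        cols, imp = candidate, cand_imp
        best_rmse = min(best_rmse, cand_rmse)

    ranked = [cols[i] for i in np.argsort(imp)[::-1]]
    return [names[i] for i in ranked]


def export_trees(model: TreeEnsembleModel) -> str:
    """Human-readable JSON ruleset; ``import_trees`` round-trips it exactly."""
    return model.to_json()


def import_trees(text: str) -> TreeEnsembleModel:
    return TreeEnsembleModel.from_json(text)
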