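"""Multitask random forest: fitting, prediction, OOB evaluation, joint
feature importance, and JSON (de)serialization."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._tree import NO_FEATURE, grow_tree, predict_tree


@dataclass
class ForestHyperparams:
    n_trees: int = 100
    max_depth: int = 6
    min_leaf: int = 3
    mtry: int | None = None  # default: ceil(sqrt(p))

    def resolve_mtry(self, n_features: int) -> int:
        m = self.mtry if self.mtry is not None else int(np.ceil(np.sqrt(n_features)))
        return max(1, min(m, n_features))


@dataclass
class ForestModel:
    """A fitted multitask forest.

    Trees are stored as flat node arrays; every leaf holds one positive-class
    frequency per task. ``medians`` are the training medians used to impute
    missing feature values, frozen at fit time.
    """

    feature_names: list[str]
    task_names: list[str]
    hyperparams: ForestHyperparams
    seed: int
    trees: list[dict] = field(default_factory=list)
    bootstrap_indices: list[np.ndarray] = field(default_factory=list)
    importances: np.ndarray | None = None
    medians: np.ndarray | None = None

    # -- persistence --------------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "format_version": 1,
            "feature_names": self.feature_names,
            "task_names": self.task_names,
            "hyperparams": vars(self.hyperparams),
            "seed": self.seed,
            "medians": None if self.medians is None else self.medians.tolist(),
            "importances": None if self.importances is None else self.importances.tolist(),
            "bootstrap_indices": [b.tolist() for b in self.bootstrap_indices],
            "trees": [{k: v.tolist() for k, v in t.items()} for t in self.trees],
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "ForestModel":
        d = json.loads(text)
        model = cls(
            feature_names=d["feature_names"],
            task_names=d["task_names"],
            hyperparams=ForestHyperparams(**d["hyperparams"]),
            seed=d["seed"],
        )
        model.medians = None if d["medians"] is None else np.array(d["medians"])
        model.importances = None if d["importances"] is None else np.array(d["importances"])
        model.bootstrap_indices = [np.array(b, dtype=np.int64) for b in d["bootstrap_indices"]]
        dtypes = {"feature": np.int64, "threshold": np.float64, "left": np.int64,
                  "right": np.int64, "leaf": np.float64, "node_n": np.int64}
        model.trees = [{k: np.array(v, dtype=dtypes[k]) for k, v in t.items()}
                       for t in d["trees"]]
        return model


def _as_matrix(X, feature_names: list[str] | None = None):
    if isinstance(X, pd.DataFrame):
        if feature_names is not None:
            missing = [f for f in feature_names if f not in X.columns]
            if missing:
                raise KeyError(f"features absent from input table: {missing}")
            X = X[feature_names]
            names = feature_names
        else:
            names = list(X.columns)
        return np.ascontiguousarray(X.to_numpy(dtype=float)), names
    X = np.asarray(X, dtype=float)
    names = feature_names if feature_names is not None else [f"f{i}" for i in range(X.shape[1])]
    return np.ascontiguousarray(X), list(names)


def _as_labels(labels):
    if isinstance(labels, pd.DataFrame):
        return np.ascontiguousarray(labels.to_numpy(dtype=float)), list(labels.columns)
    Y = np.asarray(labels, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    return np.ascontiguousarray(Y), [f"task{i}" for i in range(Y.shape[1])]


def impute_with(X: np.ndarray, medians: np.ndarray) -> np.ndarray:
    out = X.copy()
    nan_r, nan_c = np.nonzero(np.isnan(out))
    out[nan_r, nan_c] = medians[nan_c]
    return out


def fit_multitask_forest(X, labels, hyperparams: ForestHyperparams | None = None,
                         seed: int = 0) -> ForestModel:
    """Fit the forest. ``labels`` may hold one or several binary tasks; the
    split criterion is the unweighted mean of the per-task Gini decreases."""
    hp = hyperparams or ForestHyperparams()
    Xm, names = _as_matrix(X)
    Y, task_names = _as_labels(labels)
    n, p = Xm.shape
    if Y.shape[0] != n:
        raise ValueError("labels and features disagree on the number of patients")
    if np.isnan(Y).any():
        raise ValueError("missing labels are not allowed when fitting")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        medians = np.nanmedian(Xm, axis=0)
    medians = np.where(np.isnan(medians), 0.0, medians)
    Xm = impute_with(Xm, medians)
    if np.all(Xm.std(axis=0) == 0):
        warnings.warn("all features are constant; forest degenerates to marginal stumps")

    mtry = hp.resolve_mtry(p)
    rng = np.random.default_rng(seed)
    model = ForestModel(names, task_names, hp, seed, medians=medians)
    importance = np.zeros(p)
    T = Y.shape[1]
    max_nodes = 2 * n + 1
    for _ in range(hp.n_trees):
        boot = rng.integers(0, n, size=n).astype(np.int64)
        tree_seed = int(rng.integers(0, 2 ** 31 - 1))
        feature = np.full(max_nodes, NO_FEATURE, dtype=np.int64)
        threshold = np.zeros(max_nodes)
        left = np.zeros(max_nodes, dtype=np.int64)
        right = np.zeros(max_nodes, dtype=np.int64)
        leaf = np.zeros((max_nodes, T))
        node_n = np.zeros(max_nodes, dtype=np.int64)
        tree_importance = np.zeros(p)
        n_nodes = grow_tree(Xm, Y, boot, mtry, hp.max_depth, hp.min_leaf,
                            tree_seed, feature, threshold, left, right, leaf,
                            node_n, tree_importance)
        importance += tree_importance
        model.trees.append({
            "feature": feature[:n_nodes].copy(),
            "threshold": threshold[:n_nodes].copy(),
            "left": left[:n_nodes].copy(),
            "right": right[:n_nodes].copy(),
            "leaf": leaf[:n_nodes].copy(),
            "node_n": node_n[:n_nodes].copy(),
        })
        model.bootstrap_indices.append(boot)
    model.importances = importance / hp.n_trees
    return model


def predict(model: ForestModel, X) -> pd.DataFrame:
    """Per-task probabilities: mean of leaf frequencies over trees."""
    Xm, _ = _as_matrix(X, model.feature_names)
    Xm = impute_with(Xm, model.medians)
    T = len(model.task_names)
    out = np.zeros((Xm.shape[0], T))
    for t in model.trees:
        predict_tree(Xm, t["feature"], t["threshold"], t["left"], t["right"],
                     t["leaf"], out)
    out /= len(model.trees)
    index = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(Xm.shape[0])
    return pd.DataFrame(out, columns=model.task_names, index=index)


def predict_oob(model: ForestModel, X) -> pd.DataFrame:
    """Out-of-bag probabilities: for each patient, average only the trees
    whose bootstrap did not contain that patient (NaN if none)."""
    Xm, _ = _as_matrix(X, model.feature_names)
    Xm = impute_with(Xm, model.medians)
    n = Xm.shape[0]
    T = len(model.task_names)
    acc = np.zeros((n, T))
    cnt = np.zeros(n)
    for t, boot in zip(model.trees, model.bootstrap_indices):
        inbag = np.zeros(n, dtype=bool)
        inbag[boot] = True
        oob = ~inbag
        if not oob.any():
            continue
        tmp = np.zeros((int(oob.sum()), T))
        predict_tree(np.ascontiguousarray(Xm[oob]), t["feature"], t["threshold"],
                     t["left"], t["right"], t["leaf"], tmp)
        acc[oob] += tmp
        cnt[oob] += 1
    with np.errstate(invalid="ignore"):
        out = acc / cnt[:, None]
    index = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(n)
    return pd.DataFrame(out, columns=model.task_names, index=index)


def joint_importance(model: ForestModel) -> pd.Series:
    """Features ranked by mean multitask impurity decrease, weighted by the
    fraction of samples reaching each split; ties break lexicographically."""
    s = pd.Series(model.importances, index=model.feature_names, name="importance")
    order = sorted(s.index, key=lambda name: (-s[name], name))
    return s.loc[order]
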