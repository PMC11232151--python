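"""Feature-set construction: collinearity filtering, LOOCV top-k signature
selection on the joint importance ranking, random hyperparameter search, and
the stratified development split."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .forest import (ForestHyperparams, ForestModel, fit_multitask_forest,
                     joint_importance, predict, predict_oob)
from .metrics import auc

log = logging.getLogger(__name__)


def collinearity_filter(table: pd.DataFrame, r_threshold: float = 0.9
                        ) -> tuple[pd.DataFrame, list[dict]]:
    """Remove highly collinear features.

    Zero-variance columns are dropped first. Then pairs with |r| above the
    threshold are visited in descending |r|; from each pair the member with
    the higher mean absolute correlation to all still-retained features is
    dropped. The returned log records every removal and its trigger.
    """
    if table.shape[1] < 2:
        raise ValueError("collinearity filtering needs at least two features")
    removal_log: list[dict] = []
    work = table.copy()
    variances = work.var(axis=0, ddof=0)
    for name in variances.index[variances == 0]:
        removal_log.append({"dropped": name, "reason": "zero_variance",
                            "r": np.nan, "partner": None})
        work = work.drop(columns=name)

    corr = work.corr().abs()
    np.fill_diagonal(corr.values, 0.0)
    alive = {c: True for c in corr.columns}
    pairs = [(corr.iat[i, j], corr.index[i], corr.columns[j])
             for i in range(len(corr)) for j in range(i + 1, len(corr))
             if corr.iat[i, j] > r_threshold]
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    for r, a, b in pairs:
        if not (alive[a] and alive[b]):
            continue
        kept_cols = [c for c, ok in alive.items() if ok]
        mean_a = corr.loc[a, kept_cols].drop(a).mean()
        mean_b = corr.loc[b, kept_cols].drop(b).mean()
        drop = a if mean_a >= mean_b else b
        keep = b if drop == a else a
        alive[drop] = False
        removal_log.append({"dropped": drop, "reason": "collinear",
                            "r": float(r), "partner": keep})
    kept = [c for c in work.columns if alive.get(c, False)]
    return work[kept], removal_log


def split_score_multitask(X: np.ndarray, labels: np.ndarray, feature: int,
                          threshold: float) -> float:
    """Multitask split score of a proposed (feature, threshold) cut: the
    unweighted mean over tasks of the Gini impurity decrease. Exposed mainly
    for inspection; the forest computes the same quantity internally."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(labels, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = X.shape[0]
    if n < 2:
        raise ValueError("a split needs at least two samples")
    go_left = X[:, feature] <= threshold
    nl, nr = int(go_left.sum()), int((~go_left).sum())
    if nl == 0 or nr == 0:
        return 0.0

    def gini(y):
        p = y.mean()
        return 2.0 * p * (1.0 - p)

    score = 0.0
    for t in range(Y.shape[1]):
        parent = gini(Y[:, t])
        child = (nl * gini(Y[go_left, t]) + nr * gini(Y[~go_left, t])) / n
        score += parent - child
    return score / Y.shape[1]


@dataclass
class SelectionResult:
    ranking: pd.Series
    chosen_k: int
    chosen_features: list[str]
    loocv_curve: pd.DataFrame  # columns: k, auc_mean, plus one column per task
    seed: int


def _loocv_auc(X: pd.DataFrame, Y: pd.DataFrame, hp: ForestHyperparams,
               seed: int) -> dict[str, float]:
    n = len(X)
    Xm = X.to_numpy(dtype=float)
    Ym = Y.to_numpy(dtype=float)
    preds = np.empty((n, Ym.shape[1]))
    for i in range(n):
        keep = np.arange(n) != i
        model = fit_multitask_forest(Xm[keep], Ym[keep], hp, seed=seed)
        preds[i] = predict(model, Xm[i:i + 1]).to_numpy()[0]
    out = {}
    for t, task in enumerate(Y.columns):
        out[task] = auc(preds[:, t], Ym[:, t])
    out["mean"] = float(np.mean([out[t] for t in Y.columns]))
    return out


def select_common_subset(X: pd.DataFrame, labels: pd.DataFrame,
                         ranking: pd.Series, k_grid=None, seed: int = 0,
                         hyperparams: ForestHyperparams | None = None
                         ) -> SelectionResult:
    """Choose the top-k of the joint ranking whose LOOCV mean AUC across
    tasks is best; ties go to the smallest (most parsimonious) k."""
    hp = hyperparams or ForestHyperparams()
    if k_grid is None:
        k_grid = list(range(1, 31))
    k_grid = sorted(set(int(k) for k in k_grid))
    p = len(ranking)
    clipped = [k for k in k_grid if k <= p]
    if len(clipped) < len(k_grid):
        warnings.warn(f"k_grid clipped to the {p} available features")
        if not clipped:
            clipped = [p]
    rows = []
    best = None
    for k in clipped:
        feats = list(ranking.index[:k])
        res = _loocv_auc(X[feats], labels, hp, seed)
        rows.append({"k": k, "auc_mean": res["mean"],
                     **{f"auc_{t}": res[t] for t in labels.columns}})
        if best is None or res["mean"] > best[1] + 1e-12:
            best = (k, res["mean"])
    chosen_k = best[0]
    return SelectionResult(
        ranking=ranking,
        chosen_k=chosen_k,
        chosen_features=list(ranking.index[:chosen_k]),
        loocv_curve=pd.DataFrame(rows),
        seed=seed,
    )


def random_grid_search(space: dict[str, list], X, labels, n_draws: int = 20,
                       seed: int = 0, exhaustive: bool = False) -> dict:
    """Random draws from a finite hyperparameter space scored by OOB mean
    AUC across tasks; returns the best setting and the full trace."""
    keys = sorted(space)
    if not keys or any(len(space[k]) == 0 for k in keys):
        raise ValueError("hyperparameter space must be finite and nonempty")
    sizes = [len(space[k]) for k in keys]
    total = int(np.prod(sizes))
    rng = np.random.default_rng(seed)

    if exhaustive:
        combos = []
        for flat in range(total):
            combo, rem = {}, flat
            for k, size in zip(keys, sizes):
                combo[k] = space[k][rem % size]
                rem //= size
            combos.append(combo)
    else:
        combos = [{k: space[k][rng.integers(0, len(space[k]))] for k in keys}
                  for _ in range(n_draws)]

    Y = labels if isinstance(labels, pd.DataFrame) else pd.DataFrame(labels)
    trace = []
    best = None
    for i, combo in enumerate(combos):
        hp = ForestHyperparams(**combo)
        model = fit_multitask_forest(X, Y, hp, seed=seed + i)
        oob = predict_oob(model, X)
        scores = []
        for t, task in enumerate(Y.columns):
            ok = ~oob[task].isna()
            scores.append(auc(oob[task][ok], Y[task][ok]))
        mean_auc = float(np.mean(scores))
        trace.append({**combo, "oob_mean_auc": mean_auc})
        if best is None or mean_auc > best[1]:
            best = (combo, mean_auc)
    return {"best": best[0], "best_score": best[1], "trace": pd.DataFrame(trace)}


def split_development(table: pd.DataFrame, labels: pd.DataFrame,
                      frac: float = 0.66, seed: int = 0
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/validation split stratified jointly on the
    two tasks; falls back to single-label stratification when a joint
    stratum has fewer than two patients."""
    if not 0 < frac < 1:
        raise ValueError("frac must be strictly between 0 and 1")
    n = len(table)
    if n < 6:
        raise ValueError("too few patients to split")
    rng = np.random.default_rng(seed)
    strata = labels.apply(lambda row: tuple(int(v) for v in row), axis=1)
    counts = strata.value_counts()
    if (counts < 2).any():
        log.warning("joint stratum with <2 patients; falling back to "
                    "stratification on %s alone", labels.columns[0])
        strata = labels.iloc[:, 0].astype(int)
    # largest-remainder allocation: per-stratum counts floor(frac*size) with
    # the global deficit given to the largest fractional parts, so the train
    # arm has exactly round(frac*n) patients and each stratum's prevalence is
    # preserved to within one patient
    n_train_total = int(round(frac * n))
    positions = pd.Series(np.arange(n), index=table.index)
    groups = [(key, grp.to_numpy()) for key, grp in positions.groupby(strata.values)]
    floors = [int(np.floor(frac * len(idx))) for _, idx in groups]
    remainders = [frac * len(idx) - f for (_, idx), f in zip(groups, floors)]
    deficit = n_train_total - sum(floors)
    order = sorted(range(len(groups)), key=lambda i: (-remainders[i], i))
    takes = list(floors)
    for i in order[:max(0, deficit)]:
        takes[i] += 1
    train_mask = np.zeros(n, dtype=bool)
    for (_, idx), take in zip(groups, takes):
        idx = idx.copy()
        rng.shuffle(idx)
        take = min(max(take, 1), len(idx) - 1) if len(idx) > 1 else take
        train_mask[idx[:take]] = True
    return np.nonzero(train_mask)[0], np.nonzero(~train_mask)[0]
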