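"""Per-pathway EF regressors: bagged regression trees with random
feature subsets, the random 10-part split, and repeated-run evaluation.

The ensemble is built directly from its three-step description: (1) at
every node draw k of the m candidate factors and take the
variance-reducing split among them; (2) repeat over bootstrap resamples
to grow a forest of n trees; (3) evaluate on the held-out test part.
The dataset is shuffled into 10 near-equal parts, 7/10 train and 3/10
test; models are re-run many times (500 by default at full scale) and
performance is the average over runs.

Randomness protocol (part of the API contract, relied on by the
equivalence tests): one ``numpy.random.Generator`` seeded with
``random_state`` drives the whole fit; for each tree in order, first the
n bootstrap indices are drawn with ``rng.integers(0, n, n)``, then node
feature subsets are drawn with ``rng.choice(m, k, replace=False)`` in
depth-first order, left child before right.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .rda import PathwaySpec

__all__ = [
    "BaggedTreeRegressor",
    "random_partition",
    "evaluate",
    "repeated_runs",
    "train_pathway_model",
    "predict_ef",
]


def _build_tree(
    X: np.ndarray,
    y: np.ndarray,
    idx: np.ndarray,
    k: int,
    min_leaf: int,
    rng: np.random.Generator,
) -> dict:
    """Grow one tree depth-first; nodes are JSON-serializable dicts."""
    y_node = y[idx]
    if len(idx) < 2 * min_leaf or np.ptp(y_node) == 0.0:
        return {"value": float(y_node.mean())}
    m = X.shape[1]
    feats = rng.choice(m, size=k, replace=False)
    best = None  # (sse, feature, threshold)
    for f in feats:
        xv = X[idx, f]
        order = np.argsort(xv, kind="mergesort")
        xs, ys = xv[order], y_node[order]
        # candidate split after position i (1-based prefix), both sides >= min_leaf
        csum = np.cumsum(ys)
        csum2 = np.cumsum(ys * ys)
        n = len(ys)
        i = np.arange(min_leaf, n - min_leaf + 1)
        i = i[xs[i - 1] < xs[i]]  # only between distinct values
        if len(i) == 0:
            continue
        left_sse = csum2[i - 1] - csum[i - 1] ** 2 / i
        rs, rs2 = csum[-1] - csum[i - 1], csum2[-1] - csum2[i - 1]
        right_sse = rs2 - rs**2 / (n - i)
        sse = left_sse + right_sse
        j = int(np.argmin(sse))
        cand = (float(sse[j]), int(f), float(0.5 * (xs[i[j] - 1] + xs[i[j]])))
        if best is None or cand[0] < best[0] - 1e-12:
            best = cand
    if best is None:
        return {"value": float(y_node.mean())}
    _, f, thr = best
    left = idx[X[idx, f] <= thr]
    right = idx[X[idx, f] > thr]
    return {
        "feature": f,
        "threshold": thr,
        "left": _build_tree(X, y, left, k, min_leaf, rng),
        "right": _build_tree(X, y, right, k, min_leaf, rng),
    }


def _predict_tree(node: dict, X: np.ndarray, out: np.ndarray, mask: np.ndarray) -> None:
    if "value" in node:
        out[mask] = node["value"]
        return
    go_left = mask & (X[:, node["feature"]] <= node["threshold"])
    _predict_tree(node["left"], X, out, go_left)
    _predict_tree(node["right"], X, out, mask & ~go_left)


class BaggedTreeRegressor(RegressorMixin, BaseEstimator):
    """Bagged regression-tree ensemble with per-node random feature
    subsets (a random forest regressor).

    Parameters
    ----------
    n_trees : number of bootstrap trees (default 500).
    k_features : features considered at each split; default
        ``max(1, m // 3)`` where m is the number of factors; must be < m
        unless m == 1.
    min_leaf : minimum samples per leaf (default 5).
    random_state : seed for the fit-wide generator.

    Predictions are means of leaf means, so they are bounded by the
    training-target extremes.
    """

    def __init__(
        self,
        n_trees: int = 500,
        k_features: int | None = None,
        min_leaf: int = 5,
        random_state: int | None = None,
    ):
        self.n_trees = n_trees
        self.k_features = k_features
        self.min_leaf = min_leaf
        self.random_state = random_state

    def fit(self, X, y) -> "BaggedTreeRegressor":
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            X = X.to_numpy(float)
        else:
            X = np.asarray(X, float)
            self.feature_names_in_ = np.asarray(
                [f"x{i}" for i in range(X.shape[1])], dtype=object)
        y = np.asarray(y, float).ravel()
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one row per target value")
        if len(y) == 0:
            raise ValueError("empty training set")
        n, m = X.shape
        k = self.k_features if self.k_features is not None else max(1, m // 3)
        if k >= m and m > 1:
            raise ValueError(f"k_features must be < number of factors ({k} >= {m})")
        k = min(k, m)
        if np.ptp(y) == 0.0:
            warnings.warn("constant response: trees degenerate to a single leaf")
        rng = np.random.default_rng(self.random_state)
        trees = []
        for _ in range(self.n_trees):
            boot = rng.integers(0, n, n)
            trees.append(_build_tree(X, y, boot, k, self.min_leaf, rng))
        self.trees_ = trees
        self.k_ = k
        self.y_min_, self.y_max_ = float(y.min()), float(y.max())
        self.n_features_in_ = m
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "trees_")
        if isinstance(X, pd.DataFrame):
            missing = [f for f in self.feature_names_in_ if f not in X.columns]
            if missing:
                raise KeyError(f"profile is missing model factors {missing}")
            X = X[list(self.feature_names_in_)].to_numpy(float)
        else:
            X = np.asarray(X, float)
            if X.ndim == 1:
                X = X[None, :]
        acc = np.zeros(len(X))
        buf = np.empty(len(X))
        mask = np.ones(len(X), dtype=bool)
        for tree in self.trees_:
            _predict_tree(tree, X, buf, mask)
            acc += buf
        return acc / len(self.trees_)

    # -- portable serialization ------------------------------------------
    def to_json(self) -> str:
        check_is_fitted(self, "trees_")
        return json.dumps({
            "params": self.get_params(),
            "feature_names": list(self.feature_names_in_),
            "y_min": self.y_min_,
            "y_max": self.y_max_,
            "k": self.k_,
            "trees": self.trees_,
        })

    @classmethod
    def from_json(cls, payload: str) -> "BaggedTreeRegressor":
        doc = json.loads(payload)
        model = cls(**doc["params"])
        model.trees_ = doc["trees"]
        model.feature_names_in_ = np.asarray(doc["feature_names"], dtype=object)
        model.y_min_, model.y_max_ = doc["y_min"], doc["y_max"]
        model.k_ = doc["k"]
        model.n_features_in_ = len(doc["feature_names"])
        return model


def random_partition(n_or_records, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Shuffle into 10 near-equal parts; parts 1-7 train, 8-10 test.

    With remainder r, the first r parts receive one extra record. Returns
    (train_idx, test_idx), a disjoint cover of ``range(n)``.
    """
    n = n_or_records if isinstance(n_or_records, (int, np.integer)) else len(n_or_records)
    if n < 10:
        raise ValueError(f"need at least 10 records to form 10 parts, got {n}")
    perm = np.random.default_rng(seed).permutation(n)
    base, r = divmod(n, 10)
    sizes = [base + 1 if p < r else base for p in range(10)]
    bounds = np.cumsum([0] + sizes)
    train = np.concatenate([perm[bounds[p]:bounds[p + 1]] for p in range(7)])
    test = np.concatenate([perm[bounds[p]:bounds[p + 1]] for p in range(7, 10)])
    return train, test


def evaluate(y_true, y_pred) -> tuple[float, float]:
    """(R^2, RMSE) on a held-out set; R^2 is NaN for zero-variance truth."""
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    if len(y_true) == 0:
        raise ValueError("empty evaluation set")
    sse = float(np.sum((y_true - y_pred) ** 2))
    rmse = float(np.sqrt(sse / len(y_true)))
    sst = float(np.sum((y_true - y_true.mean()) ** 2))
    if sst == 0:
        warnings.warn("zero test variance: R^2 undefined")
        return float("nan"), rmse
    return 1.0 - sse / sst, rmse


@dataclass
class RepeatedRunsResult:
    """Averaged performance over repeated train/test runs."""

    runs: pd.DataFrame            # per-run seeds and metrics
    summary: pd.Series            # mean/sd of each metric
    prediction_sd: np.ndarray     # per-record sd of predictions across runs
    prediction_mean: np.ndarray


def repeated_runs(
    table: pd.DataFrame,
    factors: tuple[str, ...] | list[str],
    n_runs: int = 500,
    base_seed: int = 0,
    **hyper,
) -> RepeatedRunsResult:
    """Re-partition, re-train and re-evaluate ``n_runs`` times.

    Run i uses seed ``base_seed + i`` for both the split and the fit.
    Besides averaged R^2/RMSE, the per-record spread of predictions
    across runs is returned (consumed as the EF uncertainty source).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    X = table[list(factors)]
    y = table["ef"].to_numpy(float)
    rows = []
    preds = np.zeros((n_runs, len(table)))
    for i in range(n_runs):
        seed = base_seed + i
        tr, te = random_partition(len(table), seed)
        model = BaggedTreeRegressor(random_state=seed, **hyper)
        model.fit(X.iloc[tr], y[tr])
        r2_tr, rmse_tr = evaluate(y[tr], model.predict(X.iloc[tr]))
        r2_te, rmse_te = evaluate(y[te], model.predict(X.iloc[te]))
        preds[i] = model.predict(X)
        rows.append((i, seed, r2_tr, rmse_tr, r2_te, rmse_te))
    runs = pd.DataFrame(
        rows, columns=["run", "seed", "r2_train", "rmse_train", "r2_test", "rmse_test"])
    metrics = runs[["r2_train", "rmse_train", "r2_test", "rmse_test"]]
    summary = pd.concat([metrics.mean().add_suffix("_mean"),
                         metrics.std(ddof=1).add_suffix("_sd")])
    return RepeatedRunsResult(
        runs=runs,
        summary=summary,
        prediction_sd=preds.std(axis=0, ddof=1) if n_runs > 1 else np.zeros(len(table)),
        prediction_mean=preds.mean(axis=0),
    )


def train_pathway_model(
    table: pd.DataFrame,
    spec: PathwaySpec,
    seed: int = 0,
    **hyper,
) -> BaggedTreeRegressor:
    """Final deployed model: refit on the full pathway table (maximizing
    training data for grid prediction) with a documented seed."""
    model = BaggedTreeRegressor(random_state=seed, **hyper)
    model.fit(table[list(spec.factors)], table["ef"].to_numpy(float))
    return model


def predict_ef(model: BaggedTreeRegressor, profile: pd.DataFrame | pd.Series) -> np.ndarray:
    """Ensemble-mean EF for one or more complete profiles."""
    if isinstance(profile, pd.Series):
        profile = profile.to_frame().T
    return model.predict(profile)
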