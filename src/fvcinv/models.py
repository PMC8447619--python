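"""The four inversion regressors with grid-search tuning.

Multiple linear regression (MLR), a back-propagation neural network
(BPNN: tanh hidden layers, linear output, weight decay 0.01), epsilon-SVR
with an RBF kernel, and a random forest (RF).  Hyper-parameters are tuned
by exhaustive grid search under k-fold cross-validation minimising RMSE.

The stock grids mirror common practice for this problem:

* BPNN — 1-5 hidden layers, 1-10 neurons per layer (weight decay fixed
  at 0.01); the reported optimum architecture is two layers of (2, 4).
* SVR — epsilon 0.01, RBF kernel, gamma 0.5-4 and cost 0.5-8 in steps
  of 0.5; optimum (0.5, 4).
* RF — mtry 1..p and ntree 100-2000 in steps of 100; optimum (13, 1200).

Those reported optima ship as the *default* parameters used when a model
is fitted without tuning; they are starting points, not assertions.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVR

__all__ = [
    "ALGORITHMS",
    "DEFAULT_PARAMS",
    "FvcModel",
    "TunedModel",
    "split_train_test",
    "stock_grid",
    "bpnn_grid",
    "grid_search",
    "fit",
    "predict",
]

ALGORITHMS = ("mlr", "bpnn", "svr", "rf")

#: Documented tuning optima, used as untuned defaults.
DEFAULT_PARAMS = {
    "mlr": {},
    "bpnn": {"hidden_layers": (2, 4)},
    "svr": {"gamma": 0.5, "cost": 4.0, "epsilon": 0.01},
    "rf": {"mtry": 13, "ntree": 1200},
}


def split_train_test(table: pd.DataFrame, train_frac: float = 0.7, seed: int = 0):
    """Seeded random 70/30 partition; train size is ceil(train_frac * n)."""
    n = len(table)
    if n < 10:
        raise ValueError("need at least 10 rows to split")
    if not (0 < train_frac < 1):
        raise ValueError("train_frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = math.ceil(train_frac * n)
    return table.iloc[np.sort(order[:n_train])], table.iloc[np.sort(order[n_train:])]


def bpnn_grid(
    mode: str = "independent", max_layers: int | None = None, max_neurons: int = 10
):
    """Hidden-layer architecture grid for the BPNN.

    ``independent`` enumerates every per-layer neuron combination (the
    optimum (2, 4) is expressible); because that count grows as 10**L it
    defaults to two layers.  ``equal`` uses the same width in every layer
    and covers all five depths.
    """
    if mode == "independent":
        max_layers = 2 if max_layers is None else max_layers
        archs = []
        for layers in range(1, max_layers + 1):
            archs.extend(itertools.product(range(1, max_neurons + 1), repeat=layers))
        return [{"hidden_layers": a} for a in archs]
    if mode == "equal":
        max_layers = 5 if max_layers is None else max_layers
        return [
            {"hidden_layers": (w,) * layers}
            for layers in range(1, max_layers + 1)
            for w in range(1, max_neurons + 1)
        ]
    raise ValueError("mode must be 'independent' or 'equal'")


def stock_grid(algorithm: str, p: int | None = None) -> list[dict]:
    """The stock hyper-parameter grid for one algorithm, in search order.

    ``p`` (the feature count) bounds the RF mtry range.
    """
    if algorithm == "mlr":
        return [{}]
    if algorithm == "bpnn":
        return bpnn_grid()
    if algorithm == "svr":
        gammas = np.arange(0.5, 4.0 + 1e-9, 0.5)
        costs = np.arange(0.5, 8.0 + 1e-9, 0.5)
        return [
            {"gamma": float(g), "cost": float(c), "epsilon": 0.01}
            for g in gammas
            for c in costs
        ]
    if algorithm == "rf":
        if p is None:
            raise ValueError("rf grid needs the feature count p")
        return [
            {"mtry": m, "ntree": t}
            for m in range(1, p + 1)
            for t in range(100, 2001, 100)
        ]
    raise ValueError(f"unknown algorithm {algorithm!r}")


@dataclass
class FvcModel:
    """A fitted regressor plus the feature names it was trained on.

    Prediction aligns columns by name, so the column order of new data
    does not matter; missing columns raise with their names.
    """

    algorithm: str
    params: dict
    feature_names: list
    estimator: object

    def predict(self, X, clip: bool = False) -> np.ndarray:
        X = pd.DataFrame(X)
        missing = [c for c in self.feature_names if c not in X.columns]
        if missing:
            raise KeyError(f"missing feature columns: {missing}")
        pred = np.asarray(self.estimator.predict(X[self.feature_names]), dtype=float)
        if clip:
            pred = np.clip(pred, 0.0, 1.0)
        return pred


@dataclass
class TunedModel:
    """Grid-search outcome: chosen point, its mean CV RMSE, refitted model."""

    algorithm: str
    params: dict
    cv_rmse: float
    model: FvcModel
    cv_results: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)


def _build_estimator(algorithm: str, params: dict, p: int, seed: int):
    rs = int(seed) % (2**31 - 1)
    if algorithm == "mlr":
        return LinearRegression()
    if algorithm == "bpnn":
        return MLPRegressor(
            hidden_layer_sizes=tuple(params.get("hidden_layers", (2, 4))),
            activation="tanh",
            solver="lbfgs",
            alpha=params.get("weight_decay", 0.01),
            max_iter=2000,
            random_state=rs,
        )
    if algorithm == "svr":
        return SVR(
            kernel="rbf",
            gamma=params.get("gamma", 0.5),
            C=params.get("cost", 4.0),
            epsilon=params.get("epsilon", 0.01),
        )
    if algorithm == "rf":
        return RandomForestRegressor(
            n_estimators=int(params.get("ntree", 1200)),
            max_features=min(int(params.get("mtry", 13)), p),
            random_state=rs,
            n_jobs=1,
        )
    raise ValueError(f"unknown algorithm {algorithm!r}")


def fit(
    algorithm: str,
    params: dict | None,
    X,
    y,
    seed: int = 0,
    on_singular: str = "drop",
) -> FvcModel:
    """Fit one regressor with explicit parameters (defaults if None).

    A rank-deficient MLR design (vegetation indices are exact functions
    of the bands, so the full feature table is collinear) is handled as
    R's ``lm`` does — the least-squares solution is still well defined —
    with a warning; ``on_singular="raise"`` turns it into an error.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    if len(X) != len(y):
        raise ValueError("X and y lengths disagree")
    params = dict(DEFAULT_PARAMS[algorithm]) if params is None else dict(params)
    if algorithm == "mlr":
        design = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            if on_singular == "raise":
                raise ValueError("singular design matrix for MLR")
            warnings.warn(
                "rank-deficient MLR design: collinear columns effectively dropped"
            )
    est = _build_estimator(algorithm, params, X.shape[1], seed)
    est.fit(X, y)
    return FvcModel(algorithm, params, list(X.columns), est)


def predict(model: FvcModel, X, clip: bool = False) -> np.ndarray:
    """Predict FVC; columns aligned by name, optional clamp to [0, 1]."""
    return model.predict(X, clip=clip)


def grid_search(
    algorithm: str,
    grid: list[dict] | None,
    X,
    y,
    folds: int = 10,
    seed: int = 0,
) -> TunedModel:
    """Exhaustive grid search by k-fold CV minimising mean RMSE.

    Ties break toward the earlier grid point; the winner is refitted on
    all supplied data.  Fully deterministic under a fixed seed.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    n = len(X)
    if grid is None:
        grid = stock_grid(algorithm, p=X.shape[1])
    if not grid:
        raise ValueError("empty grid")
    if n < folds:
        raise ValueError(f"{folds}-fold CV needs at least {folds} samples")
    kf = KFold(n_splits=folds, shuffle=True, random_state=int(seed) % (2**31 - 1))
    splits = list(kf.split(X))
    if min(len(va) for _, va in splits) < 1 or min(len(tr) for tr, _ in splits) < 2:
        raise ValueError("a fold has too few samples")

    results = []
    best_idx, best_rmse = 0, np.inf
    for i, params in enumerate(grid):
        errs = []
        for k, (tr, va) in enumerate(splits):
            m = fit(algorithm, params, X.iloc[tr], y[tr], seed=seed + 17 * k)
            pred = m.predict(X.iloc[va])
            errs.append(float(np.sqrt(np.mean((y[va] - pred) ** 2))))
        mean_rmse = float(np.mean(errs))
        results.append({"params": dict(params), "cv_rmse": mean_rmse})
        if mean_rmse < best_rmse:
            best_idx, best_rmse = i, mean_rmse
    best_params = dict(grid[best_idx])
    model = fit(algorithm, best_params, X, y, seed=seed)
    return TunedModel(
        algorithm=algorithm,
        params=best_params,
        cv_rmse=best_rmse,
        model=model,
        cv_results=results,
        meta={"seed": seed, "folds": folds, "feature_names": list(X.columns)},
    )
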