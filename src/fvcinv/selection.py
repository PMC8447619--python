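"""Feature selection for FVC inversion: permutation importance, PI-RFE, SFS, Boruta.

Three complementary strategies reduce the 32-column multi-dimensional
feature set before model fitting:

* **PI-RFE** — recursive feature elimination whose per-step ranking is
  *permutation importance* (mean increase in held-out RMSE when one
  feature's values are shuffled) instead of the estimator's built-in
  weights.  Cross-validated RMSE is recorded at every subset size and
  the selected subset is the size with the lowest mean CV RMSE.
* **SFS** — greedy sequential forward selection on cross-validated RMSE.
* **Boruta** — all-relevant selection: each feature competes against
  permuted "shadow" copies inside a random forest; repeated wins/losses
  are judged by a Bonferroni-corrected binomial test.

All three default to a random-forest regressor and are fully seeded:
the same seed reproduces rankings, curves and statuses exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

__all__ = [
    "ImportanceVector",
    "SelectionResult",
    "permutation_importance",
    "pi_rfe",
    "sfs",
    "boruta",
    "default_estimator",
]


def _rmse(y_true, y_pred) -> float:
    return float(np.sqrt(np.mean((np.asarray(y_true) - np.asarray(y_pred)) ** 2)))


def default_estimator(n_estimators: int = 100, random_state: int = 0):
    """The forest regressor used inside all three selectors by default."""
    return RandomForestRegressor(
        n_estimators=n_estimators, random_state=random_state, n_jobs=1
    )


def _seeded_clone(estimator, seed: int):
    est = clone(estimator)
    if "random_state" in est.get_params():
        est.set_params(random_state=int(seed) % (2**31 - 1))
    return est


@dataclass
class ImportanceVector:
    """Permutation importances with the per-repeat raw values retained."""

    feature_names: list
    raw: np.ndarray  # shape (p, repeats): per-repeat RMSE increase
    baseline_rmse: float

    @property
    def importances(self) -> np.ndarray:
        return self.raw.mean(axis=1)

    def ranking(self) -> list:
        order = np.argsort(-self.importances, kind="stable")
        return [self.feature_names[i] for i in order]


@dataclass
class SelectionResult:
    """Outcome of one selection run.

    ``rmse_curve`` maps subset size -> mean cross-validated RMSE (empty
    for Boruta, which judges relevance rather than a size trade-off);
    ``statuses`` is Boruta's confirmed/tentative/rejected verdicts.
    """

    algorithm: str
    ranking: list
    selected: list
    rmse_curve: dict = field(default_factory=dict)
    statuses: dict = field(default_factory=dict)
    subsets: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "ranking": list(self.ranking),
            "selected": list(self.selected),
            "rmse_curve": {int(k): float(v) for k, v in self.rmse_curve.items()},
            "statuses": dict(self.statuses),
        }


def _best_size(curve: dict, fold_curve: dict, size_rule: str) -> int:
    """Pick the selected subset size from the mean-CV-RMSE curve.

    ``"min"`` takes the global minimum, ties (including differences at
    machine precision, as produced by exact-duplicate features) resolved
    toward the smaller subset.  ``"1se"`` takes the smallest size whose
    mean RMSE is within one standard error (over the folds at the
    minimising size) of the minimum — the classic parsimony rule, useful
    because a weak spurious feature can sit below the minimum by less
    than noise.
    """
    lo = min(curve.values())
    if size_rule == "min":
        tol = 1e-9 * max(1.0, lo)
        return min(s for s, v in curve.items() if v <= lo + tol)
    if size_rule == "1se":
        at_min = min(curve, key=lambda s: (curve[s], s))
        folds = np.asarray(fold_curve[at_min])
        se = folds.std(ddof=1) / np.sqrt(len(folds)) if len(folds) > 1 else 0.0
        return min(s for s, v in curve.items() if v <= lo + se)
    raise ValueError("size_rule must be 'min' or '1se'")


def permutation_importance(model, X, y, repeats: int = 10, seed: int = 0) -> ImportanceVector:
    """Mean held-out RMSE increase per feature when that feature is permuted.

    For each feature (in column order) ``repeats`` random permutations of
    its column are scored; importance is the mean of
    ``RMSE(permuted) - RMSE(baseline)``.  The permutation stream is a
    single ``numpy.random.default_rng(seed)`` consumed feature-by-feature,
    repeat-by-repeat, so a fixed seed makes the result exactly
    reproducible (and independently recomputable).
    """
    X = pd.DataFrame(X)
    p = X.shape[1]
    if p == 0:
        raise ValueError("no features to score")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    baseline = _rmse(y, model.predict(X))
    n = len(X)
    arr = X.to_numpy(dtype=float)
    # all permuted copies are stacked and scored in one predict call per
    # chunk — identical numbers to one call per permutation, much faster
    raw = np.empty((p, repeats))
    blocks, owners = [], []
    max_rows = max(n, 200_000 // max(p, 1))
    for j in range(p):
        for r in range(repeats):
            perm = rng.permutation(n)
            Xp = arr.copy()
            Xp[:, j] = arr[perm, j]
            blocks.append(Xp)
            owners.append((j, r))
            if len(blocks) * n >= max_rows or (j == p - 1 and r == repeats - 1):
                big = pd.DataFrame(np.vstack(blocks), columns=X.columns)
                preds = np.asarray(model.predict(big), dtype=float)
                for b, (jj, rr) in enumerate(owners):
                    block_pred = preds[b * n:(b + 1) * n]
                    raw[jj, rr] = _rmse(y, block_pred) - baseline
                blocks, owners = [], []
    return ImportanceVector(list(X.columns), raw, baseline)


def _cv_rmse_and_importance(
    X, y, estimator, cv_folds, fold_seed, imp_seed, repeats, want_importance=True
):
    """K-fold CV: mean validation RMSE and fold-averaged permutation importance.

    The fold partition and the estimator seeds depend only on
    ``fold_seed``, so RMSE values computed for different feature subsets
    are directly comparable: only the columns differ.
    """
    n = len(X)
    folds = min(cv_folds, n)
    kf = KFold(n_splits=folds, shuffle=True, random_state=int(fold_seed) % (2**31 - 1))
    rmses = []
    imp_sum = np.zeros(X.shape[1])
    for k, (tr, va) in enumerate(kf.split(X)):
        est = _seeded_clone(estimator, fold_seed + 1000 + k)
        est.fit(X.iloc[tr], y[tr])
        pred = est.predict(X.iloc[va])
        rmses.append(_rmse(y[va], pred))
        if want_importance:
            iv = permutation_importance(
                est, X.iloc[va].reset_index(drop=True), y[va], repeats=repeats,
                seed=imp_seed + 2000 + k,
            )
            imp_sum += iv.importances
    return rmses, imp_sum / folds


def pi_rfe(
    X,
    y,
    estimator=None,
    step: int = 1,
    cv_folds: int = 10,
    repeats: int = 5,
    seed: int = 0,
    size_rule: str = "min",
) -> SelectionResult:
    """Recursive feature elimination ranked by permutation importance.

    At each subset size the estimator is cross-validated; permutation
    importance is computed on each held-out fold and averaged, and the
    ``step`` least-important features are dropped.  The loop runs down to
    a single feature, so with ``step=1`` the RMSE curve has one entry per
    size ``p .. 1``.  The selected subset is the size with minimum mean
    CV RMSE, ties resolved toward the smaller subset (``size_rule="1se"``
    applies the one-standard-error parsimony rule instead).
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    p = X.shape[1]
    if p < 2:
        raise ValueError("need at least 2 features")
    if step < 1 or step >= p:
        raise ValueError("step must satisfy 1 <= step < p")
    estimator = estimator if estimator is not None else default_estimator()

    remaining = list(X.columns)
    eliminated: list = []
    curve: dict = {}
    fold_curve: dict = {}
    subsets: dict = {}
    final_importance = None
    it = 0
    while True:
        size = len(remaining)
        fold_rmses, imp = _cv_rmse_and_importance(
            X[remaining], y, estimator, cv_folds, seed, seed + 7919 * it, repeats
        )
        curve[size] = float(np.mean(fold_rmses))
        fold_curve[size] = fold_rmses
        subsets[size] = list(remaining)
        final_importance = dict(zip(remaining, imp))
        if size == 1:
            break
        n_drop = min(step, size - 1)
        order = np.argsort(imp, kind="stable")  # least important first
        drop = [remaining[i] for i in order[:n_drop]]
        for name in drop:
            remaining.remove(name)
        eliminated.extend(drop)
        it += 1

    survivors = sorted(remaining, key=lambda f: -final_importance[f])
    ranking = survivors + eliminated[::-1]
    best_size = _best_size(curve, fold_curve, size_rule)
    return SelectionResult(
        algorithm="pi_rfe",
        ranking=ranking,
        selected=subsets[best_size],
        rmse_curve=curve,
        subsets=subsets,
    )


def sfs(
    X,
    y,
    estimator=None,
    cv_folds: int = 10,
    seed: int = 0,
    max_size: int | None = None,
    size_rule: str = "min",
) -> SelectionResult:
    """Greedy sequential forward selection on cross-validated RMSE.

    All sizes ``1 .. p`` (or ``max_size``) are evaluated; the selected
    subset is the prefix with the globally minimal mean CV RMSE, ties
    resolved toward the smaller subset (or the one-standard-error rule
    with ``size_rule="1se"``).
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    p = X.shape[1]
    if p < 1:
        raise ValueError("need at least 1 feature")
    estimator = estimator if estimator is not None else default_estimator()
    limit = p if max_size is None else min(max_size, p)

    chosen: list = []
    pool = list(X.columns)
    curve: dict = {}
    fold_curve: dict = {}
    subsets: dict = {}
    for size in range(1, limit + 1):
        best_feat, best_rmse, best_folds = None, np.inf, None
        for feat in pool:
            folds, _ = _cv_rmse_and_importance(
                X[chosen + [feat]], y, estimator, cv_folds, seed, seed,
                repeats=1, want_importance=False,
            )
            rmse = float(np.mean(folds))
            if rmse < best_rmse:
                best_feat, best_rmse, best_folds = feat, rmse, folds
        chosen.append(best_feat)
        pool.remove(best_feat)
        curve[size] = best_rmse
        fold_curve[size] = best_folds
        subsets[size] = list(chosen)
    best_size = _best_size(curve, fold_curve, size_rule)
    return SelectionResult(
        algorithm="sfs",
        ranking=chosen + pool,
        selected=subsets[best_size],
        rmse_curve=curve,
        subsets=subsets,
    )


def boruta(
    X,
    y,
    estimator=None,
    max_iter: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    importance: str = "permutation",
    repeats: int = 2,
) -> SelectionResult:
    """All-relevant selection against permuted shadow features.

    Each iteration appends a shuffled copy of every original feature
    (the shadow pool stays at size p so the null reference does not
    weaken as features get decided), fits the estimator on the
    still-active features plus the shadows, and counts a *hit* for each
    undecided feature whose importance beats the best shadow.  Two
    one-sided binomial tests at level ``alpha`` (Bonferroni-corrected
    across the original feature count) promote features to confirmed or
    rejected; whatever remains undecided after ``max_iter`` iterations
    is tentative.

    ``importance="permutation"`` (default) fits on a random 70% of the
    rows and scores permutation importance on the held-out 30%, so a
    feature whose association with y is pure in-sample noise gains no
    systematic edge over its shadows.  ``importance="impurity"`` uses
    the forest's built-in split-gain importances instead (faster, but
    biased toward spuriously correlated columns).
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    p = X.shape[1]
    if p < 1:
        raise ValueError("need at least 1 feature")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    estimator = estimator if estimator is not None else default_estimator()
    rng = np.random.default_rng(seed)
    threshold = alpha / p  # Bonferroni across features

    undecided = list(X.columns)
    confirmed: list = []
    rejected: list = []
    hits = {f: 0 for f in X.columns}
    trials = {f: 0 for f in X.columns}
    imp_history = {f: [] for f in X.columns}
    n = len(X)

    for it in range(max_iter):
        active = undecided + confirmed
        if not undecided:
            break
        shadow = {
            f"shadow_{f}": X[f].to_numpy()[rng.permutation(n)] for f in X.columns
        }
        design = pd.concat([X[active], pd.DataFrame(shadow, index=X.index)], axis=1)
        est = _seeded_clone(estimator, seed + 31 * it)
        if importance == "permutation":
            order = rng.permutation(n)
            tr, va = order[: int(0.7 * n)], order[int(0.7 * n):]
            est.fit(design.iloc[tr], y[tr])
            iv = permutation_importance(
                est,
                design.iloc[va].reset_index(drop=True),
                y[va],
                repeats=repeats,
                seed=seed + 977 * it,
            )
            imp = dict(zip(design.columns, iv.importances))
        elif importance == "impurity":
            est.fit(design, y)
            raw = getattr(est, "feature_importances_", None)
            if raw is None:
                raise TypeError("impurity mode needs an estimator with feature_importances_")
            imp = dict(zip(design.columns, raw))
        else:
            raise ValueError("importance must be 'permutation' or 'impurity'")
        shadow_max = max(v for k, v in imp.items() if k.startswith("shadow_"))
        for f in list(undecided):
            imp_history[f].append(imp[f])
            trials[f] += 1
            if imp[f] > shadow_max:
                hits[f] += 1
            k, m = hits[f], trials[f]
            if stats.binom.sf(k - 1, m, 0.5) < threshold:
                undecided.remove(f)
                confirmed.append(f)
            elif stats.binom.cdf(k, m, 0.5) < threshold:
                undecided.remove(f)
                rejected.append(f)

    statuses = {f: "confirmed" for f in confirmed}
    statuses.update({f: "rejected" for f in rejected})
    statuses.update({f: "tentative" for f in undecided})
    mean_imp = {
        f: (float(np.mean(v)) if v else 0.0) for f, v in imp_history.items()
    }
    ranking = sorted(X.columns, key=lambda f: -mean_imp[f])
    return SelectionResult(
        algorithm="boruta",
        ranking=ranking,
        selected=sorted(confirmed, key=lambda f: -mean_imp[f]),
        statuses=statuses,
    )
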