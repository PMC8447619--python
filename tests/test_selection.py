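"""Permutation importance, PI-RFE, SFS and Boruta on controlled inputs.

Small problems use a linear estimator so the selection logic — not the
forest — is what each test exercises; forest-backed behaviour is covered
by the benchmark tests.
"""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold

from fvcinv.selection import (
    boruta,
    default_estimator,
    permutation_importance,
    pi_rfe,
    sfs,
)


def _linear_data(n=120, seed=0, noise=0.1):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame({"x1": rng.standard_normal(n), "x2": rng.standard_normal(n)})
    y = X["x1"].to_numpy() + rng.normal(0, noise, size=n)
    return X, y


# ---------------------------------------------------------------------------
# permutation importance
# ---------------------------------------------------------------------------
def _naive_permutation_importance(model, X, y, repeats, seed):
    """Independent literal re-implementation sharing only the RNG protocol."""
    rng = np.random.default_rng(seed)
    base = float(np.sqrt(np.mean((y - model.predict(X)) ** 2)))
    out = {}
    for col in X.columns:
        diffs = []
        for _ in range(repeats):
            Xp = X.copy()
            Xp[col] = X[col].to_numpy()[rng.permutation(len(X))]
            rm = float(np.sqrt(np.mean((y - model.predict(Xp)) ** 2)))
            diffs.append(rm - base)
        out[col] = diffs
    return out


def test_permutation_importance_matches_bruteforce_oracle():
    X, y = _linear_data(seed=1)
    model = LinearRegression().fit(X, y)
    iv = permutation_importance(model, X, y, repeats=5, seed=99)
    ref = _naive_permutation_importance(model, X, y, repeats=5, seed=99)
    for j, col in enumerate(X.columns):
        assert np.max(np.abs(iv.raw[j] - np.asarray(ref[col]))) < 1e-12


def test_permutation_importance_informative_vs_irrelevant():
    X, y = _linear_data(seed=2, noise=0.05)
    model = LinearRegression().fit(X, y)
    iv = permutation_importance(model, X, y, repeats=10, seed=0)
    imp = dict(zip(iv.feature_names, iv.importances))
    assert imp["x1"] > 0.1
    # irrelevant feature: importance near zero (only its spuriously
    # fitted coefficient contributes)
    assert abs(imp["x2"]) < 0.01


def test_permutation_importance_constant_feature_is_exactly_zero():
    X, y = _linear_data(seed=3)
    X["const"] = 1.0
    model = LinearRegression().fit(X, y)
    iv = permutation_importance(model, X, y, repeats=4, seed=5)
    assert np.all(iv.raw[list(X.columns).index("const")] == 0.0)


def test_permutation_importance_determinism_and_validation():
    X, y = _linear_data(seed=4)
    model = LinearRegression().fit(X, y)
    a = permutation_importance(model, X, y, repeats=3, seed=7)
    b = permutation_importance(model, X, y, repeats=3, seed=7)
    assert np.array_equal(a.raw, b.raw)
    with pytest.raises(ValueError):
        permutation_importance(model, X.iloc[:, :0], y, seed=0)


# ---------------------------------------------------------------------------
# PI-RFE
# ---------------------------------------------------------------------------
def test_pi_rfe_two_features_keeps_the_informative_one():
    """Pure-noise x2 is eliminated first; with the 1-SE parsimony rule the
    selected subset is {x1} (the global-min rule can keep a spurious
    feature whose apparent gain is below noise)."""
    wins = 0
    for seed in range(20):
        X, y = _linear_data(seed=seed)
        res = pi_rfe(
            X, y, estimator=LinearRegression(), cv_folds=5, seed=seed, size_rule="1se"
        )
        if res.ranking == ["x1", "x2"] and res.selected == ["x1"]:
            wins += 1
    assert wins >= 18


def test_pi_rfe_curve_has_one_entry_per_size():
    rng = np.random.default_rng(0)
    X = pd.DataFrame(rng.standard_normal((60, 5)), columns=list("abcde"))
    y = X["a"].to_numpy() + rng.normal(0, 0.1, 60)
    res = pi_rfe(X, y, estimator=LinearRegression(), step=1, cv_folds=4, seed=0)
    assert sorted(res.rmse_curve) == [1, 2, 3, 4, 5]
    assert set(res.selected) <= set(res.ranking)
    # curve minimum is what got selected
    best = min(res.rmse_curve, key=lambda s: (res.rmse_curve[s], s))
    assert len(res.selected) == best


def test_pi_rfe_selected_size_never_worse_than_full_size():
    rng = np.random.default_rng(1)
    X = pd.DataFrame(rng.standard_normal((80, 6)), columns=list("abcdef"))
    y = X["a"].to_numpy() + 0.5 * X["b"].to_numpy() + rng.normal(0, 0.2, 80)
    res = pi_rfe(X, y, estimator=LinearRegression(), cv_folds=5, seed=1)
    best = len(res.selected)
    assert res.rmse_curve[best] <= res.rmse_curve[max(res.rmse_curve)]


def test_pi_rfe_rejects_bad_step():
    X, y = _linear_data()
    with pytest.raises(ValueError):
        pi_rfe(X, y, step=2, estimator=LinearRegression())
    with pytest.raises(ValueError):
        pi_rfe(X[["x1"]], y, estimator=LinearRegression())


def test_pi_rfe_determinism():
    X, y = _linear_data(seed=9)
    a = pi_rfe(X, y, estimator=LinearRegression(), cv_folds=4, seed=3)
    b = pi_rfe(X, y, estimator=LinearRegression(), cv_folds=4, seed=3)
    assert a.ranking == b.ranking and a.rmse_curve == b.rmse_curve


# ---------------------------------------------------------------------------
# SFS
# ---------------------------------------------------------------------------
def test_sfs_orthogonal_informative_features_enter_first():
    rng = np.random.default_rng(0)
    n = 150
    X = pd.DataFrame(rng.standard_normal((n, 5)), columns=list("abcde"))
    y = 1.0 * X["a"].to_numpy() + 0.8 * X["b"].to_numpy() + rng.normal(0, 0.1, n)
    res = sfs(X, y, estimator=LinearRegression(), cv_folds=5, seed=0)
    assert set(res.ranking[:2]) == {"a", "b"}
    assert {"a", "b"} <= set(res.selected)


def test_sfs_first_pick_matches_exhaustive_oracle():
    """The first greedy addition equals the argmin over all single features
    scored with the identical fold protocol."""
    rng = np.random.default_rng(4)
    X = pd.DataFrame(rng.standard_normal((90, 4)), columns=list("abcd"))
    y = X["c"].to_numpy() + rng.normal(0, 0.2, 90)
    seed = 0
    res = sfs(X, y, estimator=LinearRegression(), cv_folds=3, seed=seed)

    def cv_rmse(cols):
        kf = KFold(3, shuffle=True, random_state=seed % (2**31 - 1))
        errs = []
        for tr, va in kf.split(X):
            m = LinearRegression().fit(X[cols].iloc[tr], y[tr])
            errs.append(np.sqrt(np.mean((y[va] - m.predict(X[cols].iloc[va])) ** 2)))
        return float(np.mean(errs))

    scores = {f: cv_rmse([f]) for f in X.columns}
    assert res.ranking[0] == min(scores, key=scores.get)
    assert res.rmse_curve[1] == pytest.approx(scores[res.ranking[0]], abs=1e-12)


def test_sfs_single_feature():
    rng = np.random.default_rng(5)
    X = pd.DataFrame({"only": rng.standard_normal(50)})
    y = X["only"].to_numpy()
    res = sfs(X, y, estimator=LinearRegression(), cv_folds=5, seed=0)
    assert res.selected == ["only"]


def test_sfs_duplicate_feature_not_selected():
    picked_dup = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        x1 = rng.standard_normal(100)
        X = pd.DataFrame({"x1": x1, "x1_copy": x1, "junk": rng.standard_normal(100)})
        y = x1 + rng.normal(0, 0.1, 100)
        res = sfs(X, y, estimator=LinearRegression(), cv_folds=5, seed=seed)
        first = res.ranking[0]
        other = {"x1": "x1_copy", "x1_copy": "x1"}[first]
        if other in res.selected:
            picked_dup += 1
    assert picked_dup <= 2


# ---------------------------------------------------------------------------
# Boruta
# ---------------------------------------------------------------------------
def test_boruta_confirms_signal_rejects_noise():
    """The informative feature is always confirmed; noise columns are
    rejected in nearly all seeds (with only five shadows the null maximum
    is weak, so an occasional spurious confirmation survives)."""
    clean = 0
    for seed in range(5):
        rng = np.random.default_rng(seed)
        n = 300
        x1 = rng.standard_normal(n)
        X = pd.DataFrame({"x1": x1})
        for j in range(5):
            X[f"n{j}"] = rng.uniform(0, 1, n)
        y = 2 * x1 + rng.normal(0, 0.1, n)
        res = boruta(
            X, y, estimator=default_estimator(30, seed), max_iter=40, seed=seed
        )
        assert res.statuses["x1"] == "confirmed"
        n_rej = sum(res.statuses[f"n{j}"] == "rejected" for j in range(5))
        assert n_rej >= 4
        clean += n_rej == 5
    assert clean >= 4


def test_boruta_pure_noise_confirms_nothing():
    """Type-I control: with a reasonable shadow pool (p=20), unrelated
    features are almost never confirmed."""
    confirmed_any = 0
    for seed in range(10):
        rng = np.random.default_rng(100 + seed)
        X = pd.DataFrame(
            rng.uniform(0, 1, size=(150, 20)), columns=[f"f{j}" for j in range(20)]
        )
        y = rng.standard_normal(150)
        res = boruta(
            X, y, estimator=default_estimator(30, seed), max_iter=25, seed=seed
        )
        if res.selected:
            confirmed_any += 1
    assert confirmed_any <= 1


def test_boruta_single_iteration_everything_tentative():
    rng = np.random.default_rng(0)
    X = pd.DataFrame(rng.standard_normal((80, 3)), columns=list("abc"))
    y = X["a"].to_numpy()
    res = boruta(X, y, estimator=default_estimator(20, 0), max_iter=1, seed=0)
    assert all(s == "tentative" for s in res.statuses.values())
    assert res.selected == []


# ---------------------------------------------------------------------------
# cross-algorithm consistency
# ---------------------------------------------------------------------------
def test_selectors_agree_on_informative_features():
    """The intersection of the three selected sets contains every truly
    informative feature in >=9/10 seeds (a feature all algorithms keep is
    'worth attention').  The wrapper selectors use the linear estimator —
    the benchmark response is linear — while Boruta uses its forest."""
    from fvcinv.synthetic import make_selection_benchmark

    hits = 0
    for seed in range(10):
        X, y, info = make_selection_benchmark(
            n=270, n_redundant=2, n_noise=4, seed=300 + seed
        )
        lin = LinearRegression()
        s1 = set(pi_rfe(X, y, estimator=lin, cv_folds=3, repeats=2, seed=seed).selected)
        s2 = set(sfs(X, y, estimator=lin, cv_folds=3, seed=seed).selected)
        bo = boruta(X, y, estimator=default_estimator(30, seed), max_iter=30, seed=seed)
        s3 = {f for f, s in bo.statuses.items() if s in ("confirmed", "tentative")}
        if set(info) <= (s1 & s2 & s3):
            hits += 1
    assert hits >= 9
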