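"""Shapley-value attribution of environmental influence on trait-axis scores.

A random forest models each principal-component axis as a function of the
environmental covariates; interventional (marginal) Shapley values on a
held-out test split then partition each prediction's deviation from the
background expectation among the covariates. For p <= 5 covariates the
exact 2^p coalition enumeration is used; otherwise a permutation
Monte-Carlo estimator (random feature orderings, one background draw per
ordering) whose per-ordering totals telescope so the efficiency axiom holds
up to Monte-Carlo error in the baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .impute import ImputationConfig, make_forest

__all__ = [
    "ShapleyAttribution",
    "fit_axis_model",
    "shapley_values",
    "importance_and_trends",
]


def fit_axis_model(
    scores,
    env: pd.DataFrame,
    holdout: float = 0.15,
    config: ImputationConfig | None = None,
    seed: int = 0,
):
    """Forest fit of axis scores on the environmental covariates with a
    seeded holdout split. Returns (model, X_train, X_test, y_test, test R^2)."""
    y = np.asarray(scores, dtype=float)
    if len(y) < 100:
        raise ValueError("need at least 100 observations to fit an axis model")
    config = config or ImputationConfig()
    X = env.to_numpy(dtype=float)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=holdout, random_state=seed % 2**31
    )
    model = make_forest(config, seed=seed)
    model.fit(X_tr, y_tr)
    r2 = model.score(X_te, y_te)
    return model, X_tr, X_te, y_te, float(r2)


@dataclass
class ShapleyAttribution:
    phi: np.ndarray  # n_test x p
    baseline: float
    importance: np.ndarray  # per covariate, sum |phi|
    ranking: list[int]  # covariate indices, most important first
    feature_names: list[str]
    predictions: np.ndarray
    efficiency_se: np.ndarray  # per-observation MC standard error (0 if exact)
    exact: bool

    def importance_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "covariate": [self.feature_names[j] for j in self.ranking],
                "importance": self.importance[self.ranking],
            }
        )


def _predict(model, X: np.ndarray) -> np.ndarray:
    f = model.predict if hasattr(model, "predict") else model
    out = np.empty(len(X))
    # chunk to bound memory on big hybrid matrices
    step = 200_000
    for s in range(0, len(X), step):
        out[s : s + step] = np.asarray(f(X[s : s + step]), dtype=float).ravel()
    return out


def _exact_shapley(model, X_test, background):
    n, p = X_test.shape
    nb = len(background)
    subsets = []
    for r in range(p + 1):
        subsets.extend(combinations(range(p), r))
    # value of every coalition for every test row: mean over background of
    # the hybrid (x on S, background elsewhere)
    v = {}
    for S in subsets:
        hybrid = np.repeat(background[None, :, :], n, axis=0)  # n x nb x p
        for j in S:
            hybrid[:, :, j] = X_test[:, j][:, None]
        preds = _predict(model, hybrid.reshape(n * nb, p)).reshape(n, nb)
        v[S] = preds.mean(axis=1)
    phi = np.zeros((n, p))
    for S in subsets:
        sset = set(S)
        for j in range(p):
            if j in sset:
                continue
            w = factorial(len(S)) * factorial(p - len(S) - 1) / factorial(p)
            Sj = tuple(sorted(S + (j,)))
            phi[:, j] += w * (v[Sj] - v[S])
    baseline = float(v[()].mean()) if n else 0.0
    # per-observation baseline is v[()] which is constant across rows
    return phi, float(v[()][0]), np.zeros(n)


def _mc_shapley(model, X_test, background, n_perm, rng, bg_batch=8):
    """Random-ordering estimator; each marginal contribution is averaged
    over a small batch of background draws to cut Monte-Carlo variance."""
    n, p = X_test.shape
    nb = len(background)
    bg_batch = min(bg_batch, nb)
    phi = np.zeros((n, p))
    totals = np.zeros((n, n_perm))  # per-ordering efficiency totals
    for k in range(n_perm):
        order = rng.permutation(p)
        b_idx = rng.choice(nb, size=bg_batch, replace=nb < bg_batch)
        H = np.repeat(background[b_idx][None, :, :], n, axis=0)
        prev = _predict(model, H.reshape(-1, p)).reshape(n, bg_batch)
        for j in order:
            H[:, :, j] = X_test[:, j][:, None]
            cur = _predict(model, H.reshape(-1, p)).reshape(n, bg_batch)
            delta = (cur - prev).mean(axis=1)
            phi[:, j] += delta
            totals[:, k] += delta
            prev = cur
    phi /= n_perm
    baseline = float(_predict(model, background).mean())
    se = totals.std(axis=1, ddof=1) / np.sqrt(n_perm)
    return phi, baseline, se


def shapley_values(
    model,
    X_test,
    background,
    n_perm: int = 64,
    seed: int = 0,
    feature_names: list[str] | None = None,
    max_exact_p: int = 5,
    max_background: int = 256,
    bg_batch: int = 16,
) -> ShapleyAttribution:
    """Interventional Shapley values for every test observation.

    ``model`` is anything with ``.predict`` (or a plain callable).
    ``background`` supplies the marginal feature distribution; at most
    ``max_background`` rows are used. Exact coalition enumeration is
    auto-selected for p <= ``max_exact_p``.
    """
    X_test = np.asarray(X_test, dtype=float)
    background = np.asarray(background, dtype=float)
    if background.ndim != 2 or len(background) == 0:
        raise ValueError("background must be a nonempty 2-D array")
    if background.shape[1] != X_test.shape[1]:
        raise ValueError("covariate mismatch between background and X_test")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    if len(background) > max_background:
        background = background[
            rng.choice(len(background), size=max_background, replace=False)
        ]
    p = X_test.shape[1]
    exact = p <= max_exact_p
    if exact:
        phi, baseline, se = _exact_shapley(model, X_test, background)
    else:
        phi, baseline, se = _mc_shapley(
            model, X_test, background, n_perm, rng, bg_batch=bg_batch
        )
    importance = np.abs(phi).sum(axis=0)
    ranking = list(np.argsort(-importance, kind="stable"))
    names = feature_names or [f"x{j + 1}" for j in range(p)]
    return ShapleyAttribution(
        phi=phi,
        baseline=baseline,
        importance=importance,
        ranking=ranking,
        feature_names=list(names),
        predictions=_predict(model, X_test),
        efficiency_se=se,
        exact=exact,
    )


def importance_and_trends(
    attribution: ShapleyAttribution, env_test: np.ndarray | pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Covariate importance ranking plus per-covariate (value, phi) trend
    series with a running-median smooth, for trend plotting."""
    X = (
        env_test.to_numpy(dtype=float)
        if isinstance(env_test, pd.DataFrame)
        else np.asarray(env_test, dtype=float)
    )
    ranking = attribution.importance_frame()
    trends: dict[str, pd.DataFrame] = {}
    n = len(X)
    window = max(5, n // 10)
    for j, name in enumerate(attribution.feature_names):
        order = np.argsort(X[:, j], kind="stable")
        df = pd.DataFrame(
            {"value": X[order, j], "phi": attribution.phi[order, j]}
        )
        df["phi_smooth"] = (
            df["phi"].rolling(window, center=True, min_periods=1).median()
        )
        trends[name] = df
    return ranking, trends
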