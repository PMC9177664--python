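"""Species-weighted principal component analysis of the completed trait
matrix.

Observation weights are 1/n_obs(species), so each species contributes equal
total weight to the trait space while intraspecific variation is retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["AxisResults", "species_weights", "weighted_pca", "n_axes_for_threshold"]


def species_weights(table: pd.DataFrame) -> np.ndarray:
    """Per-observation weights inversely proportional to the species'
    observation count; every species sums to total weight 1."""
    counts = table.groupby("species")["species"].transform("size").to_numpy()
    return 1.0 / counts


@dataclass
class AxisResults:
    """Weighted-PCA loadings, scores, and variance shares.

    ``variance_explained`` covers *all* axes (it sums to 1); ``loadings``
    and ``scores`` are truncated to the requested number of axes. Axes with
    (numerically) zero variance beyond the data rank are flagged.
    """

    trait_names: list[str]
    loadings: np.ndarray  # traits x n_axes
    scores: np.ndarray  # observations x n_axes
    variance_explained: np.ndarray  # all axes, sums to 1
    weights: np.ndarray
    weighted_mean: np.ndarray
    rank_deficient_axes: list[int]

    def loadings_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.loadings.shape[1])]
        return pd.DataFrame(self.loadings, index=self.trait_names, columns=cols)


def weighted_pca(X, w, n_axes: int | None = None) -> AxisResults:
    """Eigendecomposition of the weighted covariance of weighted-mean-centred X.

    Weights are normalized to sum 1 (no small-sample correction); axis sign
    is fixed by making the largest-|loading| trait positive. Accepts a
    DataFrame (trait columns) or array.
    """
    if isinstance(X, pd.DataFrame):
        trait_names = list(X.columns)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        trait_names = [f"trait_{i + 1}" for i in range(Xa.shape[1])]
    if np.isnan(Xa).any():
        raise ValueError("weighted PCA requires a completed matrix (no NaNs)")
    w = np.asarray(w, dtype=float)
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    w = w / w.sum()
    mu = w @ Xa
    Xc = Xa - mu
    C = (Xc * w[:, None]).T @ Xc
    eigval, eigvec = np.linalg.eigh(C)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    eigval = np.clip(eigval, 0.0, None)
    p = Xa.shape[1]
    n_axes = p if n_axes is None else min(n_axes, p)
    for j in range(p):
        i = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[i, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    total = eigval.sum()
    shares = eigval / total if total > 0 else eigval
    tol = max(eigval[0], 1.0) * 1e-12
    deficient = [j for j in range(n_axes) if eigval[j] <= tol]
    return AxisResults(
        trait_names=trait_names,
        loadings=eigvec[:, :n_axes],
        scores=Xc @ eigvec[:, :n_axes],
        variance_explained=shares,
        weights=w,
        weighted_mean=mu,
        rank_deficient_axes=deficient,
    )


def n_axes_for_threshold(variance_explained, threshold: float = 0.75) -> int:
    """Smallest number of leading axes whose cumulative share reaches the
    threshold (e.g. how many axes to cover 75% of trait variation)."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    shares = np.asarray(variance_explained, dtype=float)
    if threshold == 1.0:
        return int((shares > 0).sum())
    return int(np.searchsorted(np.cumsum(shares), threshold) + 1)
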