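"""Functional trait clustering: species-weighted rank correlations,
silhouette-selected hierarchical clusters, and PIC-based correlations that
strip shared-ancestry pseudo-replication.

The clustering distance is 1 - |rho| by default: trait pairs that move
together strongly - in either direction - belong to the same functional
cluster (e.g. specific leaf area and leaf thickness anti-correlate yet sit
on the same leaf-economics axis). A config switch gives the signed 1 - rho
alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .phylo import Phylogeny, pic

__all__ = [
    "ClusterResults",
    "weighted_rank_correlation",
    "correlation_matrix",
    "pic_correlation_matrix",
    "cluster_traits",
    "dendrogram_to_newick",
]


def _weighted_fractional_ranks(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Rank of each value as accumulated weight below it plus half the tied
    weight (reduces to midranks under equal weights)."""
    order = np.argsort(x, kind="stable")
    xs, ws = x[order], w[order]
    ranks_sorted = np.empty_like(ws)
    cum = 0.0
    i = 0
    n = len(xs)
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        tied = ws[i:j].sum()
        ranks_sorted[i:j] = cum + 0.5 * tied
        cum += tied
        i = j
    ranks = np.empty_like(ranks_sorted)
    ranks[order] = ranks_sorted
    return ranks


def _weighted_pearson(x, y, w) -> float:
    w = w / w.sum()
    mx, my = w @ x, w @ y
    cov = w @ ((x - mx) * (y - my))
    vx = w @ ((x - mx) ** 2)
    vy = w @ ((y - my) ** 2)
    if vx == 0 or vy == 0:
        return np.nan
    return float(np.clip(cov / np.sqrt(vx * vy), -1.0, 1.0))


def weighted_rank_correlation(x, y, w) -> float:
    """Weighted Spearman correlation: weighted fractional ranks, then
    weighted Pearson. Pairwise-complete; returns NaN (with a warning) below
    3 complete pairs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if not (len(x) == len(y) == len(w)):
        raise ValueError("x, y, w must have equal length")
    if (w[~np.isnan(x) & ~np.isnan(y)] <= 0).any():
        raise ValueError("weights must be positive")
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 3:
        warnings.warn("fewer than 3 complete pairs; correlation undefined")
        return np.nan
    xr = _weighted_fractional_ranks(x[ok], w[ok])
    yr = _weighted_fractional_ranks(y[ok], w[ok])
    return _weighted_pearson(xr, yr, w[ok])


def correlation_matrix(
    table: pd.DataFrame, traits: list[str], weights
) -> pd.DataFrame:
    """All-pairs species-weighted rank correlation matrix (symmetric, unit
    diagonal)."""
    w = np.asarray(weights, dtype=float)
    p = len(traits)
    C = np.eye(p)
    vals = {t: table[t].to_numpy(dtype=float) for t in traits}
    for i in range(p):
        for j in range(i + 1, p):
            r = weighted_rank_correlation(vals[traits[i]], vals[traits[j]], w)
            C[i, j] = C[j, i] = r
    return pd.DataFrame(C, index=traits, columns=traits)


def pic_correlation_matrix(
    species_means: pd.DataFrame, tree: Phylogeny, through_origin: bool = True
) -> pd.DataFrame:
    """Pairwise correlations among phylogenetic independent contrasts.

    For each trait pair the tree is pruned to the jointly observed species;
    the contrasts correlation is computed through the origin (the standard
    contrasts convention; contrasts have expectation zero under Brownian
    motion). Pairs sharing fewer than 4 species are reported missing.
    """
    traits = list(species_means.columns)
    p = len(traits)
    C = np.eye(p)
    tips = set(tree.tip_labels)
    for i in range(p):
        for j in range(i + 1, p):
            sub = species_means[[traits[i], traits[j]]].dropna()
            shared = [s for s in sub.index if s in tips]
            if len(shared) < 4:
                C[i, j] = C[j, i] = np.nan
                continue
            subtree = tree.subset(shared)
            u = pic(subtree, sub.loc[shared, traits[i]])
            v = pic(subtree, sub.loc[shared, traits[j]])
            if through_origin:
                denom = np.sqrt((u**2).sum() * (v**2).sum())
                r = (u @ v) / denom if denom > 0 else np.nan
            else:
                r = np.corrcoef(u, v)[0, 1]
            C[i, j] = C[j, i] = np.clip(r, -1.0, 1.0)
    return pd.DataFrame(C, index=traits, columns=traits)


@dataclass
class ClusterResults:
    corr: pd.DataFrame
    distance: pd.DataFrame
    linkage_matrix: np.ndarray
    k_opt: int
    labels: pd.Series  # trait -> cluster id
    silhouette: dict[int, float]  # candidate k -> mean silhouette width


def cluster_traits(
    corr_weighted: pd.DataFrame,
    candidate_k=None,
    absolute: bool = True,
) -> ClusterResults:
    """Average-linkage hierarchical clustering of traits on d = 1 - |rho|
    (or 1 - rho with ``absolute=False``); the cluster count maximizing the
    mean silhouette width wins, smaller k on ties."""
    traits = list(corr_weighted.columns)
    p = len(traits)
    R = corr_weighted.to_numpy(dtype=float)
    if np.isnan(R).any():
        raise ValueError("correlation matrix contains missing values")
    D = 1.0 - (np.abs(R) if absolute else R)
    D = np.clip(0.5 * (D + D.T), 0.0, None)
    np.fill_diagonal(D, 0.0)
    off = D[np.triu_indices(p, k=1)]
    if p > 2 and np.allclose(off, off[0]):
        raise ValueError("degenerate (all-equal) trait distances")
    Z = linkage(squareform(D, checks=False), method="average")
    sil: dict[int, float] = {}
    best_k, best_s = None, -np.inf
    if p > 2:
        if candidate_k is None:
            candidate_k = range(2, p)
        for k in candidate_k:
            if not 2 <= k <= p - 1:
                continue
            labels = fcluster(Z, t=k, criterion="maxclust")
            if len(set(labels)) < 2:
                continue
            s = float(silhouette_score(D, labels, metric="precomputed"))
            sil[k] = s
            if s > best_s + 1e-12:
                best_k, best_s = k, s
    if best_k is None:  # p == 2: silhouette undefined, trivial split
        best_k = 2
        sil[2] = np.nan
    labels = pd.Series(
        fcluster(Z, t=best_k, criterion="maxclust"), index=traits, name="cluster"
    )
    return ClusterResults(
        corr=corr_weighted,
        distance=pd.DataFrame(D, index=traits, columns=traits),
        linkage_matrix=Z,
        k_opt=int(best_k),
        labels=labels,
        silhouette=sil,
    )


def dendrogram_to_newick(results: ClusterResults) -> str:
    """Export the trait dendrogram as a Newick string (heights as branch
    lengths)."""
    traits = list(results.corr.columns)
    root = to_tree(results.linkage_matrix)

    def rec(node, parent_height):
        bl = parent_height - node.dist
        if node.is_leaf():
            return f"{traits[node.id]}:{bl:.6f}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{bl:.6f}"

    inner = ",".join(rec(c, root.dist) for c in (root.left, root.right))
    return f"({inner});"
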