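"""Model validation: VEcv and relative-error accuracy metrics, Moran's I
spatial and taxonomic residual autocorrelation, and spatially buffered
leave-one-out cross-validation.

VEcv ("variance explained by cross-validation") scores out-of-fit
predictions against the one-to-one line, 1 - SSE/TSS; unlike a regression
R^2 it can be negative and equals 1 only for perfect prediction. The
buffered CV excludes training rows that share the focal species' genus (or
family) and lie within a fixed haversine radius of any test point, so that
spatial and phylogenetic autocorrelation cannot leak accuracy; the pooled
score is therefore a conservative lower bound.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .impute import ImputationConfig, make_forest

__all__ = [
    "CVResult",
    "Correlogram",
    "vecv",
    "median_relative_abs_error",
    "haversine_km",
    "morans_i",
    "morans_i_correlogram",
    "taxonomic_autocorrelation",
    "buffer_partition",
    "buffered_loocv",
    "random_split_cv",
]

EARTH_RADIUS_KM = 6371.0


def vecv(y_obs, y_pred) -> float:
    """1 - SSE/TSS against the 1:1 line; may be negative."""
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_obs.shape != y_pred.shape or y_obs.ndim != 1 or len(y_obs) < 2:
        raise ValueError("y_obs and y_pred must be equal-length vectors (n >= 2)")
    tss = np.sum((y_obs - y_obs.mean()) ** 2)
    if tss == 0:
        raise ValueError("constant y_obs: TSS = 0, VEcv undefined")
    return float(1.0 - np.sum((y_pred - y_obs) ** 2) / tss)


def median_relative_abs_error(y_obs, y_pred) -> float:
    """Median of |pred - obs| / obs, in percent, on the unlogged scale."""
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if (y_obs <= 0).any():
        raise ValueError("relative error needs strictly positive observations")
    return float(np.median(np.abs(y_pred - y_obs) / y_obs) * 100.0)


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance on a 6371 km sphere; broadcasts."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def morans_i(values: np.ndarray, weights: np.ndarray) -> float:
    """Moran's I with an arbitrary (zero-diagonal) weight matrix."""
    z = np.asarray(values, dtype=float)
    z = z - z.mean()
    W = np.asarray(weights, dtype=float)
    s0 = W.sum()
    if s0 == 0:
        return np.nan
    denom = (z**2).sum()
    if denom == 0:
        return np.nan
    return float(len(z) / s0 * (z @ W @ z) / denom)


@dataclass
class Correlogram:
    bin_mid_km: np.ndarray
    morans_i: np.ndarray  # NaN where a bin has no pairs
    pair_counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_mid_km": self.bin_mid_km,
                "morans_i": self.morans_i,
                "pair_count": self.pair_counts,
            }
        )


def morans_i_correlogram(
    residuals, lat, lon, bin_edges_km
) -> Correlogram:
    """Moran's I per great-circle distance bin (binary pair weights)."""
    z = np.asarray(residuals, dtype=float)
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if len(z) < 10:
        raise ValueError("need at least 10 georeferenced residuals")
    D = haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    if np.all(D[np.triu_indices_from(D, k=1)] == 0):
        raise ValueError("all points at an identical location: degenerate distances")
    edges = np.asarray(bin_edges_km, dtype=float)
    mids, Is, counts = [], [], []
    eye = np.eye(len(z), dtype=bool)
    for lo, hi in zip(edges[:-1], edges[1:]):
        W = ((D >= lo) & (D < hi) & ~eye).astype(float)
        n_pairs = int(W.sum() / 2)
        mids.append(0.5 * (lo + hi))
        counts.append(n_pairs)
        Is.append(morans_i(z, W) if n_pairs > 0 else np.nan)
    return Correlogram(np.array(mids), np.array(Is), np.array(counts))


def taxonomic_autocorrelation(
    residuals, table: pd.DataFrame, ranks=("genus", "family")
) -> dict[str, float]:
    """Moran's I with same-taxon adjacency per taxonomic rank.

    Ranks where every group is a singleton have no adjacent pairs and are
    reported as NaN.
    """
    z = np.asarray(residuals, dtype=float)
    out: dict[str, float] = {}
    for rank in ranks:
        if rank not in table.columns:
            raise ValueError(f"rank column {rank!r} missing")
        codes = pd.factorize(table[rank].to_numpy())[0]
        W = (codes[:, None] == codes[None, :]).astype(float)
        np.fill_diagonal(W, 0.0)
        out[rank] = morans_i(z, W) if W.sum() > 0 else np.nan
    return out


def buffer_partition(
    table: pd.DataFrame,
    focal_species: str,
    trait: str,
    rank: str = "genus",
    radius_km: float = 250.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Test rows = the focal species' trait observations; training rows
    exclude the focal species entirely, plus any same-rank relative within
    ``radius_km`` (haversine) of any test point. Rows farther than the
    radius are retained (strict > comparison)."""
    observed = table[trait].notna().to_numpy()
    is_focal = (table["species"] == focal_species).to_numpy()
    test_idx = np.flatnonzero(is_focal & observed)
    if len(test_idx) == 0:
        raise ValueError(f"focal species {focal_species!r} has no {trait!r} values")
    focal_taxa = set(table.loc[test_idx, rank])
    same_taxon = table[rank].isin(focal_taxa).to_numpy()
    lat = table["lat"].to_numpy(dtype=float)
    lon = table["lon"].to_numpy(dtype=float)
    d_to_test = haversine_km(
        lat[:, None], lon[:, None], lat[test_idx][None, :], lon[test_idx][None, :]
    )
    near = np.nanmin(d_to_test, axis=1) <= radius_km
    train_mask = observed & ~is_focal & ~(same_taxon & near)
    return test_idx, np.flatnonzero(train_mask)


@dataclass
class CVResult:
    trait: str
    y_obs: np.ndarray
    y_pred: np.ndarray
    vecv: float
    mrae_unlogged: float | None
    n_iterations: int
    iterations: list[dict] = field(default_factory=list, repr=False)

    def to_json_dict(self) -> dict:
        return {
            "trait": self.trait,
            "vecv": self.vecv,
            "mrae_unlogged": self.mrae_unlogged,
            "n_iterations": self.n_iterations,
            "iterations": [
                {k: v for k, v in it.items() if k not in ("y_obs", "y_pred")}
                for it in self.iterations
            ],
        }


def buffered_loocv(
    table: pd.DataFrame,
    trait: str,
    covariate_cols: list[str],
    config: ImputationConfig,
    n_iter: int = 1000,
    rank: str = "genus",
    radius_km: float = 250.0,
    seed: int = 0,
    unlog=None,
) -> CVResult:
    """Buffered leave-one-species-out CV, pooled-then-scored.

    Focal species are sampled without replacement (up to ``n_iter``); each
    iteration refits the forest on the buffered training set and predicts
    the focal species' rows. All out-of-fit (obs, pred) pairs are pooled
    into a single VEcv, matching the metric's single-summation form.
    ``unlog``, if given, maps values back to the raw scale for the median
    relative absolute error.
    """
    observed = table[trait].notna()
    species = table.loc[observed, "species"].unique()
    if len(species) < 2:
        raise ValueError(f"trait {trait!r}: fewer than 2 species with values")
    rng = np.random.default_rng(seed)
    order = rng.permutation(species)[: min(n_iter, len(species))]
    pooled_obs, pooled_pred, iters = [], [], []
    for i, sp in enumerate(order):
        test_idx, train_idx = buffer_partition(table, sp, trait, rank, radius_km)
        if len(train_idx) < max(10, config.min_node):
            warnings.warn(f"species {sp!r}: empty/tiny buffered training set; skipped")
            continue
        X_tr = table.loc[train_idx, covariate_cols].to_numpy()
        y_tr = table.loc[train_idx, trait].to_numpy()
        X_te = table.loc[test_idx, covariate_cols].to_numpy()
        y_te = table.loc[test_idx, trait].to_numpy()
        forest = make_forest(config, seed=(seed + 7919 * i) % 2**31)
        forest.fit(X_tr, y_tr)
        pred = forest.predict(X_te)
        pooled_obs.append(y_te)
        pooled_pred.append(pred)
        iters.append(
            {
                "focal_species": str(sp),
                "n_test": int(len(test_idx)),
                "n_train_excluded": int(observed.sum() - len(test_idx) - len(train_idx)),
                "y_obs": y_te,
                "y_pred": pred,
            }
        )
    y_obs = np.concatenate(pooled_obs)
    y_pred = np.concatenate(pooled_pred)
    mrae = None
    if unlog is not None:
        mrae = median_relative_abs_error(unlog(y_obs), unlog(y_pred))
    return CVResult(
        trait=trait,
        y_obs=y_obs,
        y_pred=y_pred,
        vecv=vecv(y_obs, y_pred),
        mrae_unlogged=mrae,
        n_iterations=len(iters),
        iterations=iters,
    )


def random_split_cv(
    table: pd.DataFrame,
    trait: str,
    covariate_cols: list[str],
    config: ImputationConfig,
    n_folds: int = 5,
    seed: int = 0,
) -> CVResult:
    """Plain observation-level k-fold CV (no buffering) for comparison."""
    observed = table[trait].notna()
    sub = table.loc[observed]
    X = sub[covariate_cols].to_numpy()
    y = sub[trait].to_numpy()
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed % 2**31)
    y_pred = np.empty_like(y)
    for i, (tr, te) in enumerate(kf.split(X)):
        forest = make_forest(config, seed=(seed + 104729 * i) % 2**31)
        forest.fit(X[tr], y[tr])
        y_pred[te] = forest.predict(X[te])
    return CVResult(
        trait=trait,
        y_obs=y,
        y_pred=y_pred,
        vecv=vecv(y, y_pred),
        mrae_unlogged=None,
        n_iterations=n_folds,
    )
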