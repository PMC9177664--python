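"""Random-forest trait imputation: covariate selection, the two-step
trait-covariance refit, conditional 90th-percentile estimation for size
traits, phylogeny-only vs combined model selection, and permutation-based
relative importance of environment vs phylogeny.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance

from .phylo import EigenBasis
from .traitio import TraitConfig

__all__ = [
    "ImputationConfig",
    "FittedTraitModel",
    "ImputedTable",
    "make_forest",
    "attach_phylo_covariates",
    "select_covariates",
    "fit_stage1",
    "predict_all",
    "two_step_impute",
    "quantile_impute_q90",
    "select_model_family",
    "relative_importance",
]


@dataclass
class ImputationConfig:
    """Forest hyperparameters and imputation behaviour.

    Forest defaults follow the ranger defaults for regression: 500 trees,
    bootstrap sampling with replacement, sqrt(p) candidate variables per
    split, minimum node size 5, variance split rule.
    """

    n_trees: int = 500
    min_node: int = 5
    mtry: int | None = None  # None -> floor(sqrt(p))
    k_phylo: int = 10
    k_env: int = 10
    min_obs: int = 30
    seed: int = 0
    stage2_use_observed: bool = False
    n_jobs: int = 1

    def __post_init__(self) -> None:
        if min(self.n_trees, self.min_node, self.min_obs) <= 0:
            raise ValueError("forest hyperparameters must be positive")


def make_forest(config: ImputationConfig, seed: int) -> RandomForestRegressor:
    return RandomForestRegressor(
        n_estimators=config.n_trees,
        min_samples_leaf=config.min_node,
        max_features=config.mtry if config.mtry is not None else "sqrt",
        bootstrap=True,
        random_state=int(seed) % 2**31,
        n_jobs=config.n_jobs,
    )


def _stage_seed(base: int, tag: str) -> int:
    import hashlib

    h = hashlib.sha256(f"{base}:{tag}".encode()).digest()
    return int.from_bytes(h[:4], "little") % 2**31


def attach_phylo_covariates(table: pd.DataFrame, basis: EigenBasis) -> pd.DataFrame:
    """Merge per-species eigenvector coordinates into the observation table."""
    ev = basis.to_frame()
    missing = set(table["species"]) - set(ev.index)
    if missing:
        raise ValueError(f"species absent from eigenbasis: {sorted(missing)[:5]} ...")
    out = table.copy()
    for col in ev.columns:
        out[col] = ev.loc[out["species"], col].to_numpy()
    return out


def select_covariates(
    basis: EigenBasis | pd.DataFrame,
    env: pd.DataFrame,
    k_phylo: int,
    k_env: int,
) -> tuple[list[str], list[str]]:
    """First ``k_phylo`` eigenvectors plus one representative environmental
    variable per correlation cluster.

    Environmental variables are grouped by average-linkage clustering of
    1 - |Pearson rho| and each cluster is represented by its medoid (the
    member with the largest mean |rho| to its own cluster), which minimizes
    redundancy among the retained covariates. Ties break by column order.
    """
    ev = basis.to_frame() if isinstance(basis, EigenBasis) else basis
    if k_phylo > ev.shape[1]:
        raise ValueError(f"k_phylo={k_phylo} exceeds {ev.shape[1]} eigenvectors")
    if k_env > env.shape[1]:
        raise ValueError(f"k_env={k_env} exceeds {env.shape[1]} env variables")
    phylo_cols = list(ev.columns[:k_phylo])

    cols = list(env.columns)
    if k_env == len(cols):
        return phylo_cols, cols
    C = np.abs(np.corrcoef(env.to_numpy(), rowvar=False))
    C = np.nan_to_num(C, nan=0.0)
    np.fill_diagonal(C, 1.0)
    D = 1.0 - C
    D = 0.5 * (D + D.T)
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    labels = fcluster(Z, t=k_env, criterion="maxclust")
    chosen: list[str] = []
    for g in sorted(set(labels)):
        members = np.flatnonzero(labels == g)
        if len(members) == 1:
            chosen.append(cols[members[0]])
            continue
        sub = C[np.ix_(members, members)]
        mean_abs = (sub.sum(1) - 1.0) / (len(members) - 1)
        chosen.append(cols[members[int(np.argmax(mean_abs))]])
    return phylo_cols, sorted(chosen, key=cols.index)


@dataclass
class FittedTraitModel:
    trait: str
    covariates: list[str]
    forest: RandomForestRegressor
    oob_score: float
    family: str  # "phylo-only" | "phylo+env"
    quantile: bool = False
    importances: dict[str, float] = field(default_factory=dict)
    covariate_groups: dict[str, str] = field(default_factory=dict)


def fit_stage1(
    table: pd.DataFrame,
    covariate_cols: list[str],
    traits: list[str],
    config: ImputationConfig,
    family: str = "phylo+env",
    compute_importances: bool = False,
) -> dict[str, FittedTraitModel]:
    """One forest per trait on its observed rows; out-of-bag R^2 recorded.

    Traits with fewer than ``config.min_obs`` observed values are skipped
    with a warning.
    """
    models: dict[str, FittedTraitModel] = {}
    groups = {
        c: ("phylo" if c.startswith("phylo_ev") else "env") for c in covariate_cols
    }
    for trait in traits:
        if trait not in table.columns:
            continue
        obs = table[trait].notna()
        for c in covariate_cols:
            obs &= table[c].notna()
        n = int(obs.sum())
        if n < config.min_obs:
            warnings.warn(
                f"trait {trait!r}: only {n} observations (< {config.min_obs}); skipped"
            )
            continue
        X = table.loc[obs, covariate_cols].to_numpy()
        y = table.loc[obs, trait].to_numpy()
        forest = make_forest(config, _stage_seed(config.seed, f"stage1:{trait}"))
        forest.set_params(oob_score=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # oob on tiny data
            forest.fit(X, y)
        model = FittedTraitModel(
            trait=trait,
            covariates=list(covariate_cols),
            forest=forest,
            oob_score=float(getattr(forest, "oob_score_", np.nan)),
            family=family,
            covariate_groups=groups,
        )
        if compute_importances:
            res = permutation_importance(
                forest,
                X,
                y,
                n_repeats=3,
                random_state=_stage_seed(config.seed, f"perm:{trait}"),
                scoring="neg_mean_squared_error",
            )
            model.importances = dict(zip(covariate_cols, res.importances_mean))
        models[trait] = model
    return models


def predict_all(
    models: dict[str, FittedTraitModel], table: pd.DataFrame
) -> pd.DataFrame:
    """Model predictions for every trait at every observation."""
    out = {}
    for trait, m in models.items():
        X = table[m.covariates].to_numpy()
        out[trait] = m.forest.predict(X)
    return pd.DataFrame(out, index=table.index)


@dataclass
class ImputedTable:
    """Completed trait table with per-cell provenance.

    Observed cells always carry their input value exactly; missing focal
    cells are filled with stage-2 forest means, or conditional 90th
    percentiles for quantile-flagged size traits.
    """

    table: pd.DataFrame
    provenance: pd.DataFrame  # {"observed", "imputed-mean", "imputed-q90"}
    stage1_models: dict[str, FittedTraitModel]
    stage2_models: dict[str, FittedTraitModel]
    stage1_predictions: pd.DataFrame
    stage2_predictions: pd.DataFrame


def two_step_impute(
    table: pd.DataFrame,
    phylo_cols: list[str],
    env_cols: list[str],
    trait_config: TraitConfig,
    config: ImputationConfig,
    compute_importances: bool = False,
) -> ImputedTable:
    """Two-step gap filling.

    Step 1 fits every trait (focal and ancillary) on the phylogenetic and
    environmental covariates alone, then predicts all traits for all
    observations. Step 2 refits each focal trait adding the other traits'
    step-1 predictions as covariates, transferring information across
    traits' disjoint observation sets. Observed values take precedence in
    the output; quantile-flagged traits are filled by
    :func:`quantile_impute_q90` instead of the forest mean.
    """
    base_cols = list(phylo_cols) + list(env_cols)
    traits_all = [t for t in trait_config.all_traits if t in table.columns]
    focal = [t for t in trait_config.focal_traits if t in table.columns]
    stage1 = fit_stage1(table, base_cols, traits_all, config,
                        compute_importances=compute_importances)
    p1 = predict_all(stage1, table)
    p1 = p1.rename(columns={t: f"pred_{t}" for t in p1.columns})

    work = pd.concat([table, p1], axis=1)
    if config.stage2_use_observed:
        for t in stage1:
            obs = table[t].notna()
            work.loc[obs, f"pred_{t}"] = table.loc[obs, t]

    stage2: dict[str, FittedTraitModel] = {}
    p2 = {}
    q90 = {}
    for trait in focal:
        if trait not in stage1:
            continue  # propagate stage-1 skip
        extra = [f"pred_{t}" for t in stage1 if t != trait]
        covs = base_cols + extra
        obs = work[trait].notna()
        X = work.loc[obs, covs].to_numpy()
        y = work.loc[obs, trait].to_numpy()
        forest = make_forest(config, _stage_seed(config.seed, f"stage2:{trait}"))
        forest.fit(X, y)
        stage2[trait] = FittedTraitModel(
            trait=trait,
            covariates=covs,
            forest=forest,
            oob_score=np.nan,
            family="phylo+env",
            quantile=trait in trait_config.quantile_traits,
            covariate_groups={
                c: (
                    "phylo"
                    if c.startswith("phylo_ev")
                    else ("trait" if c.startswith("pred_") else "env")
                )
                for c in covs
            },
        )
        p2[trait] = forest.predict(work[covs].to_numpy())
        if trait in trait_config.quantile_traits:
            q90[trait] = quantile_impute_q90(work, trait, covs, config)

    p2 = pd.DataFrame(p2, index=table.index)
    completed = table.copy()
    prov = pd.DataFrame("observed", index=table.index, columns=focal)
    for trait in focal:
        if trait not in p2.columns:
            continue
        miss = completed[trait].isna()
        if trait in q90:
            completed.loc[miss, trait] = q90[trait][miss.to_numpy()]
            prov.loc[miss, trait] = "imputed-q90"
        else:
            completed.loc[miss, trait] = p2.loc[miss, trait]
            prov.loc[miss, trait] = "imputed-mean"
    return ImputedTable(
        table=completed,
        provenance=prov,
        stage1_models=stage1,
        stage2_models=stage2,
        stage1_predictions=p1,
        stage2_predictions=p2,
    )


def quantile_impute_q90(
    table: pd.DataFrame,
    trait: str,
    covariate_cols: list[str],
    config: ImputationConfig,
    q: float = 0.90,
    X_predict: np.ndarray | None = None,
) -> np.ndarray:
    """Conditional ``q``-quantile from a forest's leaf-value distribution.

    A quantile regression forest: the forest is grown as usual, then each
    prediction pools the training responses co-resident in the target row's
    leaves, weighted 1/leaf-size per tree, and takes the weighted quantile.
    """
    obs = table[trait].notna()
    X_train = table.loc[obs, covariate_cols].to_numpy()
    y_train = table.loc[obs, trait].to_numpy()
    if len(y_train) < config.min_obs:
        raise ValueError(f"trait {trait!r}: too few observations for a forest")
    forest = make_forest(config, _stage_seed(config.seed, f"q90:{trait}"))
    forest.fit(X_train, y_train)
    if X_predict is None:
        X_predict = table[covariate_cols].to_numpy()

    n_train, n_pred = len(y_train), len(X_predict)
    leaf_train = forest.apply(X_train)
    leaf_pred = forest.apply(X_predict)
    W = np.zeros((n_pred, n_train))
    for t in range(leaf_train.shape[1]):
        lt, lp = leaf_train[:, t], leaf_pred[:, t]
        order = np.argsort(lt, kind="stable")
        uniq, starts = np.unique(lt[order], return_index=True)
        members = {
            u: order[s:e]
            for u, s, e in zip(uniq, starts, list(starts[1:]) + [n_train])
        }
        for leaf_id in np.unique(lp):
            rows = np.flatnonzero(lp == leaf_id)
            m = members.get(leaf_id)
            if m is None or len(m) == 0:
                continue
            W[np.ix_(rows, m)] += 1.0 / len(m)
    W /= W.sum(axis=1, keepdims=True)
    ys_order = np.argsort(y_train, kind="stable")
    ys = y_train[ys_order]
    cum = np.cumsum(W[:, ys_order], axis=1)
    idx = np.minimum((cum < q).sum(axis=1), n_train - 1)
    return ys[idx]


def covariate_sweep(
    table: pd.DataFrame,
    basis: EigenBasis,
    env: pd.DataFrame,
    traits: list[str],
    config: ImputationConfig,
    ks=(3, 5, 10, 15, 25, 50),
) -> pd.DataFrame:
    """Diagnostic sweep over the number of covariates per source.

    For each k, selects k eigenvectors + k environmental representatives
    and records each trait's out-of-bag R^2. Accuracy typically saturates
    around k = 10, the default. k values exceeding availability are
    skipped.
    """
    rows = []
    for k in ks:
        if k > basis.vectors.shape[1] or k > env.shape[1]:
            continue
        pc, ec = select_covariates(basis, env, k, k)
        models = fit_stage1(table, pc + ec, traits, config)
        for t, m in models.items():
            rows.append({"k": k, "trait": t, "oob_r2": m.oob_score})
    return pd.DataFrame(rows)


def select_model_family(
    table: pd.DataFrame,
    trait: str,
    phylo_cols: list[str],
    env_cols: list[str],
    config: ImputationConfig,
    n_iter: int = 20,
    rank: str = "genus",
    radius_km: float = 250.0,
) -> dict:
    """Pick phylogeny-only vs phylogeny+environment by buffered-CV VEcv.

    Ties go to the combined model (richer covariates). Returns the chosen
    family plus both CV scores.
    """
    from .validate import buffered_loocv  # local import avoids a cycle

    # identical seed so both families face the same focal-species sample
    # (a paired comparison)
    fold_seed = _stage_seed(config.seed, f"family:{trait}")
    cv_phylo = buffered_loocv(
        table, trait, phylo_cols, config,
        n_iter=n_iter, rank=rank, radius_km=radius_km, seed=fold_seed,
    )
    cv_comb = buffered_loocv(
        table, trait, phylo_cols + env_cols, config,
        n_iter=n_iter, rank=rank, radius_km=radius_km, seed=fold_seed,
    )
    family = "phylo-only" if cv_phylo.vecv > cv_comb.vecv else "phylo+env"
    return {
        "trait": trait,
        "family": family,
        "vecv_phylo_only": cv_phylo.vecv,
        "vecv_combined": cv_comb.vecv,
    }


def relative_importance(
    models: dict[str, FittedTraitModel]
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Environment vs phylogeny share of permutation importance.

    Negative importances are floored at zero; shares are normalized over
    the phylo+env covariates per trait and averaged (unweighted) across
    traits for the overall split. Traits whose importances are all zero are
    reported missing.
    """
    rows = []
    for trait, m in models.items():
        if not m.importances:
            continue
        s = {"phylo": 0.0, "env": 0.0}
        for cov, imp in m.importances.items():
            grp = m.covariate_groups.get(cov)
            if grp in s:
                s[grp] += max(imp, 0.0)
        tot = s["phylo"] + s["env"]
        if tot == 0:
            rows.append({"trait": trait, "phylo_share": np.nan, "env_share": np.nan})
        else:
            rows.append(
                {
                    "trait": trait,
                    "phylo_share": s["phylo"] / tot,
                    "env_share": s["env"] / tot,
                }
            )
    df = pd.DataFrame(rows)
    overall = {
        "phylo_share": float(df["phylo_share"].mean()),
        "env_share": float(df["env_share"].mean()),
    }
    return df, overall
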