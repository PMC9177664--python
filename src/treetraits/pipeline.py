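"""Pipeline orchestration: simulate -> impute -> validate -> axes ->
attribute -> cluster, with a single master seed split deterministically per
stage, manifests recording inputs, and delimited-text outputs throughout.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .axes import n_axes_for_threshold, species_weights, weighted_pca
from .attribution import fit_axis_model, importance_and_trends, shapley_values
from .clusters import (
    cluster_traits,
    correlation_matrix,
    dendrogram_to_newick,
    pic_correlation_matrix,
)
from .impute import (
    ImputationConfig,
    attach_phylo_covariates,
    relative_importance,
    select_covariates,
    two_step_impute,
)
from .phylo import cophenetic_distances, phylo_eigenvectors, read_newick
from .synthetic import apply_missingness, simulate_traits
from .traitio import TraitConfig, load_trait_table, write_trait_table
from .validate import buffered_loocv, random_split_cv

log = logging.getLogger("treetraits.pipeline")

__all__ = ["PipelineConfig", "PipelineError", "run_stage", "run_all", "STAGES"]


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Everything a full run needs; serializable to/from YAML."""

    outdir: str = "results"
    master_seed: int = 0
    # synthetic world
    n_species: int = 200
    n_traits: int = 18
    n_covariates: int = 10
    n_obs: int = 2000
    n_blocks: int = 8
    rho_in: float = 0.7
    rho_out: float = 0.0
    true_lambda: float = 0.6
    missing_rate: float = 0.3
    # imputation
    n_trees: int = 100
    k_phylo: int = 10
    k_env: int = 10
    # cross-validation
    cv_rank: str = "genus"
    cv_radius_km: float = 250.0
    cv_n_iter: int = 10
    # axes / attribution / clustering
    n_axes: int = 7
    variance_threshold: float = 0.75
    n_axes_attrib: int = 2
    shapley_n_perm: int = 16
    shapley_background: int = 128
    shapley_holdout: float = 0.15
    shapley_max_test: int = 150
    traits_are_standardized: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    def imputation_config(self, seed: int) -> ImputationConfig:
        return ImputationConfig(
            n_trees=self.n_trees, k_phylo=self.k_phylo, k_env=self.k_env, seed=seed
        )


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed from the master seed and stage name."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % 2**31


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_manifest(outdir: Path, stage: str, inputs: list[Path], seed: int,
                    outputs: list[Path]) -> None:
    manifest = {
        "stage": stage,
        "seed": seed,
        "version": __version__,
        "inputs": {str(p): _sha256(p) for p in inputs},
        "outputs": [str(p) for p in outputs],
    }
    (outdir / f"manifest_{stage}.json").write_text(json.dumps(manifest, indent=2))


def _require(outdir: Path, fname: str, produced_by: str) -> Path:
    p = outdir / fname
    if not p.exists():
        raise PipelineError(
            f"missing upstream artifact {fname!r}: run the {produced_by!r} stage first"
        )
    return p


def _trait_config(cfg: PipelineConfig, trait_names: list[str]) -> TraitConfig:
    quantile = [
        t
        for t in ("tree_height", "stem_diameter", "crown_height", "crown_diameter",
                  "root_depth")
        if t in trait_names
    ]
    return TraitConfig(
        focal_traits=list(trait_names),
        ancillary_traits=[],
        adult_thresholds={},
        bounds={},
        quantile_traits=quantile,
    )


def _load_world_tables(cfg: PipelineConfig, outdir: Path):
    meta = json.loads(_require(outdir, "world_meta.json", "simulate").read_text())
    trait_names = meta["trait_names"]
    env_names = meta["env_names"]
    tcfg = _trait_config(cfg, trait_names)
    observed = load_trait_table(_require(outdir, "traits_observed.csv", "simulate"), tcfg)
    return meta, trait_names, env_names, tcfg, observed


def stage_simulate(cfg: PipelineConfig) -> dict:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = stage_seed(cfg.master_seed, "simulate")
    world = simulate_traits(
        n_species=cfg.n_species,
        n_traits=cfg.n_traits,
        n_covariates=cfg.n_covariates,
        n_obs=cfg.n_obs,
        n_blocks=cfg.n_blocks,
        rho_in=cfg.rho_in,
        rho_out=cfg.rho_out,
        lam=cfg.true_lambda,
        seed=seed,
    )
    masked, mask = apply_missingness(
        world, cfg.missing_rate, "mcar", seed=stage_seed(cfg.master_seed, "mask")
    )
    (outdir / "tree.nwk").write_text(world.tree.newick() + "\n")
    write_trait_table(masked, outdir / "traits_observed.csv")
    write_trait_table(world.table, outdir / "traits_truth.csv")
    meta = {
        "trait_names": world.trait_names,
        "env_names": world.env_names,
        "true_lambda": world.true_lambda.tolist(),
        "block_of": world.block_of.tolist(),
        "seed": seed,
    }
    (outdir / "world_meta.json").write_text(json.dumps(meta, indent=2))
    _write_manifest(outdir, "simulate", [], seed,
                    [outdir / f for f in
                     ("tree.nwk", "traits_observed.csv", "traits_truth.csv")])
    log.info("simulate: %d obs, %d species, %d traits",
             len(world.table), cfg.n_species, cfg.n_traits)
    return {"n_obs": len(world.table)}


def _covariates(cfg: PipelineConfig, outdir: Path, table: pd.DataFrame,
                env_names: list[str]):
    tree = read_newick(_require(outdir, "tree.nwk", "simulate").read_text())
    dm = cophenetic_distances(tree)
    basis = phylo_eigenvectors(dm, k=min(50, tree.n_tips - 1))
    table = attach_phylo_covariates(table, basis)
    phylo_cols, env_cols = select_covariates(
        basis, table[env_names], cfg.k_phylo, min(cfg.k_env, len(env_names))
    )
    return tree, basis, table, phylo_cols, env_cols


def stage_impute(cfg: PipelineConfig) -> dict:
    outdir = Path(cfg.outdir)
    seed = stage_seed(cfg.master_seed, "impute")
    meta, trait_names, env_names, tcfg, observed = _load_world_tables(cfg, outdir)
    tree, basis, table, phylo_cols, env_cols = _covariates(
        cfg, outdir, observed, env_names
    )
    imputed = two_step_impute(
        table, phylo_cols, env_cols, tcfg,
        cfg.imputation_config(seed), compute_importances=True,
    )
    out_cols = [c for c in observed.columns]
    write_trait_table(imputed.table[out_cols], outdir / "imputed.csv")
    imputed.provenance.to_csv(outdir / "provenance.csv", index=False)
    per_trait, overall = relative_importance(imputed.stage1_models)
    payload = {
        "overall": overall,
        "per_trait": per_trait.to_dict(orient="records"),
        "covariates": {"phylo": phylo_cols, "env": env_cols},
    }
    (outdir / "importances.json").write_text(json.dumps(payload, indent=2))
    _write_manifest(
        outdir, "impute",
        [outdir / "traits_observed.csv", outdir / "tree.nwk"], seed,
        [outdir / f for f in ("imputed.csv", "provenance.csv", "importances.json")],
    )
    log.info("impute: env share %.3f / phylo share %.3f",
             overall["env_share"], overall["phylo_share"])
    return payload


def stage_validate(cfg: PipelineConfig) -> dict:
    outdir = Path(cfg.outdir)
    seed = stage_seed(cfg.master_seed, "validate")
    meta, trait_names, env_names, tcfg, observed = _load_world_tables(cfg, outdir)
    tree, basis, table, phylo_cols, env_cols = _covariates(
        cfg, outdir, observed, env_names
    )
    icfg = cfg.imputation_config(seed)
    results = {}
    dumps = []
    for trait in trait_names:
        cv = buffered_loocv(
            table, trait, phylo_cols + env_cols, icfg,
            n_iter=cfg.cv_n_iter, rank=cfg.cv_rank,
            radius_km=cfg.cv_radius_km, seed=seed,
        )
        rnd = random_split_cv(table, trait, phylo_cols + env_cols, icfg,
                              seed=seed)
        results[trait] = {
            "vecv_buffered": cv.vecv,
            "vecv_random_split": rnd.vecv,
            "n_iterations": cv.n_iterations,
        }
        dumps.append(pd.DataFrame(
            {"trait": trait, "y_obs": cv.y_obs, "y_pred": cv.y_pred}
        ))
    pd.concat(dumps).to_csv(outdir / "cv_predictions.csv", index=False)
    (outdir / "cv.json").write_text(json.dumps(results, indent=2))
    _write_manifest(outdir, "validate",
                    [outdir / "traits_observed.csv", outdir / "tree.nwk"], seed,
                    [outdir / "cv.json", outdir / "cv_predictions.csv"])
    mean_vecv = float(np.mean([r["vecv_buffered"] for r in results.values()]))
    log.info("validate: mean buffered VEcv %.3f", mean_vecv)
    return {"per_trait": results, "mean_vecv_buffered": mean_vecv}


def stage_axes(cfg: PipelineConfig) -> dict:
    outdir = Path(cfg.outdir)
    meta, trait_names, env_names, tcfg, _ = _load_world_tables(cfg, outdir)
    imputed = load_trait_table(_require(outdir, "imputed.csv", "impute"), tcfg)
    w = species_weights(imputed)
    res = weighted_pca(imputed[trait_names], w, n_axes=cfg.n_axes)
    res.loadings_frame().to_csv(outdir / "pca_loadings.csv")
    scores = pd.DataFrame(
        res.scores, columns=[f"PC{i + 1}" for i in range(res.scores.shape[1])]
    )
    scores.insert(0, "obs_id", imputed["obs_id"].to_numpy())
    scores.to_csv(outdir / "pca_scores.csv", index=False)
    pd.DataFrame({"share": res.variance_explained}).to_csv(
        outdir / "pca_variance.csv", index_label="axis"
    )
    n75 = n_axes_for_threshold(res.variance_explained, cfg.variance_threshold)
    summary = {
        "variance_explained": res.variance_explained.tolist(),
        "n_axes_for_threshold": n75,
        "threshold": cfg.variance_threshold,
    }
    (outdir / "axes.json").write_text(json.dumps(summary, indent=2))
    _write_manifest(outdir, "axes", [outdir / "imputed.csv"],
                    stage_seed(cfg.master_seed, "axes"),
                    [outdir / f for f in
                     ("pca_loadings.csv", "pca_scores.csv", "pca_variance.csv")])
    log.info("axes: PC1 %.1f%%, %d axes reach %.0f%%",
             100 * res.variance_explained[0], n75, 100 * cfg.variance_threshold)
    return summary


def stage_attribute(cfg: PipelineConfig) -> dict:
    outdir = Path(cfg.outdir)
    seed = stage_seed(cfg.master_seed, "attribute")
    meta, trait_names, env_names, tcfg, observed = _load_world_tables(cfg, outdir)
    scores = pd.read_csv(_require(outdir, "pca_scores.csv", "axes"))
    imputed = load_trait_table(_require(outdir, "imputed.csv", "impute"), tcfg)
    env = imputed[env_names]
    icfg = cfg.imputation_config(seed)
    rng = np.random.default_rng(seed)
    out = {}
    for ax in range(cfg.n_axes_attrib):
        col = f"PC{ax + 1}"
        model, X_tr, X_te, y_te, r2 = fit_axis_model(
            scores[col].to_numpy(), env, holdout=cfg.shapley_holdout,
            config=icfg, seed=seed + ax,
        )
        if len(X_te) > cfg.shapley_max_test:
            keep = rng.choice(len(X_te), size=cfg.shapley_max_test, replace=False)
            X_te = X_te[keep]
        attr = shapley_values(
            model, X_te, X_tr, n_perm=cfg.shapley_n_perm,
            seed=seed + 31 * ax, feature_names=list(env.columns),
            max_background=cfg.shapley_background,
        )
        ranking, trends = importance_and_trends(attr, X_te)
        ranking.to_csv(outdir / f"shapley_importance_{col}.csv", index=False)
        pd.DataFrame(attr.phi, columns=attr.feature_names).to_csv(
            outdir / f"shapley_values_{col}.csv", index=False
        )
        out[col] = {
            "test_r2": r2,
            "ranking": ranking["covariate"].tolist(),
            "importance": ranking["importance"].tolist(),
        }
    (outdir / "attribution.json").write_text(json.dumps(out, indent=2))
    _write_manifest(outdir, "attribute",
                    [outdir / "pca_scores.csv", outdir / "imputed.csv"], seed,
                    [outdir / "attribution.json"])
    return out


def stage_cluster(cfg: PipelineConfig) -> dict:
    outdir = Path(cfg.outdir)
    meta, trait_names, env_names, tcfg, observed = _load_world_tables(cfg, outdir)
    imputed = load_trait_table(_require(outdir, "imputed.csv", "impute"), tcfg)
    tree = read_newick(_require(outdir, "tree.nwk", "simulate").read_text())
    w = species_weights(imputed)
    corr = correlation_matrix(imputed, trait_names, w)
    # PIC correlations use the *observed* data only (species means), matching
    # the raw-data sensitivity convention
    means = observed.groupby("species")[trait_names].mean()
    corr_pic = pic_correlation_matrix(means, tree)
    res = cluster_traits(corr)
    corr.to_csv(outdir / "corr_weighted.csv")
    corr_pic.to_csv(outdir / "corr_pic.csv")
    res.labels.to_csv(outdir / "cluster_labels.csv")
    pd.Series(res.silhouette, name="mean_silhouette").to_csv(
        outdir / "silhouette.csv", index_label="k"
    )
    (outdir / "dendrogram.nwk").write_text(dendrogram_to_newick(res) + "\n")
    summary = {"k_opt": res.k_opt,
               "labels": {t: int(l) for t, l in res.labels.items()}}
    (outdir / "clusters.json").write_text(json.dumps(summary, indent=2))
    _write_manifest(outdir, "cluster",
                    [outdir / "imputed.csv", outdir / "tree.nwk"],
                    stage_seed(cfg.master_seed, "cluster"),
                    [outdir / f for f in
                     ("corr_weighted.csv", "corr_pic.csv", "cluster_labels.csv",
                      "dendrogram.nwk")])
    log.info("cluster: k_opt = %d", res.k_opt)
    return summary


STAGES = {
    "simulate": stage_simulate,
    "impute": stage_impute,
    "validate": stage_validate,
    "axes": stage_axes,
    "attribute": stage_attribute,
    "cluster": stage_cluster,
}


def run_stage(stage: str, cfg: PipelineConfig) -> dict:
    if stage not in STAGES:
        raise PipelineError(f"unknown stage {stage!r}; choose from {list(STAGES)}")
    return STAGES[stage](cfg)


def run_all(cfg: PipelineConfig) -> dict:
    """End-to-end run; writes summary.json with the headline quantities."""
    outputs = {name: run_stage(name, cfg) for name in STAGES}
    summary = {
        "per_trait_vecv": {
            t: r["vecv_buffered"]
            for t, r in outputs["validate"]["per_trait"].items()
        },
        "mean_vecv_buffered": outputs["validate"]["mean_vecv_buffered"],
        "env_share": outputs["impute"]["overall"]["env_share"],
        "phylo_share": outputs["impute"]["overall"]["phylo_share"],
        "variance_explained": outputs["axes"]["variance_explained"],
        "n_axes_for_threshold": outputs["axes"]["n_axes_for_threshold"],
        "k_opt": outputs["cluster"]["k_opt"],
        "shapley_ranking": {
            ax: v["ranking"] for ax, v in outputs["attribute"].items()
        },
        "master_seed": cfg.master_seed,
    }
    Path(cfg.outdir, "summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def make_fixture(outdir: str, seed: int = 0) -> PipelineConfig:
    """Small packaged world used by the test suite and worked examples."""
    cfg = PipelineConfig(
        outdir=outdir, master_seed=seed,
        n_species=60, n_traits=8, n_covariates=6, n_obs=480, n_blocks=4,
        n_trees=50, k_phylo=6, k_env=4, cv_n_iter=5, n_axes=6,
        shapley_n_perm=8, shapley_max_test=40,
    )
    stage_simulate(cfg)
    return cfg
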