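"""Observation-level trait tables: loading, adult-tree/outlier filtering, and
reversible log-standardization.

A trait table is a plain :class:`pandas.DataFrame` with one row per
observation: an ``obs_id``, taxonomy columns (``species``, ``genus``,
``family``), WGS84 coordinates (``lat``, ``lon``), one column per trait
(missing values as NaN) and any number of environmental covariate columns.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TraitIOError",
    "TraitConfig",
    "StandardizationParams",
    "FilterReport",
    "FOCAL_TRAITS",
    "ANCILLARY_TRAITS",
    "load_trait_table",
    "write_trait_table",
    "apply_filters",
    "log_standardize",
    "inverse_transform",
]


class TraitIOError(ValueError):
    pass


# The 18 focal traits of the main analysis. Size traits are in metres;
# leaf-economics traits in their customary units (labels only - no unit
# conversion is attempted here).
FOCAL_TRAITS: list[str] = [
    "leaf_area",
    "specific_leaf_area",
    "seed_dry_mass",
    "tree_height",
    "leaf_nitrogen",
    "wood_density",
    "leaf_thickness",
    "leaf_density",
    "vcmax",
    "leaf_phosphorus",
    "leaf_potassium",
    "stomatal_conductance",
    "root_depth",
    "conduit_diameter",
    "stem_diameter",
    "bark_thickness",
    "crown_height",
    "crown_diameter",
]

# Extra traits used only as stage-2 covariates to sharpen imputation.
ANCILLARY_TRAITS: list[str] = [
    "leaf_width",
    "leaf_length",
    "leaf_cn_ratio",
    "leaf_np_ratio",
    "leaf_moisture",
    "root_shoot_ratio",
    "root_nitrogen",
    "root_cn_ratio",
    "wood_nitrogen",
    "leaf_jmax",
    "leaf_respiration",
    "leaf_chlorophyll",
]


@dataclass
class TraitConfig:
    """Which columns are traits, plus per-trait filtering rules.

    ``adult_thresholds`` mask values at or below the threshold (saplings and
    shrubs); ``bounds`` mask values outside an open plausibility interval;
    ``quantile_traits`` are size traits imputed as the conditional 90th
    percentile instead of the forest mean.
    """

    focal_traits: list[str] = field(default_factory=lambda: list(FOCAL_TRAITS))
    ancillary_traits: list[str] = field(
        default_factory=lambda: list(ANCILLARY_TRAITS)
    )
    # metres throughout for the size traits
    adult_thresholds: dict[str, float] = field(
        default_factory=lambda: {
            "tree_height": 5.0,
            "stem_diameter": 0.10,
            "root_depth": 0.25,
            "crown_height": 1.0,
            "crown_diameter": 1.0,
        }
    )
    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"stem_diameter": (0.0, 15.0)}
    )
    quantile_traits: list[str] = field(
        default_factory=lambda: [
            "tree_height",
            "stem_diameter",
            "crown_height",
            "crown_diameter",
            "root_depth",
        ]
    )
    missing_token: str = ""

    def __post_init__(self) -> None:
        overlap = set(self.focal_traits) & set(self.ancillary_traits)
        if overlap:
            raise TraitIOError(f"focal and ancillary traits overlap: {overlap}")
        for t, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise TraitIOError(f"bounds for {t} must satisfy lower < upper")

    @property
    def all_traits(self) -> list[str]:
        return self.focal_traits + self.ancillary_traits


MANDATORY_COLUMNS = ("obs_id", "species")


def load_trait_table(
    path, config: TraitConfig, delimiter: str | None = None
) -> pd.DataFrame:
    """Read a delimited trait table (comma/tab autodetected).

    Unknown columns are preserved untouched; configured trait columns are
    coerced to numeric with row-numbered errors on unparseable cells.
    """
    df = pd.read_csv(
        path,
        sep=delimiter,
        engine="python" if delimiter is None else "c",
        na_values=[config.missing_token] if config.missing_token else None,
        keep_default_na=True,
        dtype={"obs_id": str, "species": str, "genus": str, "family": str},
    )
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise TraitIOError(f"mandatory column {col!r} missing from {path}")
    if df["obs_id"].duplicated().any():
        dup = df.loc[df["obs_id"].duplicated(), "obs_id"].iloc[0]
        raise TraitIOError(f"duplicate obs_id {dup!r}")
    for col in ("lat", "lon"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    if "lat" in df.columns:
        bad = df["lat"].dropna()
        if ((bad < -90) | (bad > 90)).any():
            raise TraitIOError("latitude outside [-90, 90]")
    if "lon" in df.columns:
        bad = df["lon"].dropna()
        if ((bad < -180) | (bad > 180)).any():
            raise TraitIOError("longitude outside [-180, 180]")
    for trait in config.all_traits:
        if trait not in df.columns:
            continue
        coerced = pd.to_numeric(df[trait], errors="coerce")
        newly_bad = coerced.isna() & df[trait].notna()
        if newly_bad.any():
            row = int(np.flatnonzero(newly_bad)[0])
            raise TraitIOError(
                f"unparseable value {df[trait].iloc[row]!r} for trait "
                f"{trait!r} at data row {row + 1}"
            )
        df[trait] = coerced
    return df


def write_trait_table(df: pd.DataFrame, path, delimiter: str = ",") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=delimiter, index=False)


@dataclass
class FilterReport:
    adult_filter: dict[str, int]
    outlier_bounds: dict[str, int]

    def to_json(self) -> str:
        return json.dumps(
            {"adult_filter": self.adult_filter, "outlier_bounds": self.outlier_bounds},
            indent=2,
        )


def apply_filters(
    df: pd.DataFrame, config: TraitConfig
) -> tuple[pd.DataFrame, FilterReport]:
    """Mask (not drop) values failing adult-tree thresholds or plausibility
    bounds; rows are retained for their other traits. Idempotent."""
    out = df.copy()
    adult_counts: dict[str, int] = {}
    bound_counts: dict[str, int] = {}
    for trait, thr in config.adult_thresholds.items():
        if trait not in out.columns:
            continue
        mask = out[trait].notna() & (out[trait] <= thr)
        adult_counts[trait] = int(mask.sum())
        out.loc[mask, trait] = np.nan
    for trait, (lo, hi) in config.bounds.items():
        if trait not in out.columns:
            continue
        mask = out[trait].notna() & ((out[trait] < lo) | (out[trait] > hi))
        bound_counts[trait] = int(mask.sum())
        out.loc[mask, trait] = np.nan
    return out, FilterReport(adult_filter=adult_counts, outlier_bounds=bound_counts)


@dataclass
class StandardizationParams:
    """Per-trait natural-log mean/sd for the z-transform, plus a count of
    nonpositive raw values that had to be masked before logging."""

    log_mean: dict[str, float]
    log_sd: dict[str, float]
    n_nonpositive_masked: dict[str, int]

    def to_json(self) -> str:
        return json.dumps(
            {
                "log_mean": self.log_mean,
                "log_sd": self.log_sd,
                "n_nonpositive_masked": self.n_nonpositive_masked,
            },
            indent=2,
        )


def log_standardize(
    df: pd.DataFrame, config: TraitConfig, traits: list[str] | None = None
) -> tuple[pd.DataFrame, StandardizationParams]:
    """Natural log then z-score (sample sd, ddof=1) per trait.

    Zero/negative raw values are masked (they are impossible on the log
    scale) and counted, never clamped.
    """
    if traits is None:
        traits = [t for t in config.all_traits if t in df.columns]
    out = df.copy()
    means, sds, masked = {}, {}, {}
    for t in traits:
        vals = out[t]
        nonpos = vals.notna() & (vals <= 0)
        masked[t] = int(nonpos.sum())
        vals = vals.mask(nonpos)
        logged = np.log(vals)
        ok = logged.dropna()
        if len(ok) < 2:
            raise TraitIOError(f"trait {t!r} has fewer than 2 usable values")
        mu, sd = float(ok.mean()), float(ok.std(ddof=1))
        if sd == 0:
            raise TraitIOError(f"trait {t!r} is constant; sd = 0")
        out[t] = (logged - mu) / sd
        means[t], sds[t] = mu, sd
    return out, StandardizationParams(means, sds, masked)


def inverse_transform(df: pd.DataFrame, params: StandardizationParams) -> pd.DataFrame:
    """Undo :func:`log_standardize` (exp(z * sd + mean))."""
    out = df.copy()
    for t, mu in params.log_mean.items():
        if t in out.columns:
            out[t] = np.exp(out[t] * params.log_sd[t] + mu)
    return out
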