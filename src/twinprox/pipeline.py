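"""End-to-end pipeline: preprocessing -> WPPS -> associations -> sensitivity.

``run_pipeline`` either reads a cohort from delimited text files or
simulates one, preprocesses each domain with its recipe, scores all
pairs, runs the covariate / cross-domain / ExWAS analyses, optionally
reruns the exposome-including analyses under the two sensitivity
strategies, and writes tidy CSV results plus a JSON run log (seed,
config echo, per-stage pair counts) and a cohort summary table
(per-domain WPPS mean/sd/range, pair counts by zygosity).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .association import (
    DEFAULT_PRIORITY,
    cross_domain_models,
    exwas,
    wpps_covariate_models,
    zygosity_comparisons,
)
from .prep import (
    FeatureStandardizer,
    InverseNormalTransformer,
    MinimumImputer,
    MissingFeatureFilter,
    build_discordance_table,
)
from .sensitivity import exclude_unity_pairs, remap_and_logit
from .simulate import TwinCohort, default_config, simulate_cohort
from .wpps import compute_wpps, pivot_wpps

__all__ = ["PipelineConfig", "run_pipeline", "ConfigError", "DataError", "DEFAULT_RECIPES"]


class ConfigError(ValueError):
    """Invalid pipeline configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Input data failed validation or a stage (CLI exit code 3)."""


#: Preprocessing recipes by domain name; unknown domains get
#: ["standardize"]. Steps: filter (drop features >10% missing), impute
#: (observed feature minimum), int (inverse-normal rank transform),
#: standardize (mean 0, sd 1).
DEFAULT_RECIPES: dict[str, tuple[str, ...]] = {
    "proteome": ("filter", "impute", "standardize"),
    "metabolome": ("filter", "impute", "int", "standardize"),
    "eaa": ("standardize",),
    "exposome": ("standardize",),
}

_STEPS = {
    "filter": MissingFeatureFilter,
    "impute": MinimumImputer,
    "int": InverseNormalTransformer,
    "standardize": FeatureStandardizer,
}


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    Either ``data_dir`` points at cohort CSVs (pairs.csv, lifestyle.csv,
    one CSV per domain) or ``simulate=True`` generates the default
    synthetic cohort from ``seed``.
    """

    out_dir: str = "results"
    data_dir: str | None = None
    simulate: bool = False
    seed: int = 0
    sigma: float = 1.0
    metric: str = "euclidean"
    max_missing: float = 0.10
    priority: tuple[str, ...] = DEFAULT_PRIORITY
    fdr_family: str = "per-domain"
    q_threshold: float = 0.2
    recipes: dict = field(default_factory=dict)
    sensitivity_logit: bool = True
    sensitivity_exclude_unity: bool = True
    unity_domain: str = "exposome"
    zygosity_code: str = "MZ=1"
    sex_code: str = "F=1"

    def __post_init__(self) -> None:
        if self.data_dir is None and not self.simulate:
            raise ConfigError("either data_dir or simulate must be set")
        if self.data_dir is not None and not Path(self.data_dir).exists():
            raise ConfigError(f"data_dir does not exist: {self.data_dir}")
        if self.metric not in ("euclidean", "manhattan"):
            raise ConfigError(f"unknown metric {self.metric!r}")
        if self.fdr_family not in ("per-domain", "pooled"):
            raise ConfigError(f"unknown fdr_family {self.fdr_family!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "priority" in raw:
            raw["priority"] = tuple(raw["priority"])
        return cls(**raw)


def preprocess_domain(matrix: pd.DataFrame, recipe) -> pd.DataFrame:
    """Apply an ordered preprocessing recipe to one raw domain matrix."""
    out = matrix
    for step in recipe:
        if step not in _STEPS:
            raise ConfigError(f"unknown preprocessing step {step!r}")
        out = _STEPS[step]().fit_transform(out)
    return out


def _summary_table(wpps_wide: pd.DataFrame, pairs: pd.DataFrame) -> pd.DataFrame:
    rows = [
        {
            "quantity": "n_pairs",
            "value": float(len(pairs)),
            "sd": np.nan,
            "min": np.nan,
            "max": np.nan,
        },
        {
            "quantity": "n_pairs_mz",
            "value": float((pairs["zygosity"] == "MZ").sum()),
            "sd": np.nan,
            "min": np.nan,
            "max": np.nan,
        },
        {
            "quantity": "n_pairs_dz",
            "value": float((pairs["zygosity"] == "DZ").sum()),
            "sd": np.nan,
            "min": np.nan,
            "max": np.nan,
        },
    ]
    for domain in wpps_wide.columns:
        s = wpps_wide[domain].dropna()
        rows.append(
            {
                "quantity": f"wpps_{domain}_mean",
                "value": s.mean(),
                "sd": s.std(ddof=1),
                "min": s.min(),
                "max": s.max(),
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the result tables and writes CSVs."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: dict = {
        "seed": config.seed,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "stages": {},
    }

    # --- load or simulate -------------------------------------------------
    try:
        if config.simulate:
            cohort = simulate_cohort(default_config(seed=config.seed))
        else:
            cohort = TwinCohort.from_dir(config.data_dir)
    except (OSError, ValueError) as err:
        raise DataError(f"stage load: {err}") from err
    pairs = cohort.pairs
    log["stages"]["load"] = {
        "n_pairs": int(len(pairs)),
        "domains": {d: list(m.shape) for d, m in cohort.domains.items()},
    }

    # --- preprocessing ----------------------------------------------------
    prepped: dict[str, pd.DataFrame] = {}
    for name, raw in cohort.domains.items():
        recipe = config.recipes.get(name, DEFAULT_RECIPES.get(name, ("standardize",)))
        try:
            prepped[name] = preprocess_domain(raw, recipe)
        except ConfigError:
            raise
        except ValueError as err:
            raise DataError(f"stage prep[{name}]: {err}") from err
    log["stages"]["prep"] = {
        d: {"n_features": int(m.shape[1]), "n_individuals": int(m.shape[0])}
        for d, m in prepped.items()
    }

    # --- WPPS -------------------------------------------------------------
    try:
        wpps_long = pd.concat(
            [
                compute_wpps(m, pairs, sigma=config.sigma, metric=config.metric, domain=d)
                for d, m in prepped.items()
            ],
            ignore_index=True,
        )
    except ValueError as err:
        raise DataError(f"stage wpps: {err}") from err
    wide = pivot_wpps(wpps_long)
    log["stages"]["wpps"] = {
        d: int(wide[d].notna().sum()) for d in wide.columns
    }

    # --- associations -----------------------------------------------------
    try:
        discordance = build_discordance_table(cohort.lifestyle, pairs)
        covariate = wpps_covariate_models(wide, pairs)
        cross = pd.concat(
            [
                cross_domain_models(wide, pairs, subsample=s, priority=config.priority)
                for s in ("all", "MZ", "DZ")
            ],
            ignore_index=True,
        )
        zcomp = zygosity_comparisons(wide, pairs, priority=config.priority)
        exwas_res = exwas(
            wide,
            discordance,
            pairs,
            fdr_family=config.fdr_family,
            q_threshold=config.q_threshold,
        )
    except ValueError as err:
        raise DataError(f"stage association: {err}") from err
    log["stages"]["association"] = {
        "covariate_models": int(len(covariate)),
        "cross_domain_models": int(len(cross)),
        "exwas_tests": int(len(exwas_res)),
    }

    results = {
        "wpps": wpps_long,
        "covariate_models": covariate,
        "cross_domain": cross,
        "zygosity_comparison": zcomp,
        "exwas": exwas_res,
        "summary": _summary_table(wide, pairs),
    }

    # --- sensitivity ------------------------------------------------------
    unity = config.unity_domain
    if config.sensitivity_logit and unity in wide.columns:
        wide_logit = wide.copy()
        mask = wide_logit[unity].notna()
        wide_logit.loc[mask, unity] = remap_and_logit(wide_logit.loc[mask, unity])
        results["sensitivity_logit_cross_domain"] = cross_domain_models(
            wide_logit, pairs, priority=config.priority
        )
        results["sensitivity_logit_exwas"] = exwas(
            wide_logit[[unity]],
            discordance,
            pairs,
            fdr_family=config.fdr_family,
            q_threshold=config.q_threshold,
        )
    if config.sensitivity_exclude_unity and unity in wide.columns:
        trimmed = pivot_wpps(exclude_unity_pairs(wpps_long, domain=unity))
        results["sensitivity_exclude_cross_domain"] = cross_domain_models(
            trimmed, pairs, priority=config.priority
        )
        results["sensitivity_exclude_exwas"] = exwas(
            trimmed[[unity]],
            discordance,
            pairs,
            fdr_family=config.fdr_family,
            q_threshold=config.q_threshold,
        )
        log["stages"]["sensitivity_exclude"] = {
            "pairs_dropped": int(wide[unity].eq(1.0).sum())
        }

    # --- write ------------------------------------------------------------
    for name, table in results.items():
        table.to_csv(out_dir / f"{name}.csv", index=False)
    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=1, default=str)
    results["log"] = log
    return results
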