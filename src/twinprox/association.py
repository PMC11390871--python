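"""Inference on within-pair proximity scores.

Three layers, all ordinary least squares with classical (t-based)
inference:

* covariate models — WPPS of each domain on zygosity (MZ=1), sex (F=1)
  and the pair's age at separation from the familial home, jointly;
* prioritized cross-domain models — for each pair of domains, the
  higher-priority domain's WPPS regressed on the other's, adjusting for
  the absolute within-pair difference in age at blood sampling; with
  zygosity-stratified standardized fits compared by a one-sided z-test
  for bMZ > bDZ (larger genetic effects inflate the MZ coefficient);
* ExWAS — each domain's WPPS on each binary lifestyle-discordance
  indicator plus the age-difference covariate, with Benjamini-Hochberg
  FDR within each domain's family of tests (discussion threshold 0.2).

Results are tidy DataFrames with columns dependent, independent,
estimate, se, statistic, p_nominal, n_pairs, r_squared, subsample
(plus q_fdr / significant for the ExWAS).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "fit_linear",
    "wpps_covariate_models",
    "cross_domain_models",
    "stratified_z_comparison",
    "zygosity_comparisons",
    "exwas",
    "bh_fdr",
    "ZComparisonResult",
    "DEFAULT_PRIORITY",
]

#: Dependent-variable priority for cross-domain models: when two domains
#: are regressed on each other, the one earlier in this list is the
#: dependent variable.
DEFAULT_PRIORITY: tuple[str, ...] = ("exposome", "eaa", "proteome", "metabolome")

RESULT_COLUMNS = [
    "dependent",
    "independent",
    "estimate",
    "se",
    "statistic",
    "p_nominal",
    "n_pairs",
    "r_squared",
    "subsample",
]


def fit_linear(dependent, design, add_intercept: bool = True) -> pd.DataFrame:
    """OLS of ``dependent`` on the columns of ``design``.

    Returns one row per non-intercept coefficient with classical
    standard errors, two-sided t p-values, n and R^2.
    """
    y = np.asarray(dependent, dtype=float)
    X = pd.DataFrame(design).astype(float)
    if add_intercept:
        X = sm.add_constant(X, has_constant="add")
    if y.shape[0] <= X.shape[1] + 1:
        raise ValueError("too few observations for the design")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    fit = sm.OLS(y, X).fit()
    rows = []
    for name in X.columns:
        if name == "const":
            continue
        rows.append(
            {
                "dependent": "y",
                "independent": name,
                "estimate": fit.params[name],
                "se": fit.bse[name],
                "statistic": fit.tvalues[name],
                "p_nominal": fit.pvalues[name],
                "n_pairs": int(fit.nobs),
                "r_squared": fit.rsquared,
                "subsample": "all",
            }
        )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def _pair_covariates(pairs: pd.DataFrame) -> pd.DataFrame:
    cov = pd.DataFrame(index=pairs["pair_id"])
    cov["zygosity_mz"] = (pairs["zygosity"].to_numpy() == "MZ").astype(float)
    cov["sex_f"] = (pairs["sex"].to_numpy() == "F").astype(float)
    cov["age_left_home"] = pairs["age_left_home"].to_numpy(dtype=float)
    cov["age_diff"] = np.abs(
        pairs["age_blood_twin1"].to_numpy(dtype=float)
        - pairs["age_blood_twin2"].to_numpy(dtype=float)
    )
    return cov


def wpps_covariate_models(wpps_wide: pd.DataFrame, pairs: pd.DataFrame) -> pd.DataFrame:
    """Per domain: WPPS ~ zygosity (MZ=1) + sex (F=1) + age at separation.

    All three covariates enter jointly; pairs missing the separation age
    are dropped for that model.
    """
    if pairs["zygosity"].nunique() < 2:
        raise ValueError("covariate models need both MZ and DZ pairs")
    cov = _pair_covariates(pairs)
    out = []
    for domain in wpps_wide.columns:
        df = cov.join(wpps_wide[domain], how="inner").dropna(
            subset=[domain, "age_left_home"]
        )
        res = fit_linear(df[domain], df[["zygosity_mz", "sex_f", "age_left_home"]])
        res["dependent"] = domain
        out.append(res)
    return pd.concat(out, ignore_index=True)


def _prioritized(domain_a: str, domain_b: str, priority) -> tuple[str, str]:
    order = {d: k for k, d in enumerate(priority)}
    big = len(order)
    if order.get(domain_a, big) <= order.get(domain_b, big):
        return domain_a, domain_b
    return domain_b, domain_a


def cross_domain_models(
    wpps_wide: pd.DataFrame,
    pairs: pd.DataFrame,
    subsample: str = "all",
    priority=DEFAULT_PRIORITY,
    min_pairs: int = 10,
) -> pd.DataFrame:
    """Pairwise WPPS-WPPS regressions with the age-difference covariate.

    For each unordered pair of domains the dependent variable is the one
    earlier in ``priority``; fitted on pairs with both scores present.
    ``subsample`` restricts to "MZ" or "DZ" pairs. Domain pairs with
    fewer than ``min_pairs`` overlapping pairs are skipped with a
    warning.
    """
    cov = _pair_covariates(pairs)
    keep = pairs if subsample == "all" else pairs[pairs["zygosity"] == subsample]
    ids = keep["pair_id"]
    domains = list(wpps_wide.columns)
    rows = []
    for a_idx in range(len(domains)):
        for b_idx in range(a_idx + 1, len(domains)):
            dep, indep = _prioritized(domains[a_idx], domains[b_idx], priority)
            df = (
                wpps_wide.loc[wpps_wide.index.isin(ids), [dep, indep]]
                .join(cov["age_diff"])
                .dropna()
            )
            if len(df) < min_pairs:
                warnings.warn(
                    f"skipping {dep}~{indep} ({subsample}): only {len(df)} overlapping pairs"
                )
                continue
            res = fit_linear(df[dep], df[[indep, "age_diff"]])
            res = res[res["independent"] == indep].copy()
            res["dependent"] = dep
            res["subsample"] = subsample
            rows.append(res)
    if not rows:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    return pd.concat(rows, ignore_index=True)


@dataclass(frozen=True)
class ZComparisonResult:
    """One-sided z-test for equality of MZ and DZ standardized slopes."""

    dependent: str
    independent: str
    b_mz: float
    se_mz: float
    n_mz: int
    b_dz: float
    se_dz: float
    n_dz: int
    z: float
    p_one_sided: float


def stratified_z_comparison(
    wpps_wide: pd.DataFrame,
    pairs: pd.DataFrame,
    domain_pair: tuple[str, str],
    priority=DEFAULT_PRIORITY,
    min_pairs: int = 10,
) -> ZComparisonResult:
    """Zygosity-stratified standardized cross-domain fit and one-sided z-test.

    Each domain's WPPS is scaled to mean 0, sd 1 within each zygosity
    subsample so the two slopes are comparable;
    ``z = (bMZ - bDZ) / sqrt(seMZ^2 + seDZ^2)`` and
    ``p = 1 - Phi(z)`` (alternative: bMZ > bDZ).
    """
    dep, indep = _prioritized(*domain_pair, priority)
    cov = _pair_covariates(pairs)
    stats = {}
    for zyg in ("MZ", "DZ"):
        ids = pairs.loc[pairs["zygosity"] == zyg, "pair_id"]
        df = (
            wpps_wide.loc[wpps_wide.index.isin(ids), [dep, indep]]
            .join(cov["age_diff"])
            .dropna()
        )
        if len(df) < min_pairs:
            raise ValueError(f"{zyg} subsample too small ({len(df)} pairs)")
        for col in (dep, indep):
            sd = df[col].std(ddof=1)
            if sd == 0 or not np.isfinite(sd):
                raise ValueError(f"degenerate {col} variance in {zyg} subsample")
            df[col] = (df[col] - df[col].mean()) / sd
        res = fit_linear(df[dep], df[[indep, "age_diff"]])
        row = res[res["independent"] == indep].iloc[0]
        stats[zyg] = (row["estimate"], row["se"], int(row["n_pairs"]))
    (b_mz, se_mz, n_mz), (b_dz, se_dz, n_dz) = stats["MZ"], stats["DZ"]
    z = (b_mz - b_dz) / np.sqrt(se_mz**2 + se_dz**2)
    return ZComparisonResult(
        dependent=dep,
        independent=indep,
        b_mz=b_mz,
        se_mz=se_mz,
        n_mz=n_mz,
        b_dz=b_dz,
        se_dz=se_dz,
        n_dz=n_dz,
        z=float(z),
        p_one_sided=float(1.0 - norm.cdf(z)),
    )


def zygosity_comparisons(
    wpps_wide: pd.DataFrame, pairs: pd.DataFrame, priority=DEFAULT_PRIORITY
) -> pd.DataFrame:
    """All pairwise stratified MZ-vs-DZ comparisons as a tidy table."""
    domains = list(wpps_wide.columns)
    rows = []
    for i in range(len(domains)):
        for j in range(i + 1, len(domains)):
            try:
                r = stratified_z_comparison(
                    wpps_wide, pairs, (domains[i], domains[j]), priority
                )
            except ValueError as err:
                warnings.warn(f"skipping {domains[i]}/{domains[j]}: {err}")
                continue
            rows.append(vars(r))
    return pd.DataFrame(rows)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (clipped at 1, monotone in p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def exwas(
    wpps_wide: pd.DataFrame,
    discordance: pd.DataFrame,
    pairs: pd.DataFrame,
    fdr_family: str = "per-domain",
    q_threshold: float = 0.2,
    min_group: int = 2,
    include_age_covariate: bool = True,
) -> pd.DataFrame:
    """Exposome-wide association study of WPPS on lifestyle discordance.

    One OLS per (domain, lifestyle variable): WPPS on the binary
    discordance indicator plus the absolute age-at-blood-sampling
    difference. Pairs with a missing indicator are dropped per variable;
    variables with fewer than ``min_group`` discordant or concordant
    pairs are skipped with a warning. BH q-values are computed within
    each domain's family of tests (``fdr_family="pooled"`` corrects
    across all domains at once) and flagged at ``q_threshold``.

    With ``include_age_covariate=False`` each fit reduces to a
    two-sample comparison of mean WPPS between discordant and
    concordant pairs.
    """
    if fdr_family not in {"per-domain", "pooled"}:
        raise ValueError("fdr_family must be 'per-domain' or 'pooled'")
    bad = discordance.stack().dropna()
    if not bad.isin([0.0, 1.0]).all():
        raise ValueError("discordance values must be 0, 1 or missing")
    cov = _pair_covariates(pairs)
    rows = []
    for domain in wpps_wide.columns:
        for var in discordance.columns:
            df = (
                wpps_wide[[domain]]
                .join(discordance[var], how="inner")
                .join(cov["age_diff"])
                .dropna()
            )
            n_disc = int((df[var] == 1).sum())
            n_conc = int((df[var] == 0).sum())
            if n_disc < min_group or n_conc < min_group:
                warnings.warn(
                    f"skipping {domain}~{var}: {n_disc} discordant / {n_conc} concordant pairs"
                )
                continue
            terms = [var, "age_diff"] if include_age_covariate else [var]
            res = fit_linear(df[domain], df[terms])
            row = res[res["independent"] == var].iloc[0].to_dict()
            row.update(dependent=domain, n_discordant=n_disc, n_concordant=n_conc)
            rows.append(row)
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["q_fdr"] = np.nan
    if fdr_family == "per-domain":
        for domain in out["dependent"].unique():
            mask = out["dependent"] == domain
            out.loc[mask, "q_fdr"] = bh_fdr(out.loc[mask, "p_nominal"].to_numpy())
    else:
        out["q_fdr"] = bh_fdr(out["p_nominal"].to_numpy())
    out["significant"] = out["q_fdr"] < q_threshold
    return out.reset_index(drop=True)
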