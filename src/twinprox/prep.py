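"""Domain preprocessing: missingness filtering, minimum imputation,
inverse-normal transform, standardization, PC outlier screening,
epigenetic-age-acceleration residuals, and lifestyle dichotomization /
within-pair discordance coding.

Transformers follow the scikit-learn estimator contract (``fit`` /
``transform``, fitted attributes with a trailing underscore) and
preserve pandas DataFrames, so they compose with sklearn pipelines.
The module-level functions are thin one-shot wrappers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "MissingFeatureFilter",
    "MinimumImputer",
    "InverseNormalTransformer",
    "FeatureStandardizer",
    "filter_missing_features",
    "impute_minimum",
    "inverse_normal_transform",
    "standardize_features",
    "pca_outlier_flags",
    "eaa_residuals",
    "dichotomize_frequency",
    "discordance_indicator",
    "build_discordance_table",
    "DEFAULT_FREQUENCY_MAP",
]


def _as_frame(X) -> tuple[np.ndarray, pd.DataFrame | None]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), X
    return np.asarray(X, dtype=float), None


def _wrap_like(values: np.ndarray, template: pd.DataFrame | None, columns=None):
    if template is None:
        return values
    cols = template.columns if columns is None else columns
    return pd.DataFrame(values, index=template.index, columns=cols)


class MissingFeatureFilter(BaseEstimator, TransformerMixin):
    """Drop features whose missing fraction exceeds ``max_missing``.

    A feature is retained iff its fraction of missing values is
    <= ``max_missing`` (strictly greater excluded). Default 0.10.
    """

    def __init__(self, max_missing: float = 0.10):
        self.max_missing = max_missing

    def fit(self, X, y=None):
        if not 0.0 <= self.max_missing < 1.0:
            raise ValueError("max_missing must be in [0, 1)")
        arr, _ = _as_frame(X)
        frac = np.isnan(arr).mean(axis=0)
        self.missing_fraction_ = frac
        self.support_ = frac <= self.max_missing
        if not self.support_.any():
            raise ValueError("all features exceed the missingness threshold")
        self.n_features_in_ = arr.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        if isinstance(X, pd.DataFrame):
            return X.loc[:, self.support_]
        return np.asarray(X, dtype=float)[:, self.support_]


class MinimumImputer(BaseEstimator, TransformerMixin):
    """Replace missing cells by the feature's observed minimum."""

    def fit(self, X, y=None):
        arr, frame = _as_frame(X)
        observed = ~np.isnan(arr)
        if not observed.any(axis=0).all():
            bad = np.where(~observed.any(axis=0))[0]
            name = frame.columns[bad[0]] if frame is not None else bad[0]
            raise ValueError(f"feature {name!r} has no observed values")
        self.minima_ = np.nanmin(arr, axis=0)
        self.n_features_in_ = arr.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "minima_")
        arr, frame = _as_frame(X)
        out = np.where(np.isnan(arr), self.minima_, arr)
        return _wrap_like(out, frame)


class InverseNormalTransformer(BaseEstimator, TransformerMixin):
    """Column-wise inverse-normal rank transform (Blom offset 3/8).

    Maps values to ``Phi^{-1}((rank - c) / (n - 2c + 1))`` with average
    ranks for ties. The transform is computed on the data it is applied
    to (ranks are sample-relative, not carried from ``fit``).
    """

    def __init__(self, offset: float = 0.375):
        self.offset = offset

    def fit(self, X, y=None):
        arr, _ = _as_frame(X)
        if arr.shape[0] < 2:
            raise ValueError("need at least 2 observations")
        self.n_features_in_ = arr.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "n_features_in_")
        arr, frame = _as_frame(X)
        out = np.column_stack(
            [inverse_normal_transform(arr[:, j], offset=self.offset) for j in range(arr.shape[1])]
        )
        return _wrap_like(out, frame)


class FeatureStandardizer(BaseEstimator, TransformerMixin):
    """Scale each feature to mean 0, sd 1 (sample sd, divisor n-1)."""

    def fit(self, X, y=None):
        arr, frame = _as_frame(X)
        if np.isnan(arr).any():
            raise ValueError("standardization requires complete data")
        self.mean_ = arr.mean(axis=0)
        self.scale_ = arr.std(axis=0, ddof=1)
        zero = self.scale_ == 0
        if zero.any():
            bad = np.where(zero)[0]
            name = frame.columns[bad[0]] if frame is not None else bad[0]
            raise ValueError(f"constant feature {name!r} cannot be standardized")
        self.n_features_in_ = arr.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "scale_")
        arr, frame = _as_frame(X)
        return _wrap_like((arr - self.mean_) / self.scale_, frame)


def filter_missing_features(matrix, max_fraction: float = 0.10):
    return MissingFeatureFilter(max_missing=max_fraction).fit_transform(matrix)


def impute_minimum(matrix):
    return MinimumImputer().fit_transform(matrix)


def standardize_features(matrix):
    return FeatureStandardizer().fit_transform(matrix)


def inverse_normal_transform(values, offset: float = 0.375) -> np.ndarray:
    """Inverse-normal rank transform of one vector (ties -> average rank)."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("expected a 1-d vector")
    if v.shape[0] < 2:
        raise ValueError("need at least 2 observations")
    if np.isnan(v).any():
        raise ValueError("missing values must be imputed first")
    if np.all(v == v[0]):
        raise ValueError("constant vector cannot be rank-transformed")
    ranks = rankdata(v, method="average")
    n = v.shape[0]
    return norm.ppf((ranks - offset) / (n - 2.0 * offset + 1.0))


def pca_outlier_flags(matrix, n_components: int = 3, sd_threshold: float = 5.0) -> np.ndarray:
    """Flag individuals with any of the first PCs beyond ``sd_threshold`` SD.

    Scores are standardized per component; an individual is flagged iff
    any of the first ``n_components`` standardized scores exceeds the
    threshold in absolute value.
    """
    arr, _ = _as_frame(matrix)
    if np.isnan(arr).any():
        raise ValueError("PC outlier screen requires complete data")
    rank = np.linalg.matrix_rank(arr - arr.mean(axis=0))
    if n_components > rank:
        raise ValueError(f"n_components ({n_components}) exceeds matrix rank ({rank})")
    scores = PCA(n_components=n_components, svd_solver="full").fit_transform(arr)
    z = scores / scores.std(axis=0, ddof=1)
    return (np.abs(z) > sd_threshold).any(axis=1)


def eaa_residuals(epigenetic_age, chronological_age) -> np.ndarray:
    """Epigenetic age acceleration: OLS residuals of epigenetic on chronological age.

    The regression removes the linear effect of chronological age, so a
    constant offset between the two clocks is absorbed by the intercept
    and the residuals have mean zero.
    """
    y = np.asarray(epigenetic_age, dtype=float)
    x = np.asarray(chronological_age, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("epigenetic and chronological ages must be equal-length vectors")
    if y.shape[0] < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]):
        raise ValueError("chronological age is constant; regression undefined")
    design = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ coef


#: Frequency-scale categories mapped to the low (<= once a month) and high
#: (>= once a week) modalities; categories strictly between fall in the gap.
DEFAULT_FREQUENCY_MAP: dict[str, int | None] = {
    "never": 0,
    "less_than_once_a_month": 0,
    "once_a_month": 0,
    "2-3_times_a_month": None,
    "once_a_week": 1,
    "2-3_times_a_week": 1,
    "daily": 1,
}


def dichotomize_frequency(
    response,
    category_map: dict[str, int | None] | None = None,
    gap: str = "missing",
):
    """Dichotomize an ordinal frequency response: <= once a month -> 0,
    >= once a week -> 1.

    Categories strictly between the two modalities (``None`` in the map)
    follow ``gap``: ``"missing"`` (default), ``"low"`` or ``"high"``.
    Numeric 0/1 (or NaN) responses pass through. Scalar or array input.
    """
    if gap not in {"missing", "low", "high"}:
        raise ValueError("gap must be 'missing', 'low' or 'high'")
    cmap = DEFAULT_FREQUENCY_MAP if category_map is None else category_map
    gap_value = {"missing": np.nan, "low": 0.0, "high": 1.0}[gap]

    def one(r):
        if r is None or (isinstance(r, float) and np.isnan(r)):
            return np.nan
        if isinstance(r, (int, float, np.integer, np.floating)):
            if float(r) in (0.0, 1.0):
                return float(r)
            raise ValueError(f"numeric response must be binary, got {r!r}")
        key = str(r).strip().lower().replace(" ", "_").replace("–", "-")
        if key not in cmap:
            raise ValueError(f"unknown frequency category {r!r}")
        mapped = cmap[key]
        return gap_value if mapped is None else float(mapped)

    if isinstance(response, (list, tuple, np.ndarray, pd.Series)):
        values = [one(r) for r in response]
        if isinstance(response, pd.Series):
            return pd.Series(values, index=response.index, dtype=float)
        return np.asarray(values, dtype=float)
    return one(response)


def discordance_indicator(twin1_value, twin2_value) -> float:
    """Within-pair discordance: XOR of two binaries, missing-propagating."""
    a, b = twin1_value, twin2_value
    if a is None or b is None:
        return np.nan
    a, b = float(a), float(b)
    if np.isnan(a) or np.isnan(b):
        return np.nan
    if a not in (0.0, 1.0) or b not in (0.0, 1.0):
        raise ValueError("discordance requires binary (0/1) inputs")
    return float(a != b)


def build_discordance_table(lifestyle: pd.DataFrame, pairs: pd.DataFrame) -> pd.DataFrame:
    """Pair x variable discordance table from per-twin binary lifestyle data.

    ``lifestyle`` is indexed by twin id; values 0/1/NaN. A pair's value
    is missing iff either co-twin's response is missing.
    """
    rows = {}
    for _, row in pairs.iterrows():
        v1 = lifestyle.loc[row["twin1_id"]]
        v2 = lifestyle.loc[row["twin2_id"]]
        rows[row["pair_id"]] = [
            discordance_indicator(v1[c], v2[c]) for c in lifestyle.columns
        ]
    out = pd.DataFrame.from_dict(rows, orient="index", columns=list(lifestyle.columns))
    out.index.name = "pair_id"
    return out
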