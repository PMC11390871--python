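"""Within-pair proximity scores (WPPS).

The score for a twin pair is a Gaussian-kernel similarity,
``K(x_i, x_j) = exp(-D(x_i, x_j) / (2 sigma^2))``, of an
inertia-weighted distance computed in principal-component space:

1. full-rank PCA of the standardized domain matrix (all positive-
   variance components, covering 100% of the realized inertia);
2. each component scaled to unit variance;
3. ``D = sum_k w_k (PC_k(x_i) - PC_k(x_j))^2`` with ``w_k`` the fraction
   of inertia carried by component k (Manhattan variant:
   ``sum_k w_k |Delta_k|``);
4. the Gaussian kernel with sigma = 1 by default.

Scores lie in (0, 1]; 1 marks a pair with identical preprocessed rows.
Because PCA is an orthogonal rotation, the weighted scaled-PC squared
distance reduces algebraically to the squared Euclidean distance on the
standardized features divided by the total inertia; ``oracle_distance``
implements that closed form directly and serves as an independent
cross-check of the PCA route.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "WPPSScorer",
    "compute_wpps",
    "pair_distance",
    "gaussian_similarity",
    "oracle_distance",
    "pivot_wpps",
]

_METRICS = ("euclidean", "manhattan")


def gaussian_similarity(distance: float, sigma: float = 1.0) -> float:
    """Gaussian kernel ``exp(-D / (2 sigma^2))``; 1 iff D = 0."""
    d = np.asarray(distance, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be nonnegative")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return np.exp(-d / (2.0 * sigma**2))


def oracle_distance(standardized_matrix, twin1, twin2) -> float:
    """Closed-form pair distance: ``||z_i - z_j||^2 / total inertia``.

    Independent of the PCA route; used as its cross-check.
    """
    if isinstance(standardized_matrix, pd.DataFrame):
        arr = standardized_matrix.to_numpy(dtype=float)
        idx = standardized_matrix.index
        i = idx.get_loc(twin1) if twin1 in idx else int(twin1)
        j = idx.get_loc(twin2) if twin2 in idx else int(twin2)
    else:
        arr = np.asarray(standardized_matrix, dtype=float)
        i, j = int(twin1), int(twin2)
    total_inertia = arr.var(axis=0, ddof=1).sum()
    diff = arr[i] - arr[j]
    return float(diff @ diff / total_inertia)


class WPPSScorer(BaseEstimator):
    """Score within-pair proximity on one preprocessed data domain.

    Parameters
    ----------
    sigma : float, default 1.0
        Gaussian kernel width.
    metric : {"euclidean", "manhattan"}
        Weighted squared-Euclidean (default) or weighted Manhattan
        distance on the scaled principal components.
    identity_tol : float, default 0.0
        Tolerance for declaring two preprocessed rows identical (score
        exactly 1). 0 means exact equality, appropriate when identical
        rows arise from a shared source record (e.g. one household
        geocode) rather than numerical coincidence.
    min_variance_ratio : float, default 1e-12
        Components with variance below this fraction of total inertia
        are dropped before scaling.

    Attributes
    ----------
    scores_ : (n, r) array of raw PC scores of the fitted individuals.
    inertia_fractions_ : (r,) inertia weights, nonincreasing, summing to 1.
    component_sds_ : (r,) raw component standard deviations (ddof=1).
    total_inertia_ : float, summed variance of retained components.
    ids_ : index of fitted individuals.
    """

    def __init__(
        self,
        sigma: float = 1.0,
        metric: str = "euclidean",
        identity_tol: float = 0.0,
        min_variance_ratio: float = 1e-12,
    ):
        self.sigma = sigma
        self.metric = metric
        self.identity_tol = identity_tol
        self.min_variance_ratio = min_variance_ratio

    def fit(self, X, y=None):
        if self.metric not in _METRICS:
            raise ValueError(f"metric must be one of {_METRICS}")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if isinstance(X, pd.DataFrame):
            arr = X.to_numpy(dtype=float)
            self.ids_ = X.index.copy()
        else:
            arr = np.asarray(X, dtype=float)
            self.ids_ = pd.RangeIndex(arr.shape[0])
        if arr.shape[0] < 3:
            raise ValueError("need at least 3 individuals to fit the PCA")
        if np.isnan(arr).any():
            raise ValueError("domain matrix must be complete (impute first)")

        pca = PCA(n_components=None, svd_solver="full").fit(arr)
        lam = pca.explained_variance_
        keep = lam > self.min_variance_ratio * lam.sum()
        lam = lam[keep]
        self.n_components_ = int(keep.sum())
        self.scores_ = pca.transform(arr)[:, keep]
        self.total_inertia_ = float(lam.sum())
        self.inertia_fractions_ = lam / lam.sum()
        self.component_sds_ = np.sqrt(lam)
        self.rows_ = arr
        self.n_features_in_ = arr.shape[1]
        return self

    def scaled_scores(self) -> np.ndarray:
        """PC scores scaled to unit variance (column sd 1, ddof=1)."""
        check_is_fitted(self, "scores_")
        return self.scores_ / self.component_sds_

    def pair_distance(self, twin1, twin2) -> float:
        """Inertia-weighted distance between two fitted individuals."""
        check_is_fitted(self, "scores_")
        i, j = self.ids_.get_loc(twin1), self.ids_.get_loc(twin2)
        delta = (self.scores_[i] - self.scores_[j]) / self.component_sds_
        return _weighted_distance(delta, self.inertia_fractions_, self.metric)

    def pair_similarity(self, twin1, twin2) -> float:
        check_is_fitted(self, "scores_")
        i, j = self.ids_.get_loc(twin1), self.ids_.get_loc(twin2)
        if self._rows_identical(i, j):
            return 1.0
        return float(gaussian_similarity(self.pair_distance(twin1, twin2), self.sigma))

    def _rows_identical(self, i: int, j: int) -> bool:
        if self.identity_tol == 0.0:
            return bool(np.array_equal(self.rows_[i], self.rows_[j]))
        return bool(np.allclose(self.rows_[i], self.rows_[j], atol=self.identity_tol, rtol=0.0))

    def score_pairs(self, pairs: pd.DataFrame, domain: str | None = None) -> pd.DataFrame:
        """WPPS table for the pairs present in the fitted matrix.

        Pairs with either co-twin absent from the fitted individuals are
        dropped (complete-case per domain). Columns: pair_id, domain,
        wpps, n_features, metric.
        """
        check_is_fitted(self, "scores_")
        rows = []
        for _, row in pairs.iterrows():
            if row["twin1_id"] not in self.ids_ or row["twin2_id"] not in self.ids_:
                continue
            rows.append(
                {
                    "pair_id": row["pair_id"],
                    "domain": domain if domain is not None else "domain",
                    "wpps": self.pair_similarity(row["twin1_id"], row["twin2_id"]),
                    "n_features": self.n_features_in_,
                    "metric": self.metric,
                }
            )
        if not rows:
            raise ValueError("no pair has both co-twins in the fitted matrix")
        return pd.DataFrame(rows)


def _weighted_distance(delta: np.ndarray, weights: np.ndarray, metric: str) -> float:
    delta = np.asarray(delta, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if delta.shape != weights.shape:
        raise ValueError("weight/score dimension mismatch")
    if metric == "euclidean":
        return float(weights @ delta**2)
    if metric == "manhattan":
        return float(weights @ np.abs(delta))
    raise ValueError(f"metric must be one of {_METRICS}")


def pair_distance(scaled_scores, weights, twin1, twin2, metric: str = "euclidean") -> float:
    """Inertia-weighted distance between two rows of a scaled score matrix."""
    scores = np.asarray(scaled_scores, dtype=float)
    delta = scores[int(twin1)] - scores[int(twin2)]
    return _weighted_distance(delta, weights, metric)


def compute_wpps(
    matrix,
    pairs: pd.DataFrame,
    sigma: float = 1.0,
    metric: str = "euclidean",
    domain: str | None = None,
    identity_tol: float = 0.0,
) -> pd.DataFrame:
    """Full WPPS procedure on one preprocessed domain matrix."""
    scorer = WPPSScorer(sigma=sigma, metric=metric, identity_tol=identity_tol).fit(matrix)
    return scorer.score_pairs(pairs, domain=domain)


def pivot_wpps(tables) -> pd.DataFrame:
    """Long WPPS table(s) -> wide pair x domain score matrix."""
    if isinstance(tables, pd.DataFrame):
        long = tables
    else:
        long = pd.concat(list(tables), ignore_index=True)
    return long.pivot(index="pair_id", columns="domain", values="wpps")
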