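"""Sensitivity analyses for the skewed external-exposome WPPS.

Two strategies: (1) remap the bounded score into [0.025, 0.975] by a
linear transform and apply the logit, spreading the compressed upper
range over the real axis; (2) drop pairs whose exposome score is
exactly 1 (co-resident pairs sharing one household record).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import logit

__all__ = ["RemapParams", "remap_and_logit", "exclude_unity_pairs"]

from dataclasses import dataclass


@dataclass(frozen=True)
class RemapParams:
    lower: float = 0.025
    upper: float = 0.975

    def __post_init__(self) -> None:
        if not 0.0 < self.lower < self.upper < 1.0:
            raise ValueError("need 0 < lower < upper < 1")


def remap_and_logit(wpps, lower: float = 0.025, upper: float = 0.975, source: str = "unit"):
    """Linear remap of scores into [lower, upper] followed by the logit.

    ``source="unit"`` (default) maps the theoretical score range [0, 1]
    onto [lower, upper] (``x -> lower + (upper - lower) * x``), so a
    score of 1 lands exactly on ``upper`` regardless of the sample;
    ``source="observed"`` maps the observed min/max instead. Strictly
    increasing either way.
    """
    params = RemapParams(lower, upper)
    x = np.asarray(wpps, dtype=float)
    if x.size == 0:
        raise ValueError("empty score vector")
    if source == "unit":
        lo, hi = 0.0, 1.0
    elif source == "observed":
        lo, hi = float(np.nanmin(x)), float(np.nanmax(x))
        if hi <= lo:
            raise ValueError("degenerate observed range")
    else:
        raise ValueError("source must be 'unit' or 'observed'")
    remapped = params.lower + (params.upper - params.lower) * (x - lo) / (hi - lo)
    out = logit(remapped)
    if isinstance(wpps, pd.Series):
        return pd.Series(out, index=wpps.index, name=wpps.name)
    return out


def exclude_unity_pairs(wpps_table: pd.DataFrame, domain: str = "exposome") -> pd.DataFrame:
    """Drop rows of a long WPPS table where ``domain``'s score equals 1.

    Other domains' rows are untouched. Scores of exactly 1 come from the
    exact row-identity criterion of the scorer, so exact comparison is
    appropriate.
    """
    mask = (wpps_table["domain"] == domain) & (wpps_table["wpps"] == 1.0)
    return wpps_table.loc[~mask].reset_index(drop=True)
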