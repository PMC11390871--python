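"""Delimited-text readers/writers for cohort tables.

Domain CSVs: header row of feature names, first column the twin id.
``pairs.csv`` and ``lifestyle.csv`` follow the layouts written by
:meth:`twinprox.simulate.TwinCohort.to_dir`.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = [
    "read_domain_csv",
    "write_domain_csv",
    "read_pairs",
    "read_lifestyle",
    "read_wpps",
]

PAIR_COLUMNS = [
    "pair_id",
    "twin1_id",
    "twin2_id",
    "zygosity",
    "sex",
    "age_blood_twin1",
    "age_blood_twin2",
    "age_left_home",
    "co_resident",
]


def read_domain_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    df.index.name = "twin_id"
    return df.astype(float)


def write_domain_csv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, index_label="twin_id")


def read_pairs(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(PAIR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pairs table missing columns: {sorted(missing)}")
    df["co_resident"] = df["co_resident"].astype(bool)
    return df


def read_lifestyle(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    df.index.name = "twin_id"
    return df


def read_wpps(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
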