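"""Reading, writing and validation of the five raw input tables.

All tables are delimited text (comma or tab, autodetected), UTF-8, with a
header row.  Expected columns:

========================  =========================================
breed census              region, breed, group, heads
surname counts            surname, region, count
species occupancy         region, species, occupied_fraction
historical membership     region, time_slice, division
centroids                 region, x, y
========================  =========================================
"""

from __future__ import annotations

import numpy as np
import pandas as pd

LIVESTOCK_GROUPS = ("cattle", "sheep", "goat", "horse", "donkey", "pig")


class TableValidationError(ValueError):
    """An input table violates its contract."""


def _read(path, columns: tuple[str, ...]) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python", encoding="utf-8")
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise TableValidationError(
            f"{path}: missing required columns {missing}; found {list(df.columns)}")
    return df[list(columns)]


def _require_unique(df: pd.DataFrame, keys: list[str], what: str) -> None:
    dup = df.duplicated(subset=keys)
    if dup.any():
        row = df[dup].iloc[0]
        raise TableValidationError(
            f"duplicate {what} entry: {tuple(row[k] for k in keys)}")


# ---------------------------------------------------------------- validators

def validate_breed_census(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["heads"] = pd.to_numeric(df["heads"])
    if (df["heads"] < 0).any():
        bad = df[df["heads"] < 0].iloc[0]
        raise TableValidationError(
            f"negative head count for breed {bad['breed']!r} in region "
            f"{bad['region']!r}")
    _require_unique(df, ["region", "breed"], "(region, breed)")
    groups_per_breed = df.groupby("breed")["group"].nunique()
    bad = groups_per_breed[groups_per_breed > 1]
    if len(bad):
        raise TableValidationError(
            f"breed(s) with inconsistent group labels: {list(bad.index)}")
    return df


def validate_surname_counts(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    if len(df) == 0:
        raise TableValidationError("empty surname table")
    df["count"] = pd.to_numeric(df["count"])
    if (df["count"] < 0).any():
        raise TableValidationError("negative surname count")
    _require_unique(df, ["surname", "region"], "(surname, region)")
    return df


def validate_occupancy(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["occupied_fraction"] = pd.to_numeric(df["occupied_fraction"])
    f = df["occupied_fraction"]
    if ((f < 0) | (f > 1)).any():
        bad = df[(f < 0) | (f > 1)].iloc[0]
        raise TableValidationError(
            f"occupancy fraction outside [0, 1]: species {bad['species']!r}, "
            f"region {bad['region']!r}, value {bad['occupied_fraction']}")
    _require_unique(df, ["region", "species"], "(region, species)")
    return df


def validate_membership(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    _require_unique(df, ["region", "time_slice"], "(region, time_slice)")
    slices = sorted(df["time_slice"].unique())
    per_region = df.groupby("region")["time_slice"].apply(
        lambda s: sorted(s.unique()))
    for region, have in per_region.items():
        if have != slices:
            missing = sorted(set(slices) - set(have))
            raise TableValidationError(
                f"region {region!r} missing membership for time slice(s) "
                f"{missing}")
    return df


def validate_centroids(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    _require_unique(df, ["region"], "region")
    xy = df[["x", "y"]].apply(pd.to_numeric)
    if not np.all(np.isfinite(xy.to_numpy())):
        raise TableValidationError("non-finite centroid coordinate")
    df[["x", "y"]] = xy
    return df


# ---------------------------------------------------------------- readers

def read_breed_census(path) -> pd.DataFrame:
    return validate_breed_census(_read(path, ("region", "breed", "group", "heads")))


def read_surname_counts(path) -> pd.DataFrame:
    return validate_surname_counts(_read(path, ("surname", "region", "count")))


def read_occupancy(path) -> pd.DataFrame:
    return validate_occupancy(_read(path, ("region", "species", "occupied_fraction")))


def read_membership(path) -> pd.DataFrame:
    return validate_membership(_read(path, ("region", "time_slice", "division")))


def read_centroids(path) -> pd.DataFrame:
    return validate_centroids(_read(path, ("region", "x", "y")))
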