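"""Census data model, readers/writers, measurement conventions, and
tree-community summary statistics.

All tabular data move through pandas DataFrames with a fixed, documented
column schema (one canonical CSV dialect: comma-delimited, UTF-8, header
row, ISO-8601 dates). Validation is strict: a file that violates a
biological invariant (a seedling recorded dead and later alive, duplicate
measurements, heights off the 0.5 cm grid) raises a named error rather
than being silently coerced.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Schema constants

SUBSTRATE_LEVELS = (
    "live_tree_fern",
    "dead_tree_fern",
    "log",
    "rock",
    "root_mat",
    "soil",
)

STATUS_LEVELS = ("alive", "dead")

SEEDLING_COLUMNS = (
    "tag_id",
    "species",
    "subplot_id",
    "census_date",
    "height_cm",
    "leaf_count",
    "status",
    "substrate",
)

TREE_COLUMNS = ("species", "dbh_cm", "quadrat_id")

SUBPLOT_COLUMNS = ("subplot_id", "slope_deg", "aspect_deg", "elevation_m", "tpar")

HARVEST_COLUMNS = ("species", "height_cm", "leaf_count", "dry_mass_g", "leaf_area_cm2")


# ---------------------------------------------------------------------------
# Errors


class CensusError(ValueError):
    """Base class for census data errors."""


class SchemaMismatchError(CensusError):
    """File header does not match the documented schema."""


class DuplicateRecordError(CensusError):
    """Same (tag_id, census_date) measured twice."""


class ResurrectionError(CensusError):
    """A seedling recorded dead and subsequently alive (or re-measured)."""


class MeasurementError(CensusError):
    """A measurement violates its physical constraints."""


# ---------------------------------------------------------------------------
# Measurement convention


def round_measurement(x):
    """Round a field measurement to the nearest 0.5 cm.

    Exact ties (x = k*0.5 + 0.25) round up; this convention is the single
    place the tie rule lives. Accepts scalars or arrays; rejects negative
    input.

    >>> round_measurement(0.74)
    0.5
    >>> round_measurement(0.75)
    1.0
    """
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise MeasurementError("negative measurement")
    out = np.floor(arr * 2.0 + 0.5) / 2.0
    if np.isscalar(x) or arr.ndim == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# Validation


def _check_columns(df: pd.DataFrame, expected: Iterable[str], what: str) -> None:
    expected = tuple(expected)
    got = tuple(df.columns)
    if got != expected:
        raise SchemaMismatchError(
            f"{what}: expected columns {expected}, got {got}"
        )


def validate_census(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a seedling census table in place and return it.

    Checks the full set of record invariants: positive on-grid heights for
    live records, non-negative leaf counts, known status/substrate levels,
    strictly increasing census dates per tag, no duplicate
    (tag_id, census_date), and no record after death.
    """
    _check_columns(df, SEEDLING_COLUMNS, "seedlings")
    if len(df) == 0:
        return df
    if df.duplicated(subset=["tag_id", "census_date"]).any():
        dup = df[df.duplicated(subset=["tag_id", "census_date"], keep=False)]
        raise DuplicateRecordError(
            f"duplicate (tag_id, census_date): {sorted(set(dup['tag_id']))[:5]}"
        )
    bad_status = set(df["status"]) - set(STATUS_LEVELS)
    if bad_status:
        raise SchemaMismatchError(f"unknown status values: {sorted(bad_status)}")
    bad_sub = set(df["substrate"]) - set(SUBSTRATE_LEVELS)
    if bad_sub:
        raise SchemaMismatchError(f"unknown substrate values: {sorted(bad_sub)}")

    alive = df["status"] == "alive"
    h = df["height_cm"].to_numpy(dtype=float)
    if np.any(h[alive.to_numpy()] <= 0):
        raise MeasurementError("non-positive height on a live record")
    if np.any(df["leaf_count"].to_numpy() < 0):
        raise MeasurementError("negative leaf count")
    # heights sit on the 0.5 cm measurement grid
    if np.any(np.abs(h * 2.0 - np.round(h * 2.0)) > 1e-9):
        off = df.loc[np.abs(h * 2.0 - np.round(h * 2.0)) > 1e-9, "tag_id"]
        raise MeasurementError(
            f"height not a multiple of 0.5 cm for tags {sorted(set(off))[:5]}"
        )

    for tag, grp in df.groupby("tag_id", sort=False):
        dates = pd.to_datetime(grp["census_date"]).to_numpy()
        order = np.argsort(dates, kind="stable")
        if np.any(np.diff(dates[order]).astype("timedelta64[s]").astype(int) <= 0):
            raise DuplicateRecordError(f"non-increasing census dates for tag {tag}")
        status = grp["status"].to_numpy()[order]
        dead_seen = False
        for s in status:
            if dead_seen:
                raise ResurrectionError(f"record after death for tag {tag}")
            if s == "dead":
                dead_seen = True
    return df


# ---------------------------------------------------------------------------
# Readers / writers (one canonical dialect)

_FLOAT_FMT = "%.10g"


def _read(path, columns, what) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise SchemaMismatchError(f"{what}: empty file, header required")
    _check_columns(df, columns, what)
    return df


def read_census(path) -> pd.DataFrame:
    """Read and validate a seedling census CSV."""
    df = _read(path, SEEDLING_COLUMNS, "seedlings")
    if len(df):
        df = df.astype(
            {
                "subplot_id": int,
                "height_cm": float,
                "leaf_count": int,
            }
        )
        df["census_date"] = pd.to_datetime(df["census_date"], format="%Y-%m-%d")
    else:
        df = df.astype(
            {"subplot_id": int, "height_cm": float, "leaf_count": int},
            errors="ignore",
        )
        df["census_date"] = pd.to_datetime(df["census_date"])
    return validate_census(df)


def write_census(df: pd.DataFrame, path) -> None:
    """Write a census table in the canonical dialect (round-trip stable)."""
    out = df.copy()
    out["census_date"] = pd.to_datetime(out["census_date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_trees(path) -> pd.DataFrame:
    df = _read(path, TREE_COLUMNS, "trees")
    if len(df):
        df = df.astype({"dbh_cm": float})
        if np.any(df["dbh_cm"].to_numpy() < 1.0):
            raise MeasurementError("tree DBH below the 1 cm census threshold")
    else:
        df = df.astype({"dbh_cm": float}, errors="ignore")
    return df


def read_subplots(path) -> pd.DataFrame:
    df = _read(path, SUBPLOT_COLUMNS, "subplots")
    if len(df):
        df = df.astype(
            {
                "subplot_id": int,
                "slope_deg": float,
                "aspect_deg": float,
                "elevation_m": float,
                "tpar": float,
            }
        )
        if df["subplot_id"].duplicated().any():
            raise DuplicateRecordError("duplicate subplot_id in environment table")
        a = df["aspect_deg"].to_numpy()
        if np.any((a < 0) | (a >= 360)):
            raise MeasurementError("aspect outside [0, 360)")
        if np.any(df["slope_deg"].to_numpy() < 0):
            raise MeasurementError("negative slope")
        if np.any(df["tpar"].to_numpy() < 0):
            raise MeasurementError("negative TPAR")
    return df


def read_harvest(path) -> pd.DataFrame:
    df = _read(path, HARVEST_COLUMNS, "harvest")
    if len(df):
        df = df.astype(
            {
                "height_cm": float,
                "leaf_count": int,
                "dry_mass_g": float,
                "leaf_area_cm2": float,
            }
        )
        vals = df[["height_cm", "dry_mass_g", "leaf_area_cm2"]].to_numpy()
        if np.any(vals <= 0) or np.any(df["leaf_count"].to_numpy() < 1):
            raise MeasurementError("harvest measurements must be positive")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    """Write any stage table in the canonical dialect."""
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# Tree community statistics


def tree_community_stats(trees: pd.DataFrame, n_quadrats: int) -> pd.DataFrame:
    """Per-species relative abundance, dominance, and frequency (percent).

    RA_i = stems of species i / all stems x 100.
    RD_i = basal area of species i / total basal area x 100, with basal
    area per stem pi*(dbh/2)^2 (circular-stem convention).
    RF_i = quadrats in which species i occurs / n_quadrats x 100.
    """
    if len(trees) == 0:
        raise CensusError("empty tree table")
    if n_quadrats < 1:
        raise CensusError("n_quadrats must be >= 1")
    t = trees.copy()
    t["ba"] = math.pi * (t["dbh_cm"].to_numpy(dtype=float) / 2.0) ** 2
    n_total = len(t)
    ba_total = t["ba"].sum()
    rows = []
    for sp, grp in t.groupby("species", sort=True):
        rows.append(
            {
                "species": sp,
                "ra": 100.0 * len(grp) / n_total,
                "rd": 100.0 * grp["ba"].sum() / ba_total,
                "rf": 100.0 * grp["quadrat_id"].nunique() / n_quadrats,
            }
        )
    return pd.DataFrame(rows, columns=["species", "ra", "rd", "rf"])
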