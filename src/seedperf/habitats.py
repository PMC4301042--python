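"""Discretization of the continuous environment into one-dimensional
microhabitat categories and seedling category assignment.

The default scheme has 18 categories: three empirical-tertile levels each
for transmitted PAR, slope, and elevation; three fixed aspect sectors
(NE 0-92, SE-SW 92-242, W-NW 242-360 degrees, half-open); and six rooting
substrates. Each seedling belongs to exactly one category per axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .census_io import SUBSTRATE_LEVELS

ASPECT_LABELS = ("NE", "SE-SW", "W-NW")
ASPECT_EDGES = (92.0, 242.0)  # half-open: [0,92) NE, [92,242) SE-SW, [242,360) W-NW
LEVEL_LABELS = ("low", "medium", "high")
CONTINUOUS_AXES = ("tpar", "slope", "elevation")
AXES = ("tpar", "slope", "elevation", "aspect", "substrate")


class SchemeError(ValueError):
    """Invalid microhabitat scheme or out-of-range environmental value."""


def aspect_category(aspect) -> np.ndarray | str:
    """Map aspect (degrees in [0, 360)) to its sector label.

    The 242-degree boundary belongs to W-NW (half-open intervals).
    """
    arr = np.asarray(aspect, dtype=float)
    if np.any((arr < 0) | (arr >= 360)):
        raise SchemeError("aspect must lie in [0, 360)")
    idx = np.searchsorted(np.asarray(ASPECT_EDGES), arr, side="right")
    labels = np.asarray(ASPECT_LABELS, dtype=object)[idx]
    if np.isscalar(aspect) or arr.ndim == 0:
        return str(labels)
    return labels


def tertile_cuts(values) -> tuple[float, float]:
    """Empirical 1/3 and 2/3 quantile cut points over subplot values."""
    arr = np.asarray(values, dtype=float)
    if len(np.unique(arr)) < 3:
        raise SchemeError("need >= 3 distinct values to form three levels")
    lo, hi = np.quantile(arr, [1.0 / 3.0, 2.0 / 3.0])
    if not lo < hi:
        raise SchemeError(
            "tertile cut points coincide (heavily tied values); "
            "cannot form three levels"
        )
    return float(lo), float(hi)


def level_category(values, cuts: Sequence[float] | None = None):
    """Assign low/medium/high levels given two cut points.

    Ties fall in the lower bin: low = (-inf, c1], medium = (c1, c2],
    high = (c2, inf). If ``cuts`` is None, empirical tertiles of ``values``
    are used.
    """
    arr = np.asarray(values, dtype=float)
    if cuts is None:
        cuts = tertile_cuts(arr)
    c1, c2 = cuts
    if not c1 < c2:
        raise SchemeError("cut points must be strictly increasing")
    idx = np.searchsorted(np.asarray([c1, c2]), arr, side="left")
    # searchsorted(left) puts x == cut at the cut's own index -> lower bin
    labels = np.asarray(LEVEL_LABELS, dtype=object)[idx]
    if np.isscalar(values) or arr.ndim == 0:
        return str(labels)
    return labels


@dataclass(frozen=True)
class MicrohabitatScheme:
    """Cut points and level sets defining the one-dimensional categories."""

    tpar_cuts: tuple[float, float]
    slope_cuts: tuple[float, float]
    elevation_cuts: tuple[float, float]
    aspect_labels: tuple[str, ...] = ASPECT_LABELS
    substrate_levels: tuple[str, ...] = SUBSTRATE_LEVELS

    def __post_init__(self):
        for name in ("tpar_cuts", "slope_cuts", "elevation_cuts"):
            c1, c2 = getattr(self, name)
            if not c1 < c2:
                raise SchemeError(f"{name} must be strictly increasing")

    @classmethod
    def from_subplots(
        cls,
        subplots: pd.DataFrame,
        tpar_cuts=None,
        slope_cuts=None,
        elevation_cuts=None,
    ) -> "MicrohabitatScheme":
        """Build a scheme from a subplot environment table.

        Cut points default to empirical tertiles over subplots; any axis
        can be overridden with explicit cuts from configuration.
        """
        return cls(
            tpar_cuts=tuple(tpar_cuts) if tpar_cuts else tertile_cuts(subplots["tpar"]),
            slope_cuts=tuple(slope_cuts)
            if slope_cuts
            else tertile_cuts(subplots["slope_deg"]),
            elevation_cuts=tuple(elevation_cuts)
            if elevation_cuts
            else tertile_cuts(subplots["elevation_m"]),
        )

    def cuts_for(self, axis: str) -> tuple[float, float]:
        return {
            "tpar": self.tpar_cuts,
            "slope": self.slope_cuts,
            "elevation": self.elevation_cuts,
        }[axis]


def enumerate_microhabitats(scheme: MicrohabitatScheme) -> list[tuple[str, str]]:
    """All categories as (axis, level) pairs in canonical order.

    Order: tpar low/medium/high, slope, elevation, aspect NE/SE-SW/W-NW,
    then the substrate levels; 18 categories under the default scheme.
    """
    cats: list[tuple[str, str]] = []
    for axis in CONTINUOUS_AXES:
        cats.extend((axis, lvl) for lvl in LEVEL_LABELS)
    cats.extend(("aspect", lab) for lab in scheme.aspect_labels)
    cats.extend(("substrate", s) for s in scheme.substrate_levels)
    return cats


def categorize_subplots(subplots: pd.DataFrame, scheme: MicrohabitatScheme) -> pd.DataFrame:
    """Per-subplot category labels for the four environment-derived axes."""
    out = subplots[["subplot_id"]].copy()
    out["cat_tpar"] = level_category(subplots["tpar"], scheme.tpar_cuts)
    out["cat_slope"] = level_category(subplots["slope_deg"], scheme.slope_cuts)
    out["cat_elevation"] = level_category(
        subplots["elevation_m"], scheme.elevation_cuts
    )
    out["cat_aspect"] = aspect_category(subplots["aspect_deg"].to_numpy())
    return out


def assign_categories(
    seedlings: pd.DataFrame, subplots: pd.DataFrame, scheme: MicrohabitatScheme
) -> pd.DataFrame:
    """One row per tag with its five microhabitat memberships.

    Environment axes come from the seedling's subplot; substrate is the
    rooting substrate recorded at first measurement.
    """
    sub_cats = categorize_subplots(subplots, scheme)
    first = (
        seedlings.sort_values(["tag_id", "census_date"], kind="stable")
        .groupby("tag_id", sort=True)
        .first()
        .reset_index()
    )
    merged = first[["tag_id", "species", "subplot_id", "substrate"]].merge(
        sub_cats, on="subplot_id", how="left", validate="many_to_one"
    )
    if merged["cat_tpar"].isna().any():
        missing = merged.loc[merged["cat_tpar"].isna(), "subplot_id"].unique()
        raise SchemeError(f"subplots missing from environment table: {missing[:5]}")
    merged = merged.rename(columns={"substrate": "cat_substrate"})
    return merged[
        [
            "tag_id",
            "species",
            "subplot_id",
            "cat_tpar",
            "cat_slope",
            "cat_elevation",
            "cat_aspect",
            "cat_substrate",
        ]
    ]
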