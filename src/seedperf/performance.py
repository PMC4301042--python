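"""Per-seedling performance metrics: three relative growth rates and
first-year survival.

RGR = (ln(final size) - ln(initial size)) / elapsed years, computed from
the first to the last live measurement of each tagged seedling. Size is
stem height (RGR_ht), allometrically estimated whole-plant dry mass
(RGR_pm), or estimated total leaf area (RGR_la). Eligibility filters:
RGR needs at least two live measurements and an initial height below
10 cm. Survival is scored once per seedling, for the first year after it
was first tagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .allometry import AllometricModel, predict_size

DAYS_PER_YEAR = 365.25
MAX_INITIAL_HEIGHT_CM = 10.0  # strict: initial heights must be below this
FIRST_YEAR_WINDOW_DAYS = (330.0, 430.0)


class PerformanceError(ValueError):
    pass


def compute_rgr(initial_size, final_size, initial_date, final_date) -> float:
    """Classic relative growth rate in 1/yr.

    (ln final - ln initial) / dt with dt in years (365.25 d).
    """
    s0 = float(initial_size)
    s1 = float(final_size)
    if s0 <= 0 or s1 <= 0:
        raise PerformanceError("sizes must be positive")
    d0 = pd.Timestamp(initial_date)
    d1 = pd.Timestamp(final_date)
    days = (d1 - d0).total_seconds() / 86400.0
    if days <= 0:
        raise PerformanceError("final date must be after initial date")
    return (np.log(s1) - np.log(s0)) / (days / DAYS_PER_YEAR)


def first_year_survival(
    days_since_first: np.ndarray,
    alive: np.ndarray,
    window: tuple[float, float] = FIRST_YEAR_WINDOW_DAYS,
) -> float:
    """Survival outcome (1/0) read at the census closest to one year.

    The outcome is the status at the first census falling in ``window``
    days after first measurement; if none falls in the window, the nearest
    census after 365 d is used. NaN (undefined) when no qualifying later
    census exists. Death observed before the qualifying census also scores
    0: a seedling found dead at any census up to the read-off point did
    not survive its first year.
    """
    d = np.asarray(days_since_first, dtype=float)
    a = np.asarray(alive, dtype=bool)
    lo, hi = window
    in_win = np.nonzero((d >= lo) & (d <= hi))[0]
    if len(in_win):
        idx = in_win[0]
    else:
        after = np.nonzero(d > 365.0)[0]
        if len(after) == 0:
            # dead before any one-year read-off is still a first-year death
            if np.any(~a):
                return 0.0
            return float("nan")
        idx = after[0]
    if np.any(~a[: idx + 1]):
        return 0.0
    return 1.0 if a[idx] else 0.0


@dataclass(frozen=True)
class PerformanceOptions:
    max_initial_height: float = MAX_INITIAL_HEIGHT_CM
    first_year_window: tuple[float, float] = FIRST_YEAR_WINDOW_DAYS


def seedling_performance(
    census: pd.DataFrame,
    models: dict[str, AllometricModel],
    options: PerformanceOptions = PerformanceOptions(),
) -> pd.DataFrame:
    """Per-tag performance table from a validated census.

    Columns: tag_id, species, subplot_id, initial_height_cm, rgr_ht,
    rgr_pm, rgr_la, survived_first_year. RGR columns are NaN when the
    seedling is ineligible (single live measurement, or initial height
    >= the 10 cm cap); survival is NaN when no census falls at least a
    year after first tagging.
    """
    missing = sorted(set(census["species"].unique()) - set(models))
    if missing:
        raise PerformanceError(f"no allometric model for species: {missing}")

    rows = []
    grouped = census.sort_values(["tag_id", "census_date"], kind="stable").groupby(
        "tag_id", sort=True
    )
    for tag, grp in grouped:
        sp = grp["species"].iloc[0]
        model = models[sp]
        dates = pd.to_datetime(grp["census_date"])
        alive = (grp["status"] == "alive").to_numpy()
        heights = grp["height_cm"].to_numpy(dtype=float)
        leaves = np.maximum(grp["leaf_count"].to_numpy(dtype=float), 1.0)

        h0 = heights[0]
        rgr_ht = rgr_pm = rgr_la = float("nan")
        live_idx = np.nonzero(alive)[0]
        if len(live_idx) >= 2 and h0 < options.max_initial_height:
            i, j = live_idx[0], live_idx[-1]
            d0, d1 = dates.iloc[i], dates.iloc[j]
            rgr_ht = compute_rgr(heights[i], heights[j], d0, d1)
            m0, a0 = predict_size(model, heights[i], leaves[i])
            m1, a1 = predict_size(model, heights[j], leaves[j])
            rgr_pm = compute_rgr(m0, m1, d0, d1)
            rgr_la = compute_rgr(a0, a1, d0, d1)

        days = ((dates - dates.iloc[0]).dt.total_seconds() / 86400.0).to_numpy()
        surv = first_year_survival(days[1:], alive[1:], options.first_year_window)

        rows.append(
            {
                "tag_id": tag,
                "species": sp,
                "subplot_id": grp["subplot_id"].iloc[0],
                "initial_height_cm": h0,
                "rgr_ht": rgr_ht,
                "rgr_pm": rgr_pm,
                "rgr_la": rgr_la,
                "survived_first_year": surv,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "tag_id",
            "species",
            "subplot_id",
            "initial_height_cm",
            "rgr_ht",
            "rgr_pm",
            "rgr_la",
            "survived_first_year",
        ],
    )
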