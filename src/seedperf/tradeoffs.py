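"""Win/tie classification of pairwise species comparisons and detection of
the three performance trade-off types.

Within one (microhabitat, metric) cell, a species pair is a WIN for the
species with the significantly larger LS-mean (Shaffer-adjusted p below
alpha) and a TIE otherwise. Across cells:

* microhabitat trade-off — each species of the pair wins somewhere
  (rank reversal across habitats);
* growth-survival trade-off — within one microhabitat, opposite winners
  for an RGR metric versus survival (win-lose), or a win in one metric
  with a tie in the other (win-tie);
* light-cross trade-off — one species wins RGR in the high-light cell
  while the other wins survival in the low-light cell.

Win proportions aggregate per species: the fraction of analyzed
microhabitats in which the species beat at least one other species.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .inference import ALPHA_DEFAULT, LSMeans, PairwiseContrast

METRICS = ("rgr_ht", "rgr_pm", "rgr_la", "survival")


class Call(str, Enum):
    WIN_A = "WIN_A"
    WIN_B = "WIN_B"
    TIE = "TIE"


class GrowthSurvival(str, Enum):
    WIN_LOSE = "WIN_LOSE"
    WIN_TIE = "WIN_TIE"
    NONE = "NONE"


@dataclass(frozen=True)
class PairOutcome:
    microhabitat: tuple[str, str]  # (axis, level)
    metric: str
    species_a: str
    species_b: str
    call: Call


class TradeoffError(ValueError):
    pass


def classify_pair(
    lsmeans: LSMeans,
    contrast: PairwiseContrast,
    alpha: float = ALPHA_DEFAULT,
    microhabitat: tuple[str, str] = ("", ""),
    metric: str = "",
) -> PairOutcome:
    """WIN for the larger LS-mean when the adjusted p is below alpha, else TIE."""
    a, b = contrast.species_a, contrast.species_b
    ia = lsmeans.species.index(a)
    ib = lsmeans.species.index(b)
    if contrast.p_adjusted < alpha and lsmeans.estimate[ia] != lsmeans.estimate[ib]:
        call = Call.WIN_A if lsmeans.estimate[ia] > lsmeans.estimate[ib] else Call.WIN_B
    else:
        call = Call.TIE
    return PairOutcome(
        microhabitat=microhabitat, metric=metric, species_a=a, species_b=b, call=call
    )


def microhabitat_tradeoff(calls) -> bool:
    """True iff both species of the pair win in at least one category each."""
    calls = list(calls)
    if not calls:
        raise TradeoffError("no defined outcomes for the pair")
    return Call.WIN_A in calls and Call.WIN_B in calls


def growth_survival_tradeoff(growth_call: Call, survival_call: Call) -> GrowthSurvival:
    """Classify one microhabitat's growth-vs-survival pattern for a pair."""
    wins = {Call.WIN_A, Call.WIN_B}
    if growth_call in wins and survival_call in wins:
        if growth_call != survival_call:
            return GrowthSurvival.WIN_LOSE
        return GrowthSurvival.NONE
    if growth_call in wins or survival_call in wins:
        return GrowthSurvival.WIN_TIE
    return GrowthSurvival.NONE


def light_cross_tradeoff(high_rgr_call: Call | None, low_surv_call: Call | None) -> bool | None:
    """Rank reversal between high-light RGR and low-light survival.

    True iff the two cells have opposite winners; None (undefined) when
    either cell is undefined — undefined cells are excluded from counts.
    """
    if high_rgr_call is None or low_surv_call is None:
        return None
    wins = {Call.WIN_A, Call.WIN_B}
    return (
        high_rgr_call in wins
        and low_surv_call in wins
        and high_rgr_call != low_surv_call
    )


def wins_proportion(outcomes: list[PairOutcome], species: str, metric: str) -> float:
    """Fraction of analyzed microhabitats in which the species won >= 1 pair.

    Denominator: categories with at least one defined outcome involving
    the species for the metric (categories where the species was excluded
    by the subplot rule drop out of both numerator and denominator).
    """
    cats_analyzed = set()
    cats_won = set()
    for o in outcomes:
        if o.metric != metric:
            continue
        if species == o.species_a:
            cats_analyzed.add(o.microhabitat)
            if o.call == Call.WIN_A:
                cats_won.add(o.microhabitat)
        elif species == o.species_b:
            cats_analyzed.add(o.microhabitat)
            if o.call == Call.WIN_B:
                cats_won.add(o.microhabitat)
    if not cats_analyzed:
        raise TradeoffError(f"{species} not analyzed in any category for {metric}")
    return len(cats_won) / len(cats_analyzed)


def mean_wins(per_metric: dict[str, float]) -> float:
    """Unweighted mean of the four per-metric win proportions."""
    missing = [m for m in METRICS if m not in per_metric]
    if missing:
        raise TradeoffError(f"missing metrics: {missing}")
    return float(np.mean([per_metric[m] for m in METRICS]))


# ---------------------------------------------------------------------------
# Table builders over a full set of outcomes


def outcomes_to_frame(outcomes: list[PairOutcome]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "axis": o.microhabitat[0],
                "level": o.microhabitat[1],
                "metric": o.metric,
                "species_a": o.species_a,
                "species_b": o.species_b,
                "call": o.call.value,
            }
            for o in outcomes
        ],
        columns=["axis", "level", "metric", "species_a", "species_b", "call"],
    )


def microhabitat_tradeoff_table(outcomes: list[PairOutcome]) -> pd.DataFrame:
    """Per (pair, metric): win/tie counts and the rank-reversal flag."""
    rows = []
    pairs = sorted({(o.species_a, o.species_b) for o in outcomes})
    for a, b in pairs:
        for metric in METRICS:
            calls = [
                o.call
                for o in outcomes
                if o.metric == metric and (o.species_a, o.species_b) == (a, b)
            ]
            if not calls:
                continue
            rows.append(
                {
                    "species_a": a,
                    "species_b": b,
                    "metric": metric,
                    "n_categories": len(calls),
                    "n_win_a": sum(c == Call.WIN_A for c in calls),
                    "n_win_b": sum(c == Call.WIN_B for c in calls),
                    "n_tie": sum(c == Call.TIE for c in calls),
                    "microhabitat_tradeoff": microhabitat_tradeoff(calls),
                }
            )
    return pd.DataFrame(rows)


def growth_survival_table(outcomes: list[PairOutcome]) -> pd.DataFrame:
    """Per (pair, microhabitat, RGR metric): the growth-survival class."""
    by_key: dict = {}
    for o in outcomes:
        by_key[(o.species_a, o.species_b, o.microhabitat, o.metric)] = o.call
    rows = []
    pairs = sorted({(o.species_a, o.species_b) for o in outcomes})
    cats = sorted({o.microhabitat for o in outcomes})
    for a, b in pairs:
        for cat in cats:
            surv = by_key.get((a, b, cat, "survival"))
            if surv is None:
                continue
            for metric in ("rgr_ht", "rgr_pm", "rgr_la"):
                growth = by_key.get((a, b, cat, metric))
                if growth is None:
                    continue
                cls = growth_survival_tradeoff(growth, surv)
                rows.append(
                    {
                        "species_a": a,
                        "species_b": b,
                        "axis": cat[0],
                        "level": cat[1],
                        "rgr_metric": metric,
                        "classification": cls.value,
                    }
                )
    return pd.DataFrame(rows)


def light_cross_table(
    outcomes: list[PairOutcome],
    high_cell: tuple[str, str] = ("tpar", "high"),
    low_cell: tuple[str, str] = ("tpar", "low"),
) -> pd.DataFrame:
    """Per (pair, RGR metric): high-light growth vs low-light survival."""
    by_key: dict = {}
    for o in outcomes:
        by_key[(o.species_a, o.species_b, o.microhabitat, o.metric)] = o.call
    rows = []
    pairs = sorted({(o.species_a, o.species_b) for o in outcomes})
    for a, b in pairs:
        surv = by_key.get((a, b, low_cell, "survival"))
        for metric in ("rgr_ht", "rgr_pm", "rgr_la"):
            growth = by_key.get((a, b, high_cell, metric))
            flag = light_cross_tradeoff(growth, surv)
            rows.append(
                {
                    "species_a": a,
                    "species_b": b,
                    "rgr_metric": metric,
                    "defined": flag is not None,
                    "light_cross_tradeoff": bool(flag) if flag is not None else False,
                }
            )
    return pd.DataFrame(rows)


def wins_table(outcomes: list[PairOutcome]) -> pd.DataFrame:
    """Per-species win proportions per metric plus the mean-wins summary."""
    species = sorted(
        {o.species_a for o in outcomes} | {o.species_b for o in outcomes}
    )
    rows = []
    means = {}
    for sp in species:
        per_metric = {}
        for metric in METRICS:
            try:
                per_metric[metric] = wins_proportion(outcomes, sp, metric)
            except TradeoffError:
                per_metric[metric] = float("nan")
        for metric in METRICS:
            rows.append({"species": sp, "metric": metric, "proportion": per_metric[metric]})
        if all(np.isfinite(list(per_metric.values()))):
            means[sp] = mean_wins(per_metric)
        else:
            means[sp] = float("nan")
    for sp in species:
        rows.append({"species": sp, "metric": "mean_wins", "proportion": means[sp]})
    return pd.DataFrame(rows)
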