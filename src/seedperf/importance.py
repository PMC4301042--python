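"""LMG relative-importance decomposition of RGR variance among microhabitat
factor blocks, with initial height as an always-first covariate.

Each microhabitat axis enters as one block of reference-coded indicator
columns (aspect, elevation, slope, TPAR: 2 columns each; substrate: up to
5). The LMG share of a block is its sequential R-squared increment
averaged over every ordering of the blocks, with the covariate entered
first in all orderings. With at most six blocks the average is computed
exactly via subset weights (equivalent to enumerating all B! orderings):

    share(b) = sum over S not containing b of
               |S|! (B-|S|-1)! / B! * [R2(S + b) - R2(S)]

where every R2 includes the covariate. Shares are non-negative and sum to
total R2 minus the covariate-only R2.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TOPOGRAPHY_BLOCKS = ("aspect", "elevation", "slope")
MICROHABITAT_BLOCKS = ("aspect", "elevation", "slope", "tpar", "substrate")
MAX_BLOCKS = 6


class ImportanceError(ValueError):
    pass


@dataclass
class ImportanceResult:
    species: str
    metric: str
    total_r2: float
    covariate_r2: float
    shares: dict[str, float]  # raw LMG share per block
    normalized: dict[str, float] = field(default_factory=dict)  # percent of habitat R2
    n_obs: int = 0
    dropped_blocks: tuple[str, ...] = ()

    @property
    def topography_share(self) -> float:
        return sum(self.shares.get(b, 0.0) for b in TOPOGRAPHY_BLOCKS)

    @property
    def topography_percent(self) -> float:
        return sum(self.normalized.get(b, 0.0) for b in TOPOGRAPHY_BLOCKS)


# ---------------------------------------------------------------------------
# Design construction


def _reference_dummies(values: pd.Series) -> np.ndarray | None:
    levels = sorted(pd.unique(values))
    if len(levels) < 2:
        return None
    cols = [(values == lv).to_numpy(dtype=float) for lv in levels[1:]]
    return np.column_stack(cols)


def build_design(
    perf: pd.DataFrame, metric: str
) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray], tuple[str, ...]]:
    """Response, covariate, and indicator blocks for one species/metric.

    ``perf`` must carry the metric column, initial_height_cm, and the five
    cat_* columns. Rows with undefined RGR are dropped; factors with a
    single observed level are dropped from the block set with a warning.
    """
    sub = perf.dropna(subset=[metric])
    if len(sub) == 0:
        raise ImportanceError(f"no rows with defined {metric}")
    y = sub[metric].to_numpy(dtype=float)
    covariate = sub["initial_height_cm"].to_numpy(dtype=float)
    blocks: dict[str, np.ndarray] = {}
    dropped = []
    for block in MICROHABITAT_BLOCKS:
        dm = _reference_dummies(sub[f"cat_{block}"])
        if dm is None:
            dropped.append(block)
            warnings.warn(
                f"factor {block} has a single observed level; block dropped",
                stacklevel=2,
            )
        else:
            blocks[block] = dm
    return y, covariate, blocks, tuple(dropped)


# ---------------------------------------------------------------------------
# R-squared machinery


def _r2(y: np.ndarray, X: np.ndarray) -> float:
    coefs, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coefs
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ImportanceError("response has zero variance")
    return 1.0 - float(resid @ resid) / ss_tot


def _check_rank(y, covariate, blocks):
    names = list(blocks)
    cols = [np.ones_like(y)]
    if covariate is not None:
        cols.append(covariate)
    X = np.column_stack(cols + [blocks[b] for b in names])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify which block's columns are collinear with the rest
        cum = len(cols)
        for b in names:
            cum_next = cum + blocks[b].shape[1]
            r_without = np.linalg.matrix_rank(np.delete(X, range(cum, cum_next), axis=1))
            if r_without == rank:
                raise ImportanceError(f"design rank-deficient: block {b} collinear")
            cum = cum_next
        raise ImportanceError("design rank-deficient")


def lmg_shares(
    y: np.ndarray,
    covariate: np.ndarray | None,
    blocks: dict[str, np.ndarray],
    species: str = "",
    metric: str = "",
) -> ImportanceResult:
    """Exact LMG decomposition over block orderings (covariate always first)."""
    names = sorted(blocks)
    B = len(names)
    if B == 0:
        raise ImportanceError("no blocks")
    if B > MAX_BLOCKS:
        raise ImportanceError(f"exact enumeration limited to {MAX_BLOCKS} blocks")
    y = np.asarray(y, dtype=float)
    n = len(y)
    base_cols = [np.ones(n)]
    if covariate is not None:
        base_cols.append(np.asarray(covariate, dtype=float))
    p_total = sum(blocks[b].shape[1] for b in names) + len(base_cols)
    if n <= p_total + 2:
        raise ImportanceError("too few observations for the full design")
    _check_rank(y, base_cols[1] if covariate is not None else None, blocks)

    # R2 for every subset of blocks (covariate included in all models)
    r2_cache: dict[frozenset, float] = {}
    for r in range(B + 1):
        for subset in itertools.combinations(names, r):
            cols = list(base_cols) + [blocks[b] for b in subset]
            X = np.column_stack(cols) if len(cols) > 1 else np.ones((n, 1))
            r2_cache[frozenset(subset)] = _r2(y, X)

    covariate_r2 = r2_cache[frozenset()]
    total_r2 = r2_cache[frozenset(names)]

    shares = {}
    fact = math.factorial
    for b in names:
        others = [x for x in names if x != b]
        total = 0.0
        for r in range(B):
            w = fact(r) * fact(B - r - 1) / fact(B)
            for subset in itertools.combinations(others, r):
                s = frozenset(subset)
                total += w * (r2_cache[s | {b}] - r2_cache[s])
        shares[b] = total

    return ImportanceResult(
        species=species,
        metric=metric,
        total_r2=total_r2,
        covariate_r2=covariate_r2,
        shares=shares,
        n_obs=n,
    )


def normalize_shares(result: ImportanceResult) -> ImportanceResult:
    """Express each block share as a percentage of the microhabitat R2."""
    total = sum(result.shares.values())
    if total <= 0:
        raise ImportanceError("zero microhabitat variance; shares undefined")
    result.normalized = {b: 100.0 * s / total for b, s in result.shares.items()}
    return result


# ---------------------------------------------------------------------------
# Per-species driver and summary table


def importance_by_species(
    perf: pd.DataFrame, metrics=("rgr_ht", "rgr_pm", "rgr_la")
) -> list[ImportanceResult]:
    """Fit per-species, per-metric LMG decompositions on RGR responses."""
    results = []
    for sp in sorted(perf["species"].unique()):
        sub = perf[perf["species"] == sp]
        for metric in metrics:
            try:
                y, cov, blocks, dropped = build_design(sub, metric)
                res = lmg_shares(y, cov, blocks, species=sp, metric=metric)
                res.dropped_blocks = dropped
                normalize_shares(res)
            except ImportanceError:
                continue
            results.append(res)
    return results


def importance_table(results: list[ImportanceResult]) -> pd.DataFrame:
    """Stage table with per-species rows and species-averaged summary rows.

    Averaged rows use the unweighted mean of per-species normalized
    percentages per metric; the topography percentage is the sum of the
    aspect, elevation, and slope percentages.
    """
    rows = []
    for res in results:
        row = {
            "species": res.species,
            "metric": res.metric,
            "n_obs": res.n_obs,
            "covariate_r2": res.covariate_r2,
            "total_r2": res.total_r2,
        }
        for b in MICROHABITAT_BLOCKS:
            row[f"share_{b}"] = res.shares.get(b, 0.0)
            row[f"pct_{b}"] = res.normalized.get(b, 0.0)
        row["pct_topography"] = res.topography_percent
        rows.append(row)
    df = pd.DataFrame(rows)
    if len(df) == 0:
        return df
    for metric in sorted(df["metric"].unique()):
        sub = df[df["metric"] == metric]
        avg = {
            "species": "ALL",
            "metric": metric,
            "n_obs": int(sub["n_obs"].sum()),
            "covariate_r2": sub["covariate_r2"].mean(),
            "total_r2": sub["total_r2"].mean(),
        }
        for b in MICROHABITAT_BLOCKS:
            avg[f"share_{b}"] = sub[f"share_{b}"].mean()
            avg[f"pct_{b}"] = sub[f"pct_{b}"].mean()
        avg["pct_topography"] = sub["pct_topography"].mean()
        rows.append(avg)
    return pd.DataFrame(rows)
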