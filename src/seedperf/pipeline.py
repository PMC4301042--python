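"""End-to-end orchestration: simulate/categorize -> allometry ->
performance -> species comparisons -> trade-offs -> relative importance.

Stages communicate through on-disk CSV contracts in the run directory, so
any stage can be rerun or inspected in isolation. Output bundles are
deterministic for a fixed config and seed: stage timings go to stderr
only, and the on-disk run summary records only stage names, record
counts, and filter attrition.
"""

from __future__ import annotations

import json
import logging
import shutil
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import census_io
from .allometry import fit_all_species, models_from_table, models_to_table
from .habitats import (
    MicrohabitatScheme,
    assign_categories,
    enumerate_microhabitats,
)
from .importance import importance_by_species, importance_table
from .inference import ALPHA_DEFAULT, fit_category_metric
from .performance import (
    FIRST_YEAR_WINDOW_DAYS,
    MAX_INITIAL_HEIGHT_CM,
    PerformanceOptions,
    seedling_performance,
)
from .synthetic import SimulationConfig, generate_census, generate_landscape
from .tradeoffs import (
    METRICS,
    classify_pair,
    growth_survival_table,
    light_cross_table,
    microhabitat_tradeoff_table,
    outcomes_to_frame,
    wins_table,
)

logger = logging.getLogger("seedperf")

_CONFIG_KEYS = {
    "alpha",
    "min_subplots",
    "max_initial_height",
    "first_year_window",
    "tpar_cuts",
    "slope_cuts",
    "elevation_cuts",
    "seed",
}


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    alpha: float = ALPHA_DEFAULT
    min_subplots: int = 3
    max_initial_height: float = MAX_INITIAL_HEIGHT_CM
    first_year_window: tuple[float, float] = FIRST_YEAR_WINDOW_DAYS
    tpar_cuts: tuple[float, float] | None = None
    slope_cuts: tuple[float, float] | None = None
    elevation_cuts: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.min_subplots < 1:
            raise ConfigError("min_subplots must be >= 1")
        lo, hi = self.first_year_window
        if not 0 < lo < hi:
            raise ConfigError("first_year_window must be increasing and positive")


def validate_config(path) -> RunConfig:
    """Load a YAML config, rejecting unknown keys; empty file = defaults."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError("config must be a mapping")
    unknown = sorted(set(data) - _CONFIG_KEYS)
    if unknown:
        raise ConfigError(f"unknown config keys: {unknown}")
    if "first_year_window" in data:
        data["first_year_window"] = tuple(data["first_year_window"])
    for k in ("tpar_cuts", "slope_cuts", "elevation_cuts"):
        if data.get(k) is not None:
            data[k] = tuple(data[k])
    return RunConfig(**data)


# ---------------------------------------------------------------------------
# Stage functions (DataFrame in, DataFrame out)


def compare_all(
    perf: pd.DataFrame,
    scheme: MicrohabitatScheme,
    alpha: float = ALPHA_DEFAULT,
    min_subplots: int = 3,
):
    """Fit every (microhabitat, metric) cell and classify pair outcomes.

    ``perf`` is the performance table joined with the five cat_* columns.
    Returns (lsmeans table, contrasts table, list of PairOutcome).
    """
    perf = perf.copy()
    perf["survival"] = perf["survived_first_year"]
    lsm_rows = []
    con_rows = []
    outcomes = []
    for axis, level in enumerate_microhabitats(scheme):
        cell = perf[perf[f"cat_{axis}"] == level]
        for metric in METRICS:
            fitted = fit_category_metric(cell, metric, min_subplots=min_subplots)
            if fitted is None:
                continue
            fit, lsm, contrasts, _ = fitted
            for sp, est, se in zip(lsm.species, lsm.estimate, lsm.se):
                row = {
                    "axis": axis,
                    "level": level,
                    "metric": metric,
                    "species": sp,
                    "lsmean": est,
                    "se": se,
                }
                if lsm.probability is not None:
                    row["prob_scale"] = lsm.probability[lsm.species.index(sp)]
                else:
                    row["prob_scale"] = np.nan
                lsm_rows.append(row)
            for c in contrasts:
                con_rows.append(
                    {
                        "axis": axis,
                        "level": level,
                        "metric": metric,
                        "species_a": c.species_a,
                        "species_b": c.species_b,
                        "diff": c.estimate,
                        "se": c.se,
                        "z": c.z,
                        "p_raw": c.p_raw,
                        "p_shaffer": c.p_adjusted,
                    }
                )
                outcomes.append(
                    classify_pair(
                        lsm, c, alpha=alpha, microhabitat=(axis, level), metric=metric
                    )
                )
    return pd.DataFrame(lsm_rows), pd.DataFrame(con_rows), outcomes


def table1_like(perf: pd.DataFrame, wins: pd.DataFrame) -> pd.DataFrame:
    """Per-species summary: sample sizes, mean initial height, win rows."""
    rows = []
    for sp in sorted(perf["species"].unique()):
        sub = perf[perf["species"] == sp]
        row = {
            "species": sp,
            "n_rgr": int(sub["rgr_ht"].notna().sum()),
            "n_survival": int(sub["survived_first_year"].notna().sum()),
            "mean_initial_height_cm": float(sub["initial_height_cm"].mean()),
        }
        for metric in list(METRICS) + ["mean_wins"]:
            sel = wins[(wins["species"] == sp) & (wins["metric"] == metric)]
            row[f"wins_{metric}"] = (
                float(sel["proportion"].iloc[0]) if len(sel) else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pipeline driver


class _StageLog:
    def __init__(self):
        self.records = []

    def log(self, stage: str, records_in: int, records_out: int, **extra):
        filtered = records_in - records_out
        entry = {
            "stage": stage,
            "records_in": records_in,
            "records_out": records_out,
            "records_filtered": filtered,
            **extra,
        }
        assert records_in == records_out + filtered
        self.records.append(entry)
        logger.info("stage=%s in=%d out=%d filtered=%d", stage, records_in, records_out, filtered)


def simulate_bundle(out_dir, seed: int, config: SimulationConfig | None = None) -> None:
    """Write seedlings.csv, subplots.csv, harvest.csv, truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config or SimulationConfig()
    landscape = generate_landscape(cfg, seed)
    seedlings, harvest, truth = generate_census(cfg, landscape, seed)
    census_io.write_table(landscape, out / "subplots.csv")
    census_io.write_census(seedlings, out / "seedlings.csv")
    census_io.write_table(harvest, out / "harvest.csv")
    truth.to_json(out / "truth.json")


def run_pipeline(
    seedlings_path,
    subplots_path,
    harvest_path,
    out_dir,
    config: RunConfig | None = None,
) -> dict:
    """Execute all analysis stages, writing every stage table to out_dir.

    Returns a summary dict (also written as run_summary.json). On any
    stage failure the partially written output directory is removed and
    the error is re-raised with the stage name.
    """
    cfg = config or RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    slog = _StageLog()
    t0 = time.perf_counter()
    stage = "read"
    try:
        seedlings = census_io.read_census(seedlings_path)
        subplots = census_io.read_subplots(subplots_path)
        harvest = census_io.read_harvest(harvest_path)
        slog.log("read", len(seedlings), len(seedlings))

        stage = "categorize"
        scheme = MicrohabitatScheme.from_subplots(
            subplots,
            tpar_cuts=cfg.tpar_cuts,
            slope_cuts=cfg.slope_cuts,
            elevation_cuts=cfg.elevation_cuts,
        )
        assignments = assign_categories(seedlings, subplots, scheme)
        census_io.write_table(assignments, out / "assignments.csv")
        slog.log("categorize", seedlings["tag_id"].nunique(), len(assignments))

        stage = "allometry"
        models = fit_all_species(harvest)
        census_io.write_table(models_to_table(models), out / "allometry_models.csv")
        slog.log("allometry", len(harvest), len(harvest), n_species=len(models))

        stage = "performance"
        opts = PerformanceOptions(
            max_initial_height=cfg.max_initial_height,
            first_year_window=cfg.first_year_window,
        )
        perf = seedling_performance(seedlings, models, opts)
        perf = perf.merge(
            assignments.drop(columns=["species", "subplot_id"]),
            on="tag_id",
            validate="one_to_one",
        )
        census_io.write_table(perf, out / "performance.csv")
        slog.log(
            "performance",
            len(perf),
            int(perf["rgr_ht"].notna().sum()),
            n_survival=int(perf["survived_first_year"].notna().sum()),
        )

        stage = "compare"
        lsmeans, contrasts, outcomes = compare_all(
            perf, scheme, alpha=cfg.alpha, min_subplots=cfg.min_subplots
        )
        census_io.write_table(lsmeans, out / "lsmeans.csv")
        census_io.write_table(contrasts, out / "contrasts.csv")
        census_io.write_table(outcomes_to_frame(outcomes), out / "outcomes.csv")
        slog.log("compare", len(contrasts), len(contrasts))

        stage = "tradeoffs"
        tro = microhabitat_tradeoff_table(outcomes)
        gst = growth_survival_table(outcomes)
        lct = light_cross_table(outcomes)
        wins = wins_table(outcomes)
        census_io.write_table(tro, out / "tradeoffs.csv")
        census_io.write_table(gst, out / "gs_tradeoffs.csv")
        census_io.write_table(lct, out / "light_cross.csv")
        census_io.write_table(wins, out / "wins.csv")
        slog.log("tradeoffs", len(outcomes), len(outcomes))

        stage = "importance"
        results = importance_by_species(perf)
        census_io.write_table(importance_table(results), out / "importance.csv")
        slog.log("importance", len(perf), len(results))

        stage = "report"
        census_io.write_table(table1_like(perf, wins), out / "table1_like.csv")
        summary = {
            "alpha": cfg.alpha,
            "n_microhabitats": len(enumerate_microhabitats(scheme)),
            "stages": slog.records,
        }
        with open(out / "run_summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
        logger.info("pipeline done in %.1fs", time.perf_counter() - t0)
        return summary
    except Exception as exc:
        shutil.rmtree(out, ignore_errors=True)
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
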