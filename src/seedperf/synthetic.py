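"""Synthetic seedling-census generator with known ground truth.

Emulates the field design the analysis expects: 192 one-square-metre
subplots on a regular grid inside a mapped forest plot, four woody species
with strongly unequal abundances (tens to ~1500 seedlings), five censuses
over ~2.6 years, and measurement rounding to 0.5 cm.

The generative model mirrors the inferential model downstream:

* log-height growth rate of seedling i in subplot j:
      g_i = base_s + sum_axis eff_s[axis, level(j)] + u_j + e_i,
  with u_j ~ N(0, sigma_u^2) shared by all seedlings in a subplot and
  e_i ~ N(0, sigma_e^2) a seedling-level residual, so the downstream
  random-intercept model is correctly specified by construction;
* heights evolve as h(t) = h0 exp(g_i t) and are recorded after rounding
  to the 0.5 cm grid (floor 0.5 cm, since live seedlings have positive
  height);
* leaf counts follow a per-species count allometry on the log scale;
* mortality is an annual logistic hazard per species and habitat, applied
  per census interval, with its own subplot random intercept;
* the harvest set for allometric fitting is drawn from the same
  mass/area allometry truth that links height to mass and leaf area.

Ground truth (structural cell means, pairwise winners, trade-off flags)
is derived deterministically from the configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .census_io import SUBSTRATE_LEVELS, round_measurement
from .habitats import AXES, LEVEL_LABELS, ASPECT_LABELS

CONTINUOUS_LEVELS = {"tpar": LEVEL_LABELS, "slope": LEVEL_LABELS, "elevation": LEVEL_LABELS}
DAYS_PER_YEAR = 365.25


@dataclass
class SpeciesSpec:
    """One species' abundance, size, growth, and survival parameters."""

    name: str
    abundance: int
    base_growth: float  # baseline log-height RGR, 1/yr
    init_height_median: float  # cm
    init_height_sdlog: float
    # habitat effects on log-height growth (1/yr), per axis -> per level
    growth_effects: dict[str, dict[str, float]]
    # habitat effects on annual-survival log-odds, per axis -> per level
    survival_effects: dict[str, dict[str, float]]
    survival_base_logodds: float
    substrate_probs: tuple[float, ...]  # over the six substrates
    # allometry truth (log-log): mass ~ a + b ln h; area ~ a + b ln h + c ln n
    mass_coefs: tuple[float, float]
    mass_sdlog: float
    area_coefs: tuple[float, float, float]
    area_sdlog: float
    leaf_count_coefs: tuple[float, float]  # ln n = c0 + c1 ln h (+ noise)
    leaf_count_sdlog: float
    habitat_preference: float = 0.0  # placement bias along the TPAR gradient


@dataclass
class SimulationConfig:
    n_subplots: int = 192
    grid_shape: tuple[int, int] = (16, 12)
    census_days: tuple[float, ...] = (0.0, 380.0, 590.0, 760.0, 950.0)
    sigma_u_growth: float = 0.05  # subplot SD of log-height growth, 1/yr
    sigma_e_growth: float = 0.20  # seedling residual SD, 1/yr
    sigma_u_survival: float = 0.30  # subplot SD on the log-odds scale
    recruit_fracs: tuple[float, ...] = (0.70, 0.15, 0.10, 0.05, 0.0)
    n_harvest_per_species: int = 40
    species: list[SpeciesSpec] = field(default_factory=lambda: default_species())

    def __post_init__(self):
        if len(self.census_days) < 2:
            raise ValueError("need >= 2 census dates")
        if any(s.abundance < 0 for s in self.species):
            raise ValueError("abundances must be >= 0")


def _flat_effects(val: float = 0.0) -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {}
    for axis in ("tpar", "slope", "elevation"):
        out[axis] = {lvl: val for lvl in LEVEL_LABELS}
    out["aspect"] = {lab: val for lab in ASPECT_LABELS}
    out["substrate"] = {s: val for s in SUBSTRATE_LEVELS}
    return out


def _effects(**axis_overrides) -> dict[str, dict[str, float]]:
    eff = _flat_effects(0.0)
    for axis, mapping in axis_overrides.items():
        eff[axis].update(mapping)
    return eff


def default_species() -> list[SpeciesSpec]:
    """Four species mimicking the study community's structure.

    Abundances reproduce the strong imbalance of the focal community
    (~1460/340/1400/50). Growth bases and habitat interactions are set so
    that species ranks reverse across light and substrate categories and
    growth and survival ranks oppose each other in parts of the habitat
    space, giving the downstream trade-off detectors true positives with
    known location; magnitudes are kept within a realistic seedling RGR
    range (roughly 0.05-0.5 /yr).
    """
    # species codes follow the community roles: canopy dominant (MP),
    # two midstory trees (CT, CR), understory shrub (VC)
    return [
        SpeciesSpec(
            name="CT",
            abundance=1461,
            base_growth=0.10,
            init_height_median=2.9,
            init_height_sdlog=0.45,
            growth_effects=_effects(
                tpar={"low": 0.02, "high": -0.02},
                slope={"low": -0.02, "high": 0.02},
            ),
            survival_effects=_effects(
                tpar={"low": 0.4, "high": -0.2},
                substrate={"log": 0.8},
            ),
            survival_base_logodds=1.6,
            substrate_probs=(0.10, 0.15, 0.20, 0.05, 0.20, 0.30),
            mass_coefs=(-3.0, 1.6),
            mass_sdlog=0.25,
            area_coefs=(0.4, 0.7, 0.9),
            area_sdlog=0.15,
            leaf_count_coefs=(1.0, 1.1),
            leaf_count_sdlog=0.3,
            habitat_preference=-0.3,
        ),
        SpeciesSpec(
            name="CR",
            abundance=342,
            base_growth=0.18,
            init_height_median=3.8,
            init_height_sdlog=0.40,
            growth_effects=_effects(
                tpar={"low": -0.04, "high": 0.05},
                substrate={"log": -0.06, "root_mat": 0.04},
            ),
            survival_effects=_effects(
                tpar={"low": 0.2},
                substrate={"log": -0.5},
            ),
            survival_base_logodds=1.4,
            substrate_probs=(0.05, 0.15, 0.25, 0.05, 0.25, 0.25),
            mass_coefs=(-2.8, 1.5),
            mass_sdlog=0.25,
            area_coefs=(0.5, 0.8, 0.85),
            area_sdlog=0.15,
            leaf_count_coefs=(0.9, 1.2),
            leaf_count_sdlog=0.3,
            habitat_preference=0.2,
        ),
        SpeciesSpec(
            name="MP",
            abundance=1402,
            base_growth=0.28,
            init_height_median=0.9,
            init_height_sdlog=0.50,
            growth_effects=_effects(
                tpar={"low": -0.08, "high": 0.08},
                elevation={"low": 0.03, "high": -0.03},
                substrate={"dead_tree_fern": -0.10, "log": 0.05},
            ),
            survival_effects=_effects(
                tpar={"low": -0.6, "high": 0.3},
                substrate={"dead_tree_fern": -0.8},
            ),
            survival_base_logodds=1.2,
            substrate_probs=(0.20, 0.25, 0.20, 0.05, 0.15, 0.15),
            mass_coefs=(-3.4, 1.8),
            mass_sdlog=0.25,
            area_coefs=(0.2, 0.9, 0.8),
            area_sdlog=0.15,
            leaf_count_coefs=(1.1, 1.0),
            leaf_count_sdlog=0.3,
            habitat_preference=0.5,
        ),
        SpeciesSpec(
            name="VC",
            abundance=49,
            base_growth=0.22,
            init_height_median=4.0,
            init_height_sdlog=0.40,
            growth_effects=_effects(
                tpar={"low": 0.05, "high": -0.05},
                slope={"high": 0.04},
            ),
            survival_effects=_effects(
                tpar={"low": 0.7, "high": -0.3},
            ),
            survival_base_logodds=1.8,
            substrate_probs=(0.05, 0.10, 0.15, 0.10, 0.30, 0.30),
            mass_coefs=(-2.6, 1.4),
            mass_sdlog=0.25,
            area_coefs=(0.6, 0.75, 0.9),
            area_sdlog=0.15,
            leaf_count_coefs=(1.2, 1.05),
            leaf_count_sdlog=0.3,
            habitat_preference=-0.5,
        ),
    ]


def null_species(abundance: int = 400, n_species: int = 4) -> list[SpeciesSpec]:
    """Identical species (flat effects): the null configuration for
    calibration of false-positive rates."""
    base = default_species()[0]
    out = []
    for i in range(n_species):
        sp = SpeciesSpec(
            name=f"S{i + 1}",
            abundance=abundance,
            base_growth=0.2,
            init_height_median=2.5,
            init_height_sdlog=0.4,
            growth_effects=_flat_effects(0.0),
            survival_effects=_flat_effects(0.0),
            survival_base_logodds=1.5,
            substrate_probs=(1 / 6.0,) * 6,
            mass_coefs=base.mass_coefs,
            mass_sdlog=base.mass_sdlog,
            area_coefs=base.area_coefs,
            area_sdlog=base.area_sdlog,
            leaf_count_coefs=base.leaf_count_coefs,
            leaf_count_sdlog=base.leaf_count_sdlog,
            habitat_preference=0.0,
        )
        out.append(sp)
    return out


# ---------------------------------------------------------------------------
# Landscape


def generate_landscape(config: SimulationConfig, seed: int) -> pd.DataFrame:
    """Subplot environment table: smooth topography fields over the grid,
    uniform aspect, log-normal TPAR. Deterministic per seed."""
    rng = np.random.default_rng(seed)
    nx, ny = config.grid_shape
    n = config.n_subplots
    if nx * ny < n:
        raise ValueError("grid too small for n_subplots")
    xs, ys = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    xs = xs.ravel()[:n] / max(nx - 1, 1)
    ys = ys.ravel()[:n] / max(ny - 1, 1)

    def smooth_field(amplitude):
        # low-order trend plus a few random smooth harmonics
        a = rng.normal(0.0, 1.0, size=6)
        f = (
            a[0] * xs
            + a[1] * ys
            + a[2] * np.sin(2 * np.pi * xs + a[3])
            + a[4] * np.cos(2 * np.pi * ys + a[5])
        )
        f = f + 0.3 * rng.normal(size=n)
        return amplitude * (f - f.mean())

    elevation = 1120.0 + smooth_field(8.0)
    slope = np.abs(smooth_field(6.0)) + rng.uniform(0.0, 2.0, size=n)
    aspect = rng.uniform(0.0, 360.0, size=n)
    tpar = np.exp(rng.normal(np.log(0.05), 0.6, size=n))
    return pd.DataFrame(
        {
            "subplot_id": np.arange(1, n + 1),
            "slope_deg": slope,
            "aspect_deg": aspect,
            "elevation_m": elevation,
            "tpar": tpar,
        }
    )


# ---------------------------------------------------------------------------
# Census


def _subplot_categories(landscape: pd.DataFrame) -> pd.DataFrame:
    """Tertile/aspect labels for the generator's own habitat bookkeeping."""
    from .habitats import MicrohabitatScheme, categorize_subplots

    scheme = MicrohabitatScheme.from_subplots(landscape)
    return categorize_subplots(landscape, scheme)


def _axis_levels(axis: str) -> tuple[str, ...]:
    if axis == "aspect":
        return ASPECT_LABELS
    if axis == "substrate":
        return SUBSTRATE_LEVELS
    return LEVEL_LABELS


@dataclass
class GroundTruth:
    """Structural truth derived from the configuration.

    ``cell_effect[metric][species][(axis, level)]`` is the structural
    (habitat plus baseline) component of the cell mean on the model scale
    — log-height growth rate for the RGR metrics, annual-survival
    log-odds for survival. ``winner`` maps each (metric, axis, level,
    pair) to the species with the larger structural mean or "TIE" when
    equal; ``microhabitat_tradeoff`` flags pairs whose structural winner
    reverses across cells of the scheme.
    """

    cell_effect: dict
    winner: dict
    microhabitat_tradeoff: dict

    def to_json(self, path) -> None:
        def _keyed(d):
            if isinstance(d, dict):
                return {str(k): _keyed(v) for k, v in d.items()}
            return d

        with open(path, "w") as fh:
            json.dump(_keyed(self.__dict__), fh, indent=1, sort_keys=True)


def derive_ground_truth(config: SimulationConfig) -> GroundTruth:
    cell_effect: dict = {"rgr_ht": {}, "survival": {}}
    for sp in config.species:
        eff_g = {}
        eff_s = {}
        for axis in AXES:
            for lvl in _axis_levels(axis):
                eff_g[(axis, lvl)] = sp.base_growth + sp.growth_effects[axis][lvl]
                eff_s[(axis, lvl)] = (
                    sp.survival_base_logodds + sp.survival_effects[axis][lvl]
                )
        cell_effect["rgr_ht"][sp.name] = eff_g
        cell_effect["survival"][sp.name] = eff_s

    winner: dict = {}
    tradeoff: dict = {}
    names = [sp.name for sp in config.species]
    for metric in ("rgr_ht", "survival"):
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                wins_a = wins_b = 0
                for axis in AXES:
                    for lvl in _axis_levels(axis):
                        va = cell_effect[metric][a][(axis, lvl)]
                        vb = cell_effect[metric][b][(axis, lvl)]
                        w = "TIE" if va == vb else (a if va > vb else b)
                        winner[(metric, axis, lvl, a, b)] = w
                        wins_a += w == a
                        wins_b += w == b
                tradeoff[(metric, a, b)] = bool(wins_a and wins_b)
    return GroundTruth(
        cell_effect=cell_effect, winner=winner, microhabitat_tradeoff=tradeoff
    )


def generate_census(
    config: SimulationConfig, landscape: pd.DataFrame, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate the longitudinal census and the harvest set.

    Returns (seedlings, harvest, truth). The seedling table passes the
    census validators and uses the canonical schema.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC3]))
    cats = _subplot_categories(landscape).set_index("subplot_id")
    n_sub = len(landscape)
    subplot_ids = landscape["subplot_id"].to_numpy()
    tpar_z = (
        landscape["tpar"].rank(method="average").to_numpy() / n_sub - 0.5
    )  # placement bias axis

    u_growth = rng.normal(0.0, config.sigma_u_growth, size=n_sub)
    u_surv = rng.normal(0.0, config.sigma_u_survival, size=n_sub)

    days = np.asarray(config.census_days, dtype=float)
    dates = pd.Timestamp("2008-11-15") + pd.to_timedelta(days, unit="D")
    fracs = np.asarray(config.recruit_fracs[: len(days)], dtype=float)
    fracs = fracs / fracs.sum()

    rows = []
    tag_counter = 0
    for sp in config.species:
        # habitat-biased placement over subplots
        w = np.exp(sp.habitat_preference * tpar_z * 4.0)
        w = w / w.sum()
        placement = rng.choice(n_sub, size=sp.abundance, p=w)
        recruit_census = rng.choice(len(days), size=sp.abundance, p=fracs)
        h0 = sp.init_height_median * np.exp(
            rng.normal(0.0, sp.init_height_sdlog, size=sp.abundance)
        )
        substrate = rng.choice(
            len(SUBSTRATE_LEVELS), size=sp.abundance, p=np.asarray(sp.substrate_probs)
        )
        e_i = rng.normal(0.0, config.sigma_e_growth, size=sp.abundance)

        for i in range(sp.abundance):
            j = placement[i]
            sid = int(subplot_ids[j])
            sub_label = SUBSTRATE_LEVELS[substrate[i]]
            crow = cats.loc[sid]
            habitat = {
                "tpar": crow["cat_tpar"],
                "slope": crow["cat_slope"],
                "elevation": crow["cat_elevation"],
                "aspect": crow["cat_aspect"],
                "substrate": sub_label,
            }
            g = (
                sp.base_growth
                + sum(sp.growth_effects[ax][habitat[ax]] for ax in AXES)
                + u_growth[j]
                + e_i[i]
            )
            logodds = (
                sp.survival_base_logodds
                + sum(sp.survival_effects[ax][habitat[ax]] for ax in AXES)
                + u_surv[j]
            )
            p_annual = 1.0 / (1.0 + np.exp(-logodds))

            tag_counter += 1
            tag = f"{sp.name}-{tag_counter:05d}"
            k0 = int(recruit_census[i])
            t0 = days[k0]
            alive = True
            prev_height = None
            prev_leaves = None
            for k in range(k0, len(days)):
                t_years = (days[k] - t0) / DAYS_PER_YEAR
                if k > k0:
                    dt = (days[k] - days[k - 1]) / DAYS_PER_YEAR
                    if rng.random() > p_annual**dt:
                        alive = False
                true_h = h0[i] * np.exp(g * t_years)
                if alive:
                    rec_h = max(round_measurement(true_h), 0.5)
                    ln_n = (
                        sp.leaf_count_coefs[0]
                        + sp.leaf_count_coefs[1] * np.log(true_h)
                        + rng.normal(0.0, sp.leaf_count_sdlog)
                    )
                    rec_n = max(int(np.round(np.exp(ln_n))), 1)
                    prev_height, prev_leaves = rec_h, rec_n
                    status = "alive"
                else:
                    # dead seedlings retain their last measured height
                    rec_h = prev_height if prev_height is not None else max(
                        round_measurement(h0[i]), 0.5
                    )
                    rec_n = prev_leaves if prev_leaves is not None else 1
                    status = "dead"
                rows.append(
                    (
                        tag,
                        sp.name,
                        sid,
                        dates[k],
                        rec_h,
                        rec_n,
                        status,
                        sub_label,
                    )
                )
                if not alive:
                    break

    seedlings = pd.DataFrame(
        rows,
        columns=[
            "tag_id",
            "species",
            "subplot_id",
            "census_date",
            "height_cm",
            "leaf_count",
            "status",
            "substrate",
        ],
    )

    harvest = _generate_harvest(config, rng)
    truth = derive_ground_truth(config)
    return seedlings, harvest, truth


def _generate_harvest(config: SimulationConfig, rng) -> pd.DataFrame:
    rows = []
    for sp in config.species:
        n = config.n_harvest_per_species
        h = np.exp(rng.uniform(np.log(0.5), np.log(30.0), size=n))
        ln_n = (
            sp.leaf_count_coefs[0]
            + sp.leaf_count_coefs[1] * np.log(h)
            + rng.normal(0.0, sp.leaf_count_sdlog, size=n)
        )
        leaves = np.maximum(np.round(np.exp(ln_n)).astype(int), 1)
        mass = np.exp(
            sp.mass_coefs[0]
            + sp.mass_coefs[1] * np.log(h)
            + rng.normal(0.0, sp.mass_sdlog, size=n)
        )
        area = np.exp(
            sp.area_coefs[0]
            + sp.area_coefs[1] * np.log(h)
            + sp.area_coefs[2] * np.log(leaves)
            + rng.normal(0.0, sp.area_sdlog, size=n)
        )
        for i in range(n):
            rows.append((sp.name, h[i], leaves[i], mass[i], area[i]))
    return pd.DataFrame(
        rows, columns=["species", "height_cm", "leaf_count", "dry_mass_g", "leaf_area_cm2"]
    )


# ---------------------------------------------------------------------------
# Lightweight model-level simulators (calibration / power studies)


def simulate_gaussian_category(
    means: dict[str, float],
    n_per_species: dict[str, int],
    n_subplots: int,
    sigma_u: float,
    sigma_e: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw one (category, metric) cell directly from the random-intercept
    model: y = mean_s + u_subplot + e. Used for calibration and power
    studies where the full census machinery is unnecessary."""
    u = rng.normal(0.0, sigma_u, size=n_subplots)
    rows = []
    for sp in sorted(means):
        n = n_per_species[sp]
        sub = rng.integers(0, n_subplots, size=n)
        y = means[sp] + u[sub] + rng.normal(0.0, sigma_e, size=n)
        for i in range(n):
            rows.append((sp, int(sub[i]) + 1, y[i]))
    return pd.DataFrame(rows, columns=["species", "subplot_id", "y"])


def simulate_binomial_category(
    logodds: dict[str, float],
    n_per_species: dict[str, int],
    n_subplots: int,
    sigma_u: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Binary survival outcomes from the logistic random-intercept model."""
    u = rng.normal(0.0, sigma_u, size=n_subplots)
    rows = []
    for sp in sorted(logodds):
        n = n_per_species[sp]
        sub = rng.integers(0, n_subplots, size=n)
        p = 1.0 / (1.0 + np.exp(-(logodds[sp] + u[sub])))
        y = (rng.random(n) < p).astype(float)
        for i in range(n):
            rows.append((sp, int(sub[i]) + 1, y[i]))
    return pd.DataFrame(rows, columns=["species", "subplot_id", "y"])
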