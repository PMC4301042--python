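"""Per-species allometric models predicting whole-plant dry mass and total
leaf area from stem height and leaf count.

Models are ordinary least squares on the log-log scale:

    ln(mass) = a + b ln(height)
    ln(area) = a + b_h ln(height) + b_n ln(leaf_count)

Predictions back-transform by plain exponentiation (no smearing/Baskerville
bias correction; a known, documented systematic choice), so predicted sizes
are strictly positive and monotone in height. R-squared is reported on the
fitting (log) scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MIN_HARVEST_RECORDS = 4


class AllometryError(ValueError):
    pass


@dataclass(frozen=True)
class AllometricModel:
    species: str
    mass_coefs: tuple[float, float]  # (intercept, slope on ln height)
    area_coefs: tuple[float, float, float]  # (intercept, ln height, ln leaves)
    r2_mass: float
    r2_area: float
    n_fit: int


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    coefs, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coefs
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return coefs, r2


def fit_allometry(harvest: pd.DataFrame, species: str) -> AllometricModel:
    """Fit the two log-log regressions for one species from harvested plants."""
    sub = harvest[harvest["species"] == species]
    n = len(sub)
    if n < MIN_HARVEST_RECORDS:
        raise AllometryError(
            f"{species}: {n} harvest records, need >= {MIN_HARVEST_RECORDS}"
        )
    h = sub["height_cm"].to_numpy(dtype=float)
    m = sub["dry_mass_g"].to_numpy(dtype=float)
    la = sub["leaf_area_cm2"].to_numpy(dtype=float)
    nl = sub["leaf_count"].to_numpy(dtype=float)
    if np.any(h <= 0) or np.any(m <= 0) or np.any(la <= 0) or np.any(nl < 1):
        raise AllometryError(f"{species}: non-positive harvest measurement")

    lh = np.log(h)
    Xm = np.column_stack([np.ones(n), lh])
    cm, r2m = _ols(Xm, np.log(m))
    Xa = np.column_stack([np.ones(n), lh, np.log(nl)])
    ca, r2a = _ols(Xa, np.log(la))
    return AllometricModel(
        species=species,
        mass_coefs=(float(cm[0]), float(cm[1])),
        area_coefs=(float(ca[0]), float(ca[1]), float(ca[2])),
        r2_mass=float(r2m),
        r2_area=float(r2a),
        n_fit=n,
    )


def fit_all_species(harvest: pd.DataFrame) -> dict[str, AllometricModel]:
    return {
        sp: fit_allometry(harvest, sp) for sp in sorted(harvest["species"].unique())
    }


def predict_size(model: AllometricModel, height, leaf_count):
    """Predicted (dry mass g, total leaf area cm2) for measured seedlings."""
    h = np.asarray(height, dtype=float)
    n = np.asarray(leaf_count, dtype=float)
    if np.any(h <= 0):
        raise AllometryError("height must be positive")
    if np.any(n < 1):
        raise AllometryError("leaf count must be >= 1")
    a0, a1 = model.mass_coefs
    b0, b1, b2 = model.area_coefs
    mass = np.exp(a0 + a1 * np.log(h))
    area = np.exp(b0 + b1 * np.log(h) + b2 * np.log(n))
    if np.isscalar(height) or h.ndim == 0:
        return float(mass), float(area)
    return mass, area


def models_to_table(models: dict[str, AllometricModel]) -> pd.DataFrame:
    """Serialize fitted models to a plain-text coefficient table."""
    rows = []
    for sp in sorted(models):
        m = models[sp]
        rows.append(
            {
                "species": sp,
                "mass_intercept": m.mass_coefs[0],
                "mass_slope_ln_height": m.mass_coefs[1],
                "area_intercept": m.area_coefs[0],
                "area_slope_ln_height": m.area_coefs[1],
                "area_slope_ln_leaves": m.area_coefs[2],
                "r2_mass": m.r2_mass,
                "r2_area": m.r2_area,
                "n_fit": m.n_fit,
            }
        )
    return pd.DataFrame(rows)


def models_from_table(table: pd.DataFrame) -> dict[str, AllometricModel]:
    out = {}
    for _, r in table.iterrows():
        out[r["species"]] = AllometricModel(
            species=r["species"],
            mass_coefs=(float(r["mass_intercept"]), float(r["mass_slope_ln_height"])),
            area_coefs=(
                float(r["area_intercept"]),
                float(r["area_slope_ln_height"]),
                float(r["area_slope_ln_leaves"]),
            ),
            r2_mass=float(r["r2_mass"]),
            r2_area=float(r["r2_area"]),
            n_fit=int(r["n_fit"]),
        )
    return out
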