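import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20140909)


@pytest.fixture
def tiny_census():
    """Three seedlings, hand-authored: one grows, one dies in year one,
    one is tagged at the final census."""
    rows = [
        # tag, species, subplot, date, height, leaves, status, substrate
        ("t1", "MP", 1, "2008-11-15", 2.0, 3, "alive", "soil"),
        ("t1", "MP", 1, "2009-11-15", 4.0, 6, "alive", "soil"),
        ("t2", "CT", 2, "2008-11-15", 3.0, 4, "alive", "log"),
        ("t2", "CT", 2, "2009-11-20", 3.0, 4, "dead", "log"),
        ("t3", "VC", 3, "2009-11-20", 5.0, 8, "alive", "root_mat"),
    ]
    df = pd.DataFrame(
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
    df["census_date"] = pd.to_datetime(df["census_date"])
    return df


@pytest.fixture
def identity_models():
    """Allometric models with mass = height (identity on the log scale)."""
    from seedperf.allometry import AllometricModel

    out = {}
    for sp in ("MP", "CT", "VC", "CR"):
        out[sp] = AllometricModel(
            species=sp,
            mass_coefs=(0.0, 1.0),
            area_coefs=(0.0, 1.0, 0.0),
            r2_mass=1.0,
            r2_area=1.0,
            n_fit=10,
        )
    return out
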