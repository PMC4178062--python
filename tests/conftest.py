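import numpy as np
import pandas as pd
import pytest

from stockid.synthetic import SyntheticConfig, default_config


@pytest.fixture(scope="session")
def default_cfg() -> SyntheticConfig:
    return default_config(seed=0)


def small_config(seed=0, n_per_stratum=10, resid_sd=0.05, group_dev=None,
                 slopes=None, characters=("c1", "c2", "c3"), fa=False):
    """Compact three-group, two-sex synthetic config for unit tests."""
    characters = list(characters)
    group_dev = group_dev or {}
    slopes = slopes or {}
    raw = {
        "seed": seed,
        "n_per_stratum": n_per_stratum,
        "tl_mean_mm": 864.0,
        "tl_sd_mm": 60.0,
        "groups": ["g1", "g2", "g3"],
        "rivers": {"g1": ["r1"], "g2": ["r2"], "g3": ["r3"]},
        "sexes": ["male", "female"],
        "total_mass": {
            "male": [0.0898, 2.1209],
            "female": [0.0568, 2.2342],
            "resid_sd": 0.08,
        },
        "characters": {
            c: {
                "male": 4.0,
                "female": 4.0,
                "slope": slopes.get(c, 1.0),
                "resid_sd": resid_sd,
                "group_dev": group_dev.get(c, [0.0, 0.0, 0.0]),
            }
            for c in characters
        },
    }
    if fa:
        raw["fatty_acids"] = {
            "dispersion": 0.3,
            "means": {
                "g1": {"C16:0": 30.0, "C18:0": 20.0, "C18:1ω9": 25.0,
                       "C22:6ω3": 25.0},
                "g2": {"C16:0": 40.0, "C18:0": 15.0, "C18:1ω9": 25.0,
                       "C22:6ω3": 20.0},
                "g3": {"C16:0": 25.0, "C18:0": 20.0, "C17:0": 10.0,
                       "C22:6ω3": 45.0},
            },
        }
    return SyntheticConfig.from_dict(raw)


@pytest.fixture
def three_group_blobs():
    """Well-separated 3-group Gaussian data for discriminant tests."""
    rng = np.random.default_rng(42)
    centers = np.array([[0.0, 0.0, 0.0], [3.0, 0.5, 0.0], [0.5, 3.0, 1.0]])
    X = np.vstack([c + rng.normal(size=(25, 3)) for c in centers])
    y = np.repeat(["a", "b", "c"], 25)
    return X, y
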