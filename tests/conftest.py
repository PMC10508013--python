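import numpy as np
import pandas as pd
import pytest


def random_table(rng: np.random.Generator, n: int, n_provinces: int = 4) -> pd.DataFrame:
    """A random valid household table exercising all indicator edge regions.

    OOP is a mixture of exact zeros, small amounts, and catastrophic amounts;
    a few rows report food above total consumption (kept, flagged downstream).
    """
    consumption = rng.lognormal(9.5, 1.0, size=n)
    food_frac = rng.uniform(0.05, 1.1, size=n)  # occasionally > 1 (D1 region)
    kind = rng.random(n)
    oop = np.where(
        kind < 0.25,
        0.0,
        np.where(
            kind < 0.75,
            rng.lognormal(5.5, 1.2, size=n),
            rng.uniform(0.0, 1.5, size=n) * consumption,
        ),
    )
    return pd.DataFrame(
        {
            "household_id": [f"H{i:05d}" for i in range(n)],
            "survey_id": "rand",
            "wave_year": 2017,
            "urban": rng.integers(0, 2, size=n),
            "province": [f"P{p}" for p in rng.integers(0, n_provinces, size=n)],
            "family_size": (1 + rng.poisson(1.8, size=n)).astype(float),
            "income_total": rng.lognormal(10.0, 1.0, size=n),
            "consumption_total": consumption,
            "food_expenditure": food_frac * consumption,
            "oop_health_expenditure": oop,
            "weight": rng.lognormal(0.0, 0.6, size=n),
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20170919)


@pytest.fixture
def small_table(rng):
    return random_table(rng, 50)
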