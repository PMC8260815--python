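import numpy as np
import pandas as pd
import pytest

from pqctlong.lmm import GROUP_LESS, GROUP_WELL


def simulate_cs_cohort(
    n_per_group: int,
    interaction: float,
    sigma_b: float,
    sigma_e: float,
    seed: int,
    mu: float = 400.0,
    change_lt: float = -10.0,
    age_slope: float = 0.0,
    outcome: str = "y",
    follow_missing: float = 0.0,
) -> pd.DataFrame:
    """Two-occasion cohort with exact compound-symmetry covariance.

    Independent of :mod:`pqctlong.cohortsim`; used as the generating truth
    for calibration checks of the mixed model.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(2 * n_per_group):
        group = GROUP_WELL if i < n_per_group else GROUP_LESS
        age = rng.uniform(40.0, 85.0)
        b = rng.normal(0.0, sigma_b)
        mean = mu + age_slope * (age - 62.5)
        y0 = mean + b + rng.normal(0.0, sigma_e)
        change = change_lt + (interaction if group == GROUP_WELL else 0.0)
        y1 = mean + change + b + rng.normal(0.0, sigma_e)
        if follow_missing > 0 and rng.random() < follow_missing:
            y1 = np.nan
        rows.append(
            dict(subject=f"S{i:04d}", group=group, age0=age, occasion=0, outcome=outcome, value=y0)
        )
        rows.append(
            dict(subject=f"S{i:04d}", group=group, age0=age, occasion=10, outcome=outcome, value=y1)
        )
    return pd.DataFrame(rows)


@pytest.fixture
def small_cohort():
    return simulate_cs_cohort(30, 8.0, 30.0, 10.0, seed=7)
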