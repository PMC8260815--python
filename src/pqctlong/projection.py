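"""Cross-sectional age projection versus longitudinal change.

A cross-sectional linear model of the baseline trait on continuous age
yields a predicted per-decade change, 100 * (10 * slope) / EMM, where the
estimated marginal mean (EMM) is the fitted value at the sample mean
baseline age.  Contrasting this with the per-decade change estimated by
the longitudinal mixed model (pooled over groups, weighted by group size)
quantifies how far age-gradient extrapolation misses true within-person
aging — e.g. under a birth-cohort gradient in the baselines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .lmm import GROUP_LESS, GROUP_WELL, FitResult

__all__ = [
    "CrossSectionalFit",
    "cross_sectional_projection",
    "compare_projection_to_longitudinal",
]


@dataclass
class CrossSectionalFit:
    """OLS age trend of one baseline outcome."""

    outcome: str
    slope: float  # units / year
    slope_se: float
    emm: float  # fitted value at the mean baseline age
    reference_age: float
    pct_per_decade: float
    n: int


def cross_sectional_projection(
    table: pd.DataFrame, outcome: str, by_group: str | None = None
) -> CrossSectionalFit:
    """OLS of baseline value on continuous age; %/decade at the mean age.

    ``by_group`` restricts the regression to one group; the default pools
    all participants.
    """
    sub = table[
        (table["outcome"] == outcome)
        & (table["occasion"] == 0)
        & table["value"].notna()
    ]
    if by_group is not None:
        sub = sub[sub["group"] == by_group]
    if len(sub) < 3:
        raise ValueError("need at least three baseline observations")
    age = sub["age0"].to_numpy(dtype=float)
    if np.ptp(age) == 0:
        raise ValueError("degenerate age variance")
    y = sub["value"].to_numpy(dtype=float)
    res = sm.OLS(y, sm.add_constant(age)).fit()
    ref_age = float(age.mean())
    emm = float(res.params[0] + res.params[1] * ref_age)
    slope = float(res.params[1])
    if emm <= 0:
        raise ValueError("non-positive estimated marginal mean")
    return CrossSectionalFit(
        outcome=outcome,
        slope=slope,
        slope_se=float(res.bse[1]),
        emm=emm,
        reference_age=ref_age,
        pct_per_decade=100.0 * (10.0 * slope) / emm,
        n=len(sub),
    )


def compare_projection_to_longitudinal(
    table: pd.DataFrame, fits: dict[str, FitResult]
) -> pd.DataFrame:
    """Per-outcome cross-sectional vs longitudinal %/decade table.

    The longitudinal %/decade pools the two groups' estimated changes and
    baselines weighted by group size.  Outcomes lacking either a fit or
    enough baseline data are skipped.
    """
    rows = []
    for outcome, fit in fits.items():
        try:
            cs = cross_sectional_projection(table, outcome)
        except ValueError:
            continue
        est = fit.group_estimates()
        n_wt = int(
            table[
                (table["outcome"] == outcome)
                & (table["occasion"] == 0)
                & (table["group"] == GROUP_WELL)
                & table["value"].notna()
            ]["subject"].nunique()
        )
        n_lt = int(
            table[
                (table["outcome"] == outcome)
                & (table["occasion"] == 0)
                & (table["group"] == GROUP_LESS)
                & table["value"].notna()
            ]["subject"].nunique()
        )
        w = np.array([n_wt, n_lt], dtype=float)
        w = w / w.sum()
        change = w[0] * est[GROUP_WELL]["change"] + w[1] * est[GROUP_LESS]["change"]
        baseline = w[0] * est[GROUP_WELL]["baseline"] + w[1] * est[GROUP_LESS]["baseline"]
        long_pct = 100.0 * change / baseline
        rows.append(
            {
                "outcome": outcome,
                "cross_sectional_pct_per_decade": cs.pct_per_decade,
                "longitudinal_pct_per_decade": long_pct,
                "difference": long_pct - cs.pct_per_decade,
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out.loc["mean"] = [
            "mean",
            out["cross_sectional_pct_per_decade"].mean(),
            out["longitudinal_pct_per_decade"].mean(),
            out["difference"].mean(),
        ]
    return out.reset_index(drop=True)
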