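"""Random-intercept linear mixed models for two-occasion cohorts.

Per outcome the model is

    y_ij = b0 + b1*group_i + b2*time_ij + b3*group_i*time_ij
           + b4*(age_i - mean age) + u_i + e_ij,

with a subject random intercept u_i ~ N(0, sigma_b^2) and residual
e_ij ~ N(0, sigma_e^2), i.e. a compound-symmetry covariance within
subject.  ``group`` is 1 for the well-trained and 0 for the less-trained
athletes and ``time`` is 0/1 for the baseline/10-year occasion, so b2 is
the less-trained 10-year change, b2 + b3 the well-trained change, and b3
the group-by-time interaction of interest.

With at most two occasions the covariance has a single free ratio
gamma = sigma_b^2 / sigma_e^2, so (RE)ML reduces to a one-dimensional
profiled search over gamma with closed-form GLS fixed effects at each
candidate — no general mixed-model optimizer is needed and the fit is
deterministic.  All available records are used: subjects missing the
follow-up occasion still inform baseline means and variance components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "FitResult",
    "fit_random_intercept_model",
    "estimated_group_changes",
    "baseline_group_test",
    "GROUP_WELL",
    "GROUP_LESS",
]

GROUP_WELL = "well-trained"
GROUP_LESS = "less-trained"

_PARAM_NAMES = ("intercept", "group", "time", "group_time", "age_c")


@dataclass
class FitResult:
    """Fixed effects, variance components and derived group summaries."""

    outcome: str
    params: pd.Series  # intercept, group, time, group_time[, age_c]
    cov: pd.DataFrame
    sigma_b2: float
    sigma_e2: float
    loglik: float  # restricted (or full-ML) log-likelihood
    method: str  # "reml" or "ml"
    converged: bool
    n_obs: int
    n_subjects: int
    mean_age: float

    @property
    def interaction(self) -> float:
        return float(self.params["group_time"])

    @property
    def interaction_se(self) -> float:
        return float(np.sqrt(self.cov.loc["group_time", "group_time"]))

    @property
    def df_within(self) -> float:
        """Containment denominator df for within-subject effects.

        Observations minus subjects minus the two within-subject fixed
        effects (time, group x time) — the classical df a nested-levels
        mixed-model fitter assigns to level-1 terms.
        """
        return float(max(self.n_obs - self.n_subjects - 2, 1))

    @property
    def interaction_p(self) -> float:
        """Two-sided Wald p-value with a t reference (containment df)."""
        z = self.interaction / self.interaction_se
        return float(2.0 * stats.t.sf(abs(z), self.df_within))

    def group_estimates(self) -> dict[str, dict[str, float]]:
        """Estimated baseline mean and 10-year change per group (at mean age)."""
        out = {}
        for group, g in ((GROUP_LESS, 0.0), (GROUP_WELL, 1.0)):
            c_bl = self._contrast({"intercept": 1.0, "group": g})
            c_ch = self._contrast({"time": 1.0, "group_time": g})
            out[group] = {
                "baseline": self._apply(c_bl),
                "baseline_se": self._se(c_bl),
                "change": self._apply(c_ch),
                "change_se": self._se(c_ch),
            }
        return out

    def _contrast(self, weights: dict[str, float]) -> np.ndarray:
        c = np.zeros(len(self.params))
        for name, w in weights.items():
            c[list(self.params.index).index(name)] = w
        return c

    def _apply(self, c: np.ndarray) -> float:
        return float(c @ self.params.to_numpy())

    def _se(self, c: np.ndarray) -> float:
        return float(np.sqrt(c @ self.cov.to_numpy() @ c))


def _design(
    table: pd.DataFrame, outcome: str, use_age: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, list[str]]:
    sub = table[(table["outcome"] == outcome) & table["value"].notna()].copy()
    if sub.empty:
        raise ValueError(f"no records for outcome {outcome!r}")
    groups = set(sub["group"])
    unknown = groups - {GROUP_WELL, GROUP_LESS}
    if unknown:
        raise ValueError(f"unknown group labels {sorted(unknown)}")
    # canonical record order makes the fit invariant to input permutations
    sub = sub.sort_values(["subject", "occasion"], kind="mergesort")
    y = sub["value"].to_numpy(dtype=float)
    g = (sub["group"] == GROUP_WELL).to_numpy(dtype=float)
    time = sub["occasion"].to_numpy(dtype=float) / 10.0
    baseline_ages = sub.drop_duplicates("subject")["age0"]
    mean_age = float(baseline_ages.mean())
    cols = [np.ones_like(y), g, time, g * time]
    names = list(_PARAM_NAMES[:4])
    if use_age:
        cols.append(sub["age0"].to_numpy(dtype=float) - mean_age)
        names.append("age_c")
    X = np.column_stack(cols)
    subj_codes = pd.factorize(sub["subject"], sort=True)[0]
    return y, X, subj_codes, mean_age, names


class _Profile:
    """Profiled (RE)ML criterion over gamma = sigma_b^2 / sigma_e^2."""

    def __init__(self, y: np.ndarray, X: np.ndarray, subj: np.ndarray, reml: bool):
        self.y, self.X, self.reml = y, X, reml
        self.N, self.p = X.shape
        m = subj.max() + 1
        self.n_i = np.bincount(subj, minlength=m).astype(float)
        self.S = np.zeros((m, self.p))  # per-subject column sums of X
        np.add.at(self.S, subj, X)
        self.t = np.bincount(subj, weights=y, minlength=m)
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)

    def solve(self, gamma: float):
        c = gamma / (1.0 + self.n_i * gamma)
        XWX = self.XtX - (self.S * c[:, None]).T @ self.S
        XWy = self.Xty - self.S.T @ (c * self.t)
        yWy = self.yty - float(c @ (self.t * self.t))
        beta = np.linalg.solve(XWX, XWy)
        rss = max(yWy - float(beta @ XWy), 1e-300)
        return beta, rss, XWX

    def minus2ll(self, gamma: float) -> float:
        _, rss, XWX = self.solve(gamma)
        logdet_v = float(np.log1p(self.n_i * gamma).sum())
        sign, logdet_x = np.linalg.slogdet(XWX)
        if self.reml:
            df = self.N - self.p
            s2 = rss / df
            return df * np.log(2.0 * np.pi * s2) + df + logdet_v + logdet_x
        s2 = rss / self.N
        return self.N * np.log(2.0 * np.pi * s2) + self.N + logdet_v

    def minus2ll_at(self, gamma: float, sigma_e2: float) -> float:
        """Criterion at explicit variance components (no profiling)."""
        beta, rss, XWX = self.solve(gamma)
        logdet_v = self.N * np.log(sigma_e2) + float(np.log1p(self.n_i * gamma).sum())
        out = logdet_v + rss / sigma_e2 + self.N * np.log(2.0 * np.pi)
        if self.reml:
            _, logdet_x = np.linalg.slogdet(XWX)
            out += logdet_x - self.p * np.log(sigma_e2)
        return out


def fit_random_intercept_model(
    table: pd.DataFrame,
    outcome: str,
    covariates: tuple[str, ...] = ("age",),
    reml: bool = True,
) -> FitResult:
    """Fit the per-outcome random-intercept model by profiled (RE)ML.

    ``table`` is a long-format measurement table with columns ``subject``,
    ``group``, ``age0``, ``occasion``, ``outcome``, ``value``.  Occasions
    other than 0/10 years are treated as continuous time in decades.
    """
    use_age = "age" in covariates
    y, X, subj, mean_age, names = _design(table, outcome, use_age)
    n_subjects = int(subj.max()) + 1
    for grp in (0.0, 1.0):
        if (X[:, 1] == grp)[X[:, 2] == 0.0].sum() < 2:
            raise ValueError("each group needs at least two baseline records")

    prof = _Profile(y, X, subj, reml)
    converged = True
    if np.ptp(y) == 0.0:  # zero-variance outcome: boundary solution
        gamma = 0.0
    else:
        res = optimize.minimize_scalar(
            lambda u: prof.minus2ll(np.exp(u)),
            bounds=(-18.0, 18.0),
            method="bounded",
            options={"xatol": 1e-10},
        )
        converged = bool(res.success)
        gamma = float(np.exp(res.x))
        if prof.minus2ll(0.0) <= res.fun:  # boundary sigma_b^2 = 0
            gamma = 0.0
    beta, rss, XWX = prof.solve(gamma)
    df = prof.N - prof.p if reml else prof.N
    sigma_e2 = rss / df
    sigma_b2 = gamma * sigma_e2
    cov = sigma_e2 * np.linalg.inv(XWX)
    loglik = -0.5 * prof.minus2ll_at(gamma, sigma_e2)
    return FitResult(
        outcome=outcome,
        params=pd.Series(beta, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        sigma_b2=float(sigma_b2),
        sigma_e2=float(sigma_e2),
        loglik=float(loglik),
        method="reml" if reml else "ml",
        converged=converged,
        n_obs=prof.N,
        n_subjects=n_subjects,
        mean_age=mean_age,
    )


def restricted_loglik(fit: FitResult, table: pd.DataFrame, sigma_b2: float, sigma_e2: float) -> float:
    """Criterion of ``fit``'s model evaluated at given variance components."""
    use_age = "age_c" in fit.params.index
    y, X, subj, _, _ = _design(table, fit.outcome, use_age)
    prof = _Profile(y, X, subj, fit.method == "reml")
    return -0.5 * prof.minus2ll_at(sigma_b2 / sigma_e2, sigma_e2)


def estimated_group_changes(fit: FitResult, alpha: float = 0.05) -> dict[str, dict[str, float]]:
    """Per-group estimated 10-year change with a t-based Wald CI.

    Pass the unadjusted level (0.05) or a multiplicity-adjusted alpha to
    obtain the corresponding wider simultaneous intervals.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if not fit.converged:
        raise ValueError("fit did not converge")
    z = stats.t.ppf(1.0 - alpha / 2.0, fit.df_within)
    out = {}
    for group, est in fit.group_estimates().items():
        half = z * est["change_se"]
        out[group] = {
            "change": est["change"],
            "se": est["change_se"],
            "ci_low": est["change"] - half,
            "ci_high": est["change"] + half,
            "baseline": est["baseline"],
            "baseline_se": est["baseline_se"],
        }
    return out


def baseline_group_test(table: pd.DataFrame, outcome: str) -> tuple[float, float]:
    """Welch two-sample t test on baseline values; returns (t, two-sided p)."""
    sub = table[
        (table["outcome"] == outcome)
        & (table["occasion"] == 0)
        & table["value"].notna()
    ]
    a = sub.loc[sub["group"] == GROUP_WELL, "value"].to_numpy(dtype=float)
    b = sub.loc[sub["group"] == GROUP_LESS, "value"].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two baseline observations")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
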