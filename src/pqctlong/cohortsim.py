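"""Synthetic two-group, two-occasion longitudinal cohorts.

The generator emulates the design the longitudinal analysis assumes: two
training groups measured at baseline and ~10 years later on K outcomes.
For subject i, outcome k and occasion indicator occ (0/1):

    y_i0k = mu_k + a_k * (age_i - mean age) + b_ik + e_i0k
    y_i1k = y's mean structure + Delta_k + delta_k * 1[well-trained]
            + b_ik + e_i0k + w_ik

where b_ik ~ N(0, sigma_bk^2) is between-subject heterogeneity, e_i0k ~
N(0, sigma_ek^2) is measurement error and w_i. is a multivariate-normal
increment with per-outcome SD sigma_dk and a common correlation matrix R.
Building the follow-up value on top of the baseline residual makes the
per-subject change scores exactly Delta_k + delta_k*group + w_ik, so their
cross-outcome correlation matrix is exactly R — the quantity the
multiplicity correction consumes.  With sigma_dk = sqrt(2)*sigma_ek the
occasions are marginally exchangeable (compound symmetry) as the mixed
model assumes.

The shipped default configuration (``CohortSpec.reference()``) mirrors
the published table magnitudes for 19 tibial outcomes, so a reference
cohort is one call (or one CLI command) away.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .lmm import GROUP_LESS, GROUP_WELL

__all__ = ["OutcomeSpec", "CohortSpec", "simulate_cohort"]


@dataclass
class OutcomeSpec:
    """Population parameters of one outcome, in outcome units."""

    baseline_mean: float
    baseline_sd: float
    change_lt: float  # mean 10-year change in the less-trained group
    group_time_effect: float  # WT minus LT difference in change (interaction)


@dataclass
class CohortSpec:
    """Design and distribution parameters of a simulated cohort."""

    outcomes: dict[str, OutcomeSpec]
    n_well_trained: int = 36
    n_less_trained: int = 33
    age_mean: float = 60.6
    age_sd: float = 11.1
    age_min: float = 40.0
    age_max: float = 85.0
    age_slope_pct_per_decade: float = -3.4
    cv_rms_pct: float = 1.0  # measurement error, % of baseline mean
    change_sd_pct: float | None = None  # None -> sqrt(2) x measurement error
    change_corr: np.ndarray | None = None  # K x K; None -> identity
    followup_missing_rate: float = 0.0
    dropout_rate: float = 0.0  # whole-subject loss of the follow-up visit
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_well_trained < 2 or self.n_less_trained < 2:
            raise ValueError("need at least two subjects per group")
        if not self.outcomes:
            raise ValueError("at least one outcome is required")
        k = len(self.outcomes)
        if self.change_corr is not None:
            r = np.asarray(self.change_corr, dtype=float)
            if r.shape != (k, k):
                raise ValueError("correlation matrix shape must match outcomes")
            if not np.allclose(r, r.T, atol=1e-10) or not np.allclose(
                np.diag(r), 1.0, atol=1e-10
            ):
                raise ValueError("correlation matrix must be symmetric with unit diagonal")
            eig = np.linalg.eigvalsh(r)
            if eig.min() < -1e-10:
                nearest = _nearest_psd(r)
                raise ValueError(
                    "change correlation matrix is not positive semi-definite "
                    f"(min eigenvalue {eig.min():.3g}); nearest PSD correlation "
                    f"has off-diagonal range [{nearest.min():.3f}, "
                    f"{nearest[~np.eye(k, dtype=bool)].max():.3f}]"
                )
            self.change_corr = r

    @classmethod
    def from_config(cls, cfg: dict, seed: int | None = None) -> "CohortSpec":
        """Build a spec from a (YAML-derived) configuration mapping."""
        outcomes = {
            name: OutcomeSpec(**params) for name, params in cfg["outcomes"].items()
        }
        corr_cfg = cfg.get("change_correlation")
        corr = None
        if corr_cfg is not None:
            k = len(outcomes)
            if corr_cfg.get("type") == "exchangeable":
                r = float(corr_cfg["r"])
                corr = np.full((k, k), r)
                np.fill_diagonal(corr, 1.0)
            elif corr_cfg.get("type") == "matrix":
                corr = np.asarray(corr_cfg["values"], dtype=float)
            else:
                raise ValueError(f"unknown correlation type {corr_cfg.get('type')!r}")
        return cls(
            outcomes=outcomes,
            n_well_trained=int(cfg.get("n_well_trained", 36)),
            n_less_trained=int(cfg.get("n_less_trained", 33)),
            age_mean=float(cfg.get("age_mean", 60.6)),
            age_sd=float(cfg.get("age_sd", 11.1)),
            age_min=float(cfg.get("age_min", 40.0)),
            age_max=float(cfg.get("age_max", 85.0)),
            age_slope_pct_per_decade=float(cfg.get("age_slope_pct_per_decade", 0.0)),
            cv_rms_pct=float(cfg.get("cv_rms_pct", 1.0)),
            change_sd_pct=(
                None
                if cfg.get("change_sd_pct") is None
                else float(cfg["change_sd_pct"])
            ),
            change_corr=corr,
            followup_missing_rate=float(cfg.get("followup_missing_rate", 0.0)),
            dropout_rate=float(cfg.get("dropout_rate", 0.0)),
            seed=int(seed if seed is not None else cfg.get("seed", 0)),
        )

    @classmethod
    def reference(cls, seed: int = 0) -> "CohortSpec":
        """The shipped 19-outcome configuration at published magnitudes."""
        text = (
            importlib.resources.files("pqctlong.data")
            .joinpath("reference_cohort.yaml")
            .read_text()
        )
        return cls.from_config(yaml.safe_load(text), seed=seed)


def _nearest_psd(r: np.ndarray) -> np.ndarray:
    lam, q = np.linalg.eigh((r + r.T) / 2.0)
    lam = np.clip(lam, 0.0, None)
    out = q @ np.diag(lam) @ q.T
    d = np.sqrt(np.clip(np.diag(out), 1e-12, None))
    return out / np.outer(d, d)


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a cohort; returns a long-format measurement table.

    Columns: ``subject``, ``group``, ``age0``, ``occasion`` (0/10 years),
    ``outcome``, ``value``; missing values appear as NaN records so the
    table keeps one row per subject x occasion x outcome.  Deterministic
    given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    names = list(spec.outcomes)
    k = len(names)
    mu = np.array([spec.outcomes[n].baseline_mean for n in names])
    sd = np.array([spec.outcomes[n].baseline_sd for n in names])
    delta_lt = np.array([spec.outcomes[n].change_lt for n in names])
    inter = np.array([spec.outcomes[n].group_time_effect for n in names])
    sigma_e = spec.cv_rms_pct / 100.0 * np.abs(mu)
    sigma_b = np.sqrt(np.clip(sd**2 - sigma_e**2, 0.0, None))
    if spec.change_sd_pct is None:
        sigma_d = np.sqrt(2.0) * sigma_e
    else:
        sigma_d = spec.change_sd_pct / 100.0 * np.abs(mu)
    corr = spec.change_corr if spec.change_corr is not None else np.eye(k)
    cov_d = np.outer(sigma_d, sigma_d) * corr
    age_slope = spec.age_slope_pct_per_decade / 100.0 / 10.0 * mu  # units/yr

    n = spec.n_well_trained + spec.n_less_trained
    group = np.array([GROUP_WELL] * spec.n_well_trained + [GROUP_LESS] * spec.n_less_trained)
    is_wt = (group == GROUP_WELL).astype(float)
    if spec.age_sd > 0:
        lo = (spec.age_min - spec.age_mean) / spec.age_sd
        hi = (spec.age_max - spec.age_mean) / spec.age_sd
        ages = stats.truncnorm.rvs(
            lo, hi, loc=spec.age_mean, scale=spec.age_sd, size=n, random_state=rng
        )
    else:
        ages = np.full(n, spec.age_mean)
    age_c = ages - ages.mean()

    b = rng.normal(0.0, 1.0, size=(n, k)) * sigma_b
    e0 = rng.normal(0.0, 1.0, size=(n, k)) * sigma_e
    w = (
        rng.multivariate_normal(np.zeros(k), cov_d, size=n, method="eigh")
        if cov_d.any()
        else np.zeros((n, k))
    )
    base = mu + np.outer(age_c, age_slope) + b + e0
    change = delta_lt + np.outer(is_wt, inter) + w
    follow = base + change

    dropout = rng.random(n) < spec.dropout_rate
    miss = rng.random((n, k)) < spec.followup_missing_rate
    follow = follow.copy()
    follow[dropout, :] = np.nan
    follow[miss] = np.nan

    subj = np.array([f"S{i + 1:03d}" for i in range(n)])
    frames = []
    for occ, vals in ((0, base), (10, follow)):
        frames.append(
            pd.DataFrame(
                {
                    "subject": np.repeat(subj, k),
                    "group": np.repeat(group, k),
                    "age0": np.repeat(np.round(ages, 1), k),
                    "occasion": occ,
                    "outcome": np.tile(names, n),
                    "value": vals.ravel(),
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    return table.sort_values(
        ["subject", "occasion", "outcome"], kind="mergesort", ignore_index=True
    )
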