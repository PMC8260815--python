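"""Effective number of tests (Cheverud/Nyholt) and Sidak-style adjustment.

With K correlated outcomes the number of effectively independent tests is
estimated from the eigenvalue dispersion of their correlation matrix:

    M_eff = 1 + (K - 1) * (1 - Var(lambda) / K),

where Var(lambda) is the sample variance (divisor K - 1) of the K
eigenvalues.  An identity correlation gives M_eff = K, perfect correlation
gives M_eff = 1.  Because the tests of interest concern 10-year changes,
the correlation matrix is computed from per-subject change scores
(follow-up minus baseline).  The significance level is then Sidak-corrected
with M_eff in place of the test count: alpha_adj = 1 - (1 - alpha)^(1/M_eff),
and raw p-values map to p_adj = 1 - (1 - p)^M_eff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MeffResult",
    "change_scores",
    "change_correlation",
    "effective_number_of_tests",
    "sidak_adjust",
    "sidak_alpha",
    "meff_from_table",
]


@dataclass
class MeffResult:
    """Correlation spectrum, effective test count and adjusted levels."""

    n_outcomes: int
    correlation: pd.DataFrame
    eigenvalues: np.ndarray
    eigenvalue_variance: float
    m_eff: float
    alpha: float
    adjusted_alpha: float
    adjusted_p: pd.Series | None = None
    excluded_outcomes: list[str] = field(default_factory=list)


def change_scores(table: pd.DataFrame) -> pd.DataFrame:
    """Per-subject change scores (follow-up minus baseline) per outcome."""
    wide = table.pivot_table(
        index=["subject", "outcome"], columns="occasion", values="value", aggfunc="first"
    )
    occasions = sorted(wide.columns)
    if len(occasions) < 2:
        raise ValueError("change scores need two occasions")
    first, last = occasions[0], occasions[-1]
    delta = (wide[last] - wide[first]).unstack("outcome")
    return delta


def change_correlation(
    table: pd.DataFrame, min_pairs: int = 3
) -> tuple[pd.DataFrame, list[str]]:
    """Pearson correlation matrix of change scores, pairwise complete.

    Outcomes with fewer than ``min_pairs`` complete subject pairs or with
    zero change variance are excluded (with a warning) and listed in the
    second return value.
    """
    delta = change_scores(table)
    excluded = []
    for col in list(delta.columns):
        vals = delta[col].dropna()
        if len(vals) < min_pairs or vals.nunique() <= 1:
            excluded.append(col)
    if excluded:
        warnings.warn(
            f"excluding outcomes with <{min_pairs} complete pairs or zero "
            f"change variance: {excluded}",
            stacklevel=2,
        )
        delta = delta.drop(columns=excluded)
    if delta.shape[1] < 2:
        raise ValueError("need at least two usable outcomes")
    corr = delta.corr(method="pearson", min_periods=min_pairs)
    np.fill_diagonal(corr.values, 1.0)
    return corr, excluded


def effective_number_of_tests(corr) -> float:
    """Cheverud/Nyholt effective number of tests from a correlation matrix.

    Pairwise-complete correlation matrices can be slightly non-PSD; any
    negative eigenvalues are clipped at zero (with a warning) before the
    eigenvalue variance is taken.
    """
    mat = np.asarray(corr, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(mat), 1.0, atol=1e-10):
        raise ValueError("correlation matrix must have a unit diagonal")
    k = mat.shape[0]
    if k == 1:
        return 1.0
    lam = np.linalg.eigvalsh(mat)
    if lam.min() < -1e-10:
        warnings.warn(
            "correlation matrix is not positive semi-definite; clipping "
            "negative eigenvalues at zero",
            stacklevel=2,
        )
    lam = np.clip(lam, 0.0, None)
    var_lam = float(np.var(lam, ddof=1))
    return float(1.0 + (k - 1) * (1.0 - var_lam / k))


def sidak_alpha(alpha: float, m_eff: float) -> float:
    """M_eff-Sidak-corrected significance level 1 - (1 - alpha)^(1/M_eff)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if m_eff < 1.0:
        raise ValueError("M_eff must be >= 1")
    return float(-np.expm1(np.log1p(-alpha) / m_eff))


def sidak_adjust(alpha: float, m_eff: float, p_values=None):
    """Adjusted alpha and (optionally) Sidak-adjusted p-values.

    Returns ``adjusted_alpha`` alone, or ``(adjusted_alpha, adjusted_p)``
    when ``p_values`` is given; p_adj = min(1, 1 - (1 - p)^M_eff).
    """
    adj_alpha = sidak_alpha(alpha, m_eff)
    if p_values is None:
        return adj_alpha
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0.0) | (p > 1.0)):
        raise ValueError("p-values must lie in [0, 1]")
    adj_p = np.minimum(1.0, -np.expm1(m_eff * np.log1p(-p)))
    adj_p = np.maximum(adj_p, p)  # guard round-off; adjustment never shrinks p
    if isinstance(p_values, pd.Series):
        adj_p = pd.Series(adj_p, index=p_values.index)
    return adj_alpha, adj_p


def meff_from_table(
    table: pd.DataFrame,
    alpha: float = 0.05,
    p_values: pd.Series | None = None,
) -> MeffResult:
    """Full multiplicity correction from a long-format measurement table."""
    corr, excluded = change_correlation(table)
    lam = np.clip(np.linalg.eigvalsh(corr.to_numpy()), 0.0, None)
    m_eff = effective_number_of_tests(corr)
    if p_values is not None:
        adj_alpha, adj_p = sidak_adjust(alpha, m_eff, p_values)
    else:
        adj_alpha, adj_p = sidak_adjust(alpha, m_eff), None
    return MeffResult(
        n_outcomes=corr.shape[0],
        correlation=corr,
        eigenvalues=lam,
        eigenvalue_variance=float(np.var(lam, ddof=1)),
        m_eff=m_eff,
        alpha=alpha,
        adjusted_alpha=adj_alpha,
        adjusted_p=adj_p,
        excluded_outcomes=excluded,
    )
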