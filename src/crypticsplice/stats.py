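"""Shared statistical primitives: two-proportion tests, multiple-testing
helpers and significance tiers used across the enrichment analyses."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class ProportionTestResult:
    k1: int
    n1: int
    k2: int
    n2: int
    p_value: float
    statistic: float
    method: str          # "chi2_cc" or "fisher"
    chi2_p: float        # the chi-square p regardless of which method was used


def two_proportion_test(
    k1: int, n1: int, k2: int, n2: int, exact_fallback: bool = True
) -> ProportionTestResult:
    """Two-proportion chi-square test with Yates continuity correction.

    Matches R's ``prop.test`` on 2x2 tables.  When any observed cell is
    below 5 and ``exact_fallback`` is on, Fisher's exact test is reported
    instead (flagged in ``method``); the chi-square p-value is always kept
    alongside for reference.
    """
    for v, n in ((k1, n1), (k2, n2)):
        if not 0 <= v <= n:
            raise ValueError("counts must satisfy 0 <= k <= n")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    total = table.sum()
    if total == 0 or table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        return ProportionTestResult(k1, n1, k2, n2, 1.0, 0.0, "degenerate", 1.0)
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    corrected = np.maximum(np.abs(table - expected) - 0.5, 0.0)
    chi2 = float((corrected**2 / expected).sum())
    chi2_p = float(sps.chi2.sf(chi2, df=1))
    if exact_fallback and table.min() < 5:
        _, fisher_p = sps.fisher_exact(table.astype(int))
        return ProportionTestResult(k1, n1, k2, n2, float(fisher_p), chi2, "fisher", chi2_p)
    return ProportionTestResult(k1, n1, k2, n2, chi2_p, chi2, "chi2_cc", chi2_p)


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment; never decreases a p-value."""
    p = np.asarray(p_values, dtype=float)
    m = m if m is not None else p.size
    return np.minimum(p * max(m, 1), 1.0)


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH step-up FDR adjustment (monotone, adjusted >= raw holds after
    the cumulative-minimum step for the largest p)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def significance_tier(adjusted_p: float) -> str:
    """Star labels at the conventional tiers 0.05, 1e-3, 1e-16."""
    if adjusted_p < 1e-16:
        return "***"
    if adjusted_p < 1e-3:
        return "**"
    if adjusted_p < 0.05:
        return "*"
    return ""


def hypergeometric_upper_tail(overlap: int, background: int, set_a: int, set_b: int) -> float:
    """P(X >= overlap) for X ~ Hypergeom(background, set_a, set_b)."""
    return float(sps.hypergeom.sf(overlap - 1, background, set_a, set_b))


def binomial_ci(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Clopper–Pearson interval for a binomial proportion."""
    if n == 0:
        return (0.0, 1.0)
    alpha = 1 - conf
    lo = sps.beta.ppf(alpha / 2, k, n - k + 1) if k > 0 else 0.0
    hi = sps.beta.ppf(1 - alpha / 2, k + 1, n - k) if k < n else 1.0
    return float(lo), float(hi)
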