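"""Rank correlations and quantile utilities shared by the pipeline stages.

Kendall's tau is the tie-corrected tau-b; Spearman's rho uses midranks.  Both
delegate to scipy.stats (the field's standard implementations) and are
cross-checked in the test suite against explicit O(n^2)/midrank oracles.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import StatisticsError


@dataclass(frozen=True)
class RankCorrResult:
    """One rank-based correlation test.

    statistic is tau-b or rho in [-1, 1]; p_value is two-sided.
    """

    method: str  # "kendall" | "spearman"
    statistic: float
    p_value: float
    n: int

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def _validated(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StatisticsError("x and y must be 1-d arrays of equal length")
    if len(x) < 3:
        raise StatisticsError(f"need at least 3 pairs, got {len(x)}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise StatisticsError("non-finite values in correlation input")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise StatisticsError("statistic undefined: one variable is constant")
    return x, y


def kendall_tau(x, y) -> RankCorrResult:
    """Kendall's tau-b with tie correction, two-sided p-value.

    scipy uses the exact null distribution for small untied samples and the
    normal approximation otherwise.
    """
    x, y = _validated(x, y)
    res = stats.kendalltau(x, y)
    return RankCorrResult("kendall", float(res.statistic), float(res.pvalue), len(x))


def spearman_rho(x, y) -> RankCorrResult:
    """Spearman's rho on midranks, two-sided p-value."""
    x, y = _validated(x, y)
    res = stats.spearmanr(x, y)
    return RankCorrResult("spearman", float(res.statistic), float(res.pvalue), len(x))


def age_size_correlation(nupts) -> tuple[RankCorrResult, RankCorrResult]:
    """Correlate K (relative age) against size across a NUPT catalog."""
    ages = [r.K for r in nupts]
    sizes = [r.size for r in nupts]
    return kendall_tau(ages, sizes), spearman_rho(ages, sizes)


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH step-up adjusted p-values (optional; raw p at alpha=0.05 is the
    default decision rule throughout the package)."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def iqr_threshold(values) -> tuple[float, float, float, float]:
    """(Q1, Q3, IQR, Q3 + 1.5*IQR) with linear interpolation between order
    statistics — the outlier rule used for hotspot calling."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise StatisticsError("cannot take quartiles of an empty sample")
    q1, q3 = np.percentile(v, [25.0, 75.0])  # linear interpolation default
    iqr = q3 - q1
    return float(q1), float(q3), float(iqr), float(q3 + 1.5 * iqr)
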