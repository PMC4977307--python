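"""Cohort-level statistical comparisons.

Nonparametric Wilcoxon rank-sum (Mann-Whitney U) tests between
cancerous and contralateral unaffected breasts, and Pearson linear
correlation between paired per-patient metrics (e.g. CC vs MLO yellow
percentages).  Two-sided throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["ComparisonResult", "wilcoxon_rank_sum", "pearson_correlation"]


@dataclass(frozen=True)
class ComparisonResult:
    statistic: float
    p_value: float
    n1: int
    n2: int
    method: str                     # 'exact' | 'normal-approx-tie-corrected' | ...
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "statistic": float(self.statistic),
            "p_value": float(self.p_value),
            "n1": self.n1,
            "n2": self.n2,
            "method": self.method,
            "degenerate": self.degenerate,
        }


def wilcoxon_rank_sum(x, y, alternative: str = "two-sided") -> ComparisonResult:
    """Wilcoxon rank-sum test.

    Exact enumeration when n1 * n2 <= 400 and there are no ties,
    otherwise the normal approximation with tie and continuity
    correction.  Two samples with all values identical give p = 1 with
    the degenerate flag set.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError("need at least 3 observations per sample")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return ComparisonResult(
            statistic=float(x.size * y.size / 2), p_value=1.0,
            n1=x.size, n2=y.size, method="degenerate", degenerate=True,
        )
    has_ties = np.unique(pooled).size < pooled.size
    if x.size * y.size <= 400 and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative=alternative, method="exact")
        method = "exact"
    else:
        res = stats.mannwhitneyu(
            x, y, alternative=alternative, method="asymptotic", use_continuity=True
        )
        method = "normal-approx-tie-corrected"
    return ComparisonResult(
        statistic=float(res.statistic), p_value=float(res.pvalue),
        n1=x.size, n2=y.size, method=method,
    )


def pearson_correlation(x, y) -> ComparisonResult:
    """Pearson r with the two-sided p-value from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("samples must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: Pearson correlation undefined")
    r, p = stats.pearsonr(x, y)
    return ComparisonResult(
        statistic=float(r), p_value=float(p), n1=x.size, n2=y.size, method="pearson-t"
    )
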