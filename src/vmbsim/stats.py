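"""Frequency and rank statistics used across analyses.

Thin, explicit wrappers: Pearson chi-square on a 2x2 table without
continuity correction (arms of ~2,000 virtual patients make the correction
immaterial), the two-sided Wilcoxon rank-sum test, and Benjamini-Hochberg
step-up adjustment.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["chi_square_frequency_test", "rank_sum_test", "bh_adjust"]


def chi_square_frequency_test(
    a_success: int, a_n: int, b_success: int, b_n: int
) -> tuple[float, float]:
    """Pearson chi-square comparing two response frequencies.

    Returns ``(statistic, p_value)``.  Raises ``ValueError`` for counts
    exceeding their totals or for a degenerate (zero-margin) table.
    """
    if not (0 <= a_success <= a_n and 0 <= b_success <= b_n):
        raise ValueError("successes must lie in [0, n]")
    table = np.array(
        [[a_success, a_n - a_success], [b_success, b_n - b_success]], dtype=float
    )
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("degenerate 2x2 table: a margin is zero")
    res = sps.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value."""
    return float(sps.ranksums(np.asarray(x, float), np.asarray(y, float)).pvalue)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values, order-preserving."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvals must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
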