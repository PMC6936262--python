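"""Thin wrappers around scipy/statsmodels used by every screen."""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["bh_adjust", "mwu_with_direction"]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (NaN-tolerant)."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def mwu_with_direction(x, y, alternative: str = "two-sided"):
    """Mann-Whitney U of x vs y plus the sign of the median difference.

    Returns (U, p, direction) with direction in {+1, -1, 0} by
    median(x) - median(y).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    res = stats.mannwhitneyu(x, y, alternative=alternative)
    diff = np.median(x) - np.median(y)
    direction = 0 if diff == 0 else (1 if diff > 0 else -1)
    return float(res.statistic), float(res.pvalue), direction
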