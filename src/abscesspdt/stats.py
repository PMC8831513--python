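"""Paired nonparametric tests used to summarize sweep tables.

The Friedman test compares threshold power (or optimal Intralipid
concentration) across simulation conditions with geometries as blocks; the
Wilcoxon signed-rank test compares paired eligibility outcomes between
planning strategies.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats as sps

__all__ = ["friedman_test", "wilcoxon_signed_rank"]


def friedman_test(matrix) -> tuple[float, float]:
    """Friedman rank test on a blocks x treatments matrix.

    Within-block ranks (average ranks for ties), tie-corrected chi-square
    statistic, p-value from the asymptotic chi-square distribution with
    k - 1 degrees of freedom.  Implemented directly (rather than via scipy)
    so the two-treatment case is supported; agrees with
    ``scipy.stats.friedmanchisquare`` for k >= 3.

    Fully tied data (no rank variation in any block) is degenerate: a
    warning is emitted and (0.0, 1.0) returned.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need at least 2 blocks and 2 treatments")
    n, k = m.shape
    ranks = np.apply_along_axis(sps.rankdata, 1, m)
    rj = ranks.sum(axis=0)
    q = 12.0 / (n * k * (k + 1)) * np.sum(rj**2) - 3.0 * n * (k + 1)

    # tie correction: 1 - sum(t^3 - t) / (n k (k^2 - 1))
    ties = 0.0
    for row in m:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts**3 - counts))
    c = 1.0 - ties / (n * k * (k**2 - 1))
    if c <= 0:
        warnings.warn("no rank variation in any block; Friedman test degenerate")
        return 0.0, 1.0
    stat = q / c
    p = float(sps.chi2.sf(stat, k - 1))
    return float(stat), p


def wilcoxon_signed_rank(
    x, y=None, alternative: str = "two-sided", method: str = "auto"
) -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired samples (or precomputed differences).

    Thin wrapper over ``scipy.stats.wilcoxon``; ``method`` selects the exact
    or normal-approximation p-value ('auto' picks exact for small n without
    ties).  All-zero differences are degenerate: a warning is emitted and
    (0.0, 1.0) returned.
    """
    x = np.asarray(x, dtype=float)
    d = x if y is None else x - np.asarray(y, dtype=float)
    if np.all(d == 0):
        warnings.warn("all paired differences are zero; Wilcoxon test degenerate")
        return 0.0, 1.0
    res = sps.wilcoxon(d, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)
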