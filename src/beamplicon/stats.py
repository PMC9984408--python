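"""Paired Wilcoxon signed-rank test with an exact small-sample null.

The exact two-sided p-value is computed from the full null distribution of
the signed-rank sum (every sign pattern equally likely), via a
generating-function convolution that also handles midranks from ties.  For
more than ``EXACT_MAX_N`` nonzero differences a normal approximation with
tie correction and continuity correction is used.  Zero differences are
dropped; if every difference is zero the samples are indistinguishable and
p = 1.0 by convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

EXACT_MAX_N = 25


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W+ : sum of ranks of positive differences
    pvalue: float
    n: int  # number of nonzero differences used
    method: str  # 'exact' | 'normal' | 'degenerate'


def _exact_null_cdf(ranks: np.ndarray, w_plus: float) -> tuple[float, float]:
    """P(W+ <= w) and P(W+ >= w) under the exact null for given ranks.

    Ranks may be midranks (multiples of 0.5); internally doubled to stay on
    an integer lattice.
    """
    doubled = np.round(ranks * 2).astype(int)
    total = int(doubled.sum())
    # distribution of sum over subsets, as counts indexed by doubled rank sum
    dist = np.zeros(total + 1, dtype=float)
    dist[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    dist /= dist.sum()
    w2 = int(round(w_plus * 2))
    p_le = float(dist[: w2 + 1].sum())
    p_ge = float(dist[w2:].sum())
    return p_le, p_ge


def wilcoxon_signed_rank(x, y=None, method: str = "auto") -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired samples (or differences).

    Parameters
    ----------
    x, y
        Paired observations; if ``y`` is None, ``x`` is taken as differences.
    method
        'exact', 'normal', or 'auto' (exact for <= 25 nonzero differences).
    """
    d = np.asarray(x, dtype=float)
    if y is not None:
        d = d - np.asarray(y, dtype=float)
    d = d[~np.isnan(d)]
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        return WilcoxonResult(statistic=0.0, pvalue=1.0, n=0, method="degenerate")

    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if method == "auto":
        method = "exact" if n <= EXACT_MAX_N else "normal"

    if method == "exact":
        p_le, p_ge = _exact_null_cdf(ranks, w_plus)
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return WilcoxonResult(statistic=w_plus, pvalue=p, n=n, method="exact")

    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts) / 48.0).sum())
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        return WilcoxonResult(statistic=w_plus, pvalue=1.0, n=n,
                              method="degenerate")
    # continuity correction shrinks |W - mean| by 0.5
    z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / np.sqrt(var)
    p = min(1.0, 2.0 * float(norm.sf(abs(z))))
    return WilcoxonResult(statistic=w_plus, pvalue=p, n=n, method="normal")
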