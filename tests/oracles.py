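"""Independent brute-force oracles used by the tests.

These are written as straight-line reimplementations, kept deliberately
separate from the package's code paths: a plain Gotoh dynamic program for
semi-global affine alignment scores, a full-enumeration Wilcoxon signed-rank
null, and a loop-by-loop RNA variant filter.
"""

from itertools import product

import numpy as np

NEG = float("-inf")


def semiglobal_score(read: str, ref: str, match=2, mismatch=-1,
                     gap_open=-6, gap_extend=-1) -> float:
    """Best semi-global score: read global, reference end overhangs free;
    gap of length L costs gap_open + L*gap_extend."""
    n, m = len(read), len(ref)
    go = gap_open + gap_extend  # first gap base
    ge = gap_extend
    M = [[NEG] * (m + 1) for _ in range(n + 1)]  # read i aligned to ref j
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in ref (insertion)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # internal gap in read
    H = [[NEG] * (m + 1) for _ in range(n + 1)]
    for j in range(m + 1):
        H[0][j] = 0.0  # free leading reference skip
    for i in range(1, n + 1):
        X[i][0] = go + (i - 1) * ge
        H[i][0] = X[i][0]
        for j in range(1, m + 1):
            s = match if read[i - 1] == ref[j - 1] else mismatch
            M[i][j] = H[i - 1][j - 1] + s
            X[i][j] = max(M[i - 1][j] + go, X[i - 1][j] + ge,
                          Y[i - 1][j] + go)
            Y[i][j] = max(M[i][j - 1] + go, Y[i][j - 1] + ge,
                          X[i][j - 1] + go)
            H[i][j] = max(M[i][j], X[i][j], Y[i][j])
    return max(max(M[n][j], X[n][j]) for j in range(m + 1))


def wilcoxon_exact_enumeration(diffs) -> float:
    """Two-sided signed-rank p by enumerating all 2^n sign assignments of the
    absolute differences (midranks for ties; zeros dropped; all-zero -> 1)."""
    from scipy.stats import rankdata

    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 1.0
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    w_values = [sum(r for r, s in zip(ranks, signs) if s)
                for signs in product([False, True], repeat=n)]
    w_values = np.array(w_values)
    p_le = np.mean(w_values <= w_obs + 1e-9)
    p_ge = np.mean(w_values >= w_obs - 1e-9)
    return min(1.0, 2.0 * min(p_le, p_ge))


def rna_filter_reference(oe, control, gfp, coverage_percentile=90.0,
                         consensus=0.99, min_reads_gfp=10):
    """Loop-by-loop reimplementation of the RNA off-target filter chain.

    Returns the list of retained overexpression variants, in input order.
    """
    if not oe:
        return []
    depths = sorted(v.depth for v in oe)
    threshold = float(np.percentile(depths, coverage_percentile))
    retained = []
    for v in oe:
        ctrl = None
        for c in control:
            if c.contig == v.contig and c.position == v.position:
                ctrl = c
                break
        if ctrl is None or ctrl.depth <= threshold:
            continue
        ref_frac = 1.0 - (ctrl.alt_depth / ctrl.depth if ctrl.depth else 1.0)
        if ref_frac < consensus:
            continue
        in_background = False
        for g in gfp:
            if (g.contig, g.position, g.ref, g.alt) == (v.contig, v.position,
                                                        v.ref, v.alt):
                if g.depth >= min_reads_gfp and g.alt_depth > 0:
                    in_background = True
                break
        if not in_background:
            retained.append(v)
    return retained
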