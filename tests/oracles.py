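"""Independent reference implementations used only as test oracles.

These deliberately share no code with ``castworks.align``: a plain-loop
affine Smith-Waterman for tiny instances, and a row-vectorised variant
(prefix-scan for within-row gaps) for medium instances, cross-checked
against each other.
"""

from __future__ import annotations

import numpy as np

from castworks.dna import encode, revcomp

NEG = -(10 ** 7)


def sw_affine_python(q: str, t: str, match=2, mismatch=-3,
                     gap_open=-5, gap_extend=-2) -> int:
    """Best local affine-gap alignment score, O(mn) plain loops."""
    qc, tc = encode(q), encode(t)
    m, n = len(qc), len(tc)
    H = np.zeros((m + 1, n + 1), dtype=int)
    E = np.full((m + 1, n + 1), NEG, dtype=int)
    F = np.full((m + 1, n + 1), NEG, dtype=int)
    best = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i, j] = max(H[i, j - 1] + gap_open, E[i, j - 1] + gap_extend)
            F[i, j] = max(H[i - 1, j] + gap_open, F[i - 1, j] + gap_extend)
            s = match if (qc[i - 1] == tc[j - 1] and qc[i - 1] < 4) else mismatch
            H[i, j] = max(0, H[i - 1, j - 1] + s, E[i, j], F[i, j])
            best = max(best, H[i, j])
    return int(best)


def sw_affine_rowscan(q: str, t: str, match=2, mismatch=-3,
                      gap_open=-5, gap_extend=-2) -> int:
    """Best local affine score, vectorised per row.

    Within-row gap opens are resolved with a running prefix maximum of
    gap-open candidates (valid because gap_open <= gap_extend, so chained
    opens never beat one long gap).
    """
    qc, tc = encode(q), encode(t)
    n = len(tc)
    h_prev = np.zeros(n + 1, dtype=np.int64)
    f_prev = np.full(n + 1, NEG, dtype=np.int64)
    js = np.arange(n + 1)
    best = 0
    for c in qc:
        s = np.where((tc == c) & (c < 4), match, mismatch)
        f = np.maximum(h_prev + gap_open, f_prev + gap_extend)
        g = np.zeros(n + 1, dtype=np.int64)
        g[1:] = np.maximum.reduce([np.zeros(n, dtype=np.int64),
                                   h_prev[:-1] + s, f[1:]])
        a = g + gap_open - gap_extend * js
        p = np.maximum.accumulate(a)
        h = g.copy()
        h[1:] = np.maximum(g[1:], p[:-1] + gap_extend * (js[1:] - 1))
        best = max(best, int(h.max()))
        h_prev, f_prev = h, f
    return best


def sw_best_both_strands(q: str, t: str, **scores) -> int:
    """Oracle score over both query strands."""
    return max(sw_affine_rowscan(q, t, **scores),
               sw_affine_rowscan(revcomp(q), t, **scores))


def binomial_ci(k: int, n: int, alpha: float = 0.05):
    """Exact (Clopper-Pearson) binomial confidence interval for k/n."""
    from scipy import stats

    lo = 0.0 if k == 0 else stats.beta.ppf(alpha / 2, k, n - k + 1)
    hi = 1.0 if k == n else stats.beta.ppf(1 - alpha / 2, k + 1, n - k)
    return float(lo), float(hi)
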