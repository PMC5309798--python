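"""Independent brute-force and closed-form oracles used by the tests.

Each oracle recomputes a quantity by the most transparent route available
(per-base arrays, exhaustive enumeration, direct formula evaluation) and is
deliberately kept independent of the implementation paths it checks.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats as sps


def per_base_coverage(intervals, lo, hi):
    """Depth per base over [lo, hi) by direct counting."""
    depth = np.zeros(hi - lo, dtype=int)
    for start, end in intervals:
        depth[max(start, lo) - lo:min(end, hi) - lo] += 1
    return depth


def per_base_segments(intervals, lo, hi):
    """(start, end, depth) runs of the per-base depth array, zero runs dropped."""
    depth = per_base_coverage(intervals, lo, hi)
    segs = []
    i = 0
    while i < len(depth):
        j = i
        while j < len(depth) and depth[j] == depth[i]:
            j += 1
        if depth[i] > 0:
            segs.append((lo + i, lo + j, int(depth[i])))
        i = j
    return segs


def per_base_peaks(intervals, lo, hi):
    """Bases whose depth exceeds both nearest differing depths (0 outside),
    grouped into maximal runs — the brute-force peak-region definition."""
    depth = per_base_coverage(intervals, lo, hi)
    padded = np.concatenate([[0], depth, [0]])
    n = len(padded)
    peaks = []
    i = 1
    while i < n - 1:
        j = i
        while j < n - 1 and padded[j] == padded[i]:
            j += 1
        left = padded[i - 1]
        right = padded[j] if j < n else 0
        if padded[i] > left and padded[i] > right and padded[i] > 0:
            peaks.append((lo + i - 1, lo + j - 1, int(padded[i])))
        i = j
    return peaks


def per_base_overlap(a, b, lo, hi):
    """|union(a) ∩ union(b)| by per-base set intersection."""
    in_a = np.zeros(hi - lo, dtype=bool)
    in_b = np.zeros(hi - lo, dtype=bool)
    for start, end in a:
        in_a[start - lo:end - lo] = True
    for start, end in b:
        in_b[start - lo:end - lo] = True
    return int((in_a & in_b).sum())


# 16-row truth table for dosage-class assignment, written out explicitly:
# key = (in_benign_gain, in_benign_loss, in_path_gain_peak, in_path_loss_peak)
TRUTH_TABLE = {
    (False, False, False, False): "unclassified",
    (True, False, False, False): "B",
    (False, True, False, False): "B",
    (True, True, False, False): "B",
    (False, False, True, False): "P",
    (False, False, False, True): "P",
    (False, False, True, True): "P",
    (True, False, True, False): "X",       # benign gain + path gain
    (False, True, False, True): "X",       # benign loss + path loss
    (True, True, True, False): "X",
    (True, True, False, True): "X",
    (True, False, True, True): "X",
    (False, True, True, True): "X",
    (True, True, True, True): "X",
    (False, True, True, False): "BL_PG",   # exactly benign loss + path gain
    (True, False, False, True): "BG_PL",   # exactly benign gain + path loss
}


def chi2_direct(obs):
    """Pearson chi-square and adjusted residuals by direct formula."""
    obs = np.asarray(obs, dtype=float)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    total = obs.sum()
    exp = row * col / total
    chi2 = ((obs - exp) ** 2 / exp).sum()
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = sps.distributions.chi2.sf(chi2, df)
    adj = (obs - exp) / np.sqrt(exp * (1 - row / total) * (1 - col / total))
    return chi2, df, p, adj


def mwu_direct(x, y):
    """Exact U by pairwise comparison; tie-corrected normal p with
    continuity correction."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = len(x), len(y)
    u1 = sum((xi > yj) + 0.5 * (xi == yj) for xi in x for yj in y)
    mu = n1 * n2 / 2
    n = n1 + n2
    _, t = np.unique(np.concatenate([x, y]), return_counts=True)
    tie = (t ** 3 - t).sum()
    sd = math.sqrt(n1 * n2 / 12 * ((n + 1) - tie / (n * (n - 1))))
    z = (abs(u1 - mu) - 0.5) / sd
    return u1, min(1.0, 2 * sps.norm.sf(z))


def fligner_direct(*groups):
    """Normal-scores scale statistic by direct evaluation."""
    absdev = [np.abs(np.asarray(g, float) - np.median(g)) for g in groups]
    allv = np.concatenate(absdev)
    ranks = sps.rankdata(allv)
    N = len(allv)
    a = sps.norm.ppf(0.5 + ranks / (2 * (N + 1)))
    abar, v = a.mean(), a.var(ddof=1)
    stat = 0.0
    i = 0
    for g in absdev:
        ai = a[i:i + len(g)]
        i += len(g)
        stat += len(g) * (ai.mean() - abar) ** 2
    stat /= v
    return stat, sps.distributions.chi2.sf(stat, len(groups) - 1)


def hypergeom_enumerate(N, K, n, k):
    """Upper-tail P(X >= k) by direct summation of the hypergeometric pmf."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, i) * math.comb(N - K, n - i)
        for i in range(k, min(n, K) + 1)
    ) / total
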