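"""Independent brute-force / closed-form oracles used by the test suite.

Everything here is deliberately naive (enumeration, direct formulas,
sort-based scans) and shares no code with the package implementation.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.stats import chi2, rankdata


# --- Hurst: classic rescaled-range (R/S) analysis ---------------------------

def rescaled_range_hurst(x: np.ndarray) -> float:
    """R/S estimate: slope of log(R/S) vs log(window) over log-spaced sizes."""
    x = np.asarray(x, dtype=float)
    n = x.size
    sizes = np.unique(np.round(np.geomspace(16, n // 4, 12)).astype(int))
    log_s, log_rs = [], []
    for s in sizes:
        m = n // s
        rs_vals = []
        for i in range(m):
            seg = x[i * s:(i + 1) * s]
            dev = np.cumsum(seg - seg.mean())
            r = dev.max() - dev.min()
            sd = seg.std()
            if sd > 0:
                rs_vals.append(r / sd)
        if rs_vals:
            log_s.append(np.log(s))
            log_rs.append(np.log(np.mean(rs_vals)))
    return float(np.polyfit(log_s, log_rs, 1)[0])


# --- Wilcoxon rank-sum: exhaustive enumeration ------------------------------

def exact_rank_sum_p(x, y) -> float:
    """Two-sided exact p by enumerating all C(n+m, n) group assignments.

    Assumes no ties.  The two-sided p is twice the smaller tail probability
    of the U statistic (including the observed value), capped at 1.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    nx = x.size
    u_obs = ranks[:nx].sum() - nx * (nx + 1) / 2
    us = []
    for idx in combinations(range(pooled.size), nx):
        r = ranks[list(idx)].sum() - nx * (nx + 1) / 2
        us.append(r)
    us = np.asarray(us)
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return min(1.0, 2.0 * min(p_le, p_ge))


# --- Wilcoxon signed-rank: exhaustive sign enumeration ----------------------

def exact_signed_rank_p(x, y) -> float:
    """Two-sided exact p by enumerating all 2^n sign assignments.

    Zero differences are dropped (Wilcoxon's original rule); assumes no
    ties among the non-zero absolute differences.
    """
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in range(2 ** n):
        mask = np.array([(signs >> i) & 1 for i in range(n)], dtype=bool)
        ws.append(ranks[mask].sum())
    ws = np.asarray(ws)
    p_le = np.mean(ws <= w_obs)
    p_ge = np.mean(ws >= w_obs)
    return min(1.0, 2.0 * min(p_le, p_ge))


# --- Kruskal-Wallis: direct rank-sum formula --------------------------------

def kruskal_wallis_formula(groups):
    """H statistic (tie-corrected) and chi-square p from the textbook formula."""
    groups = [np.asarray(g, float) for g in groups]
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = rankdata(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + g.size]
        h += r.sum() ** 2 / g.size
        start += g.size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts ** 3 - counts) / (n ** 3 - n)
    if tie > 0:
        h /= tie
    p = chi2.sf(h, len(groups) - 1)
    return h, p


# --- Friedman: direct within-row rank formula -------------------------------

def friedman_formula(matrix):
    """Friedman chi-square (tie-corrected) and p from the direct formula."""
    m = np.asarray(matrix, float)
    n, k = m.shape
    ranks = np.apply_along_axis(rankdata, 1, m)
    col_sums = ranks.sum(axis=0)
    q = 12.0 / (n * k * (k + 1)) * np.sum(col_sums ** 2) - 3 * n * (k + 1)
    # tie correction across rows
    ties = 0.0
    for row in m:
        _, counts = np.unique(row, return_counts=True)
        ties += np.sum(counts ** 3 - counts)
    c = 1.0 - ties / (n * k * (k ** 2 - 1))
    if c > 0:
        q /= c
    return q, chi2.sf(q, k - 1)


# --- Youden cutoff: exhaustive threshold scan -------------------------------

def youden_scan(values, labels):
    """Best Youden index and mean-of-best cutoffs by scanning all midpoints.

    Direction follows the class medians: the positive class is called below
    the cutoff when its median is lower.
    """
    values = np.asarray(values, float)
    labels = np.asarray(labels, bool)
    pos, neg = values[labels], values[~labels]
    below = np.median(pos) < np.median(neg)
    uniq = np.unique(values)
    cands = uniq if uniq.size == 1 else (uniq[:-1] + uniq[1:]) / 2
    best_j, best_cuts = -np.inf, []
    for c in cands:
        if below:
            sens, spec = np.mean(pos < c), np.mean(neg >= c)
        else:
            sens, spec = np.mean(pos > c), np.mean(neg <= c)
        j = sens + spec - 1
        if j > best_j:
            best_j, best_cuts = j, [c]
        elif j == best_j:
            best_cuts.append(c)
    cut = float(np.mean(best_cuts))
    # the rule reports sensitivity/specificity re-evaluated at the final
    # (mean) cutoff, so the reported Youden index may fall below the maximum
    if below:
        sens, spec = np.mean(pos < cut), np.mean(neg >= cut)
    else:
        sens, spec = np.mean(pos > cut), np.mean(neg <= cut)
    return cut, 100 * sens, 100 * spec, float(sens + spec - 1)


# --- moving median: per-index sorted window ---------------------------------

def naive_moving_median(x, w):
    """Centred moving median with partial windows at the edges (odd w)."""
    x = np.asarray(x, float)
    h = w // 2
    return np.array([np.median(np.sort(x[max(0, i - h):i + h + 1]))
                     for i in range(x.size)])


# --- spectral band power: direct full-length periodogram --------------------

def periodogram_band_powers(x, fs, edges):
    """Integrated band powers from a single full-length periodogram."""
    x = np.asarray(x, float)
    n = x.size
    spec = np.abs(np.fft.rfft(x - x.mean())) ** 2 / n ** 2
    spec[1:-1] *= 2
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return np.array([spec[(freqs >= lo) & (freqs < hi)].sum()
                     for lo, hi in zip(edges[:-1], edges[1:])])
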