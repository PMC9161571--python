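"""Independent brute-force reference implementations used only by tests.

Everything here is written as plainly as possible — explicit Python
loops, textbook formulas — and shares no code with the package, so that
agreement between the two is meaningful evidence of correctness.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# --------------------------------------------------------------------------
# GLCM and Haralick features
# --------------------------------------------------------------------------

def glcm_bruteforce(quantized, mask, direction, n_levels, distance=1):
    """Symmetric normalized co-occurrence matrix by explicit voxel loops."""
    quantized = np.asarray(quantized)
    mask = np.asarray(mask).astype(bool)
    off = tuple(distance * d for d in direction)
    counts = np.zeros((n_levels, n_levels), dtype=float)
    nz, ny, nx = quantized.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not mask[z, y, x]:
                    continue
                z2, y2, x2 = z + off[0], y + off[1], x + off[2]
                if not (0 <= z2 < nz and 0 <= y2 < ny and 0 <= x2 < nx):
                    continue
                if not mask[z2, y2, x2]:
                    continue
                i = quantized[z, y, x] - 1
                j = quantized[z2, y2, x2] - 1
                counts[i, j] += 1
                counts[j, i] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("no pairs")
    return counts / total


def _log2(x):
    return math.log(x, 2)


def haralick_bruteforce(p):
    """The 13 Haralick statistics by direct double loops (base-2 logs)."""
    p = np.asarray(p, dtype=float)
    g = p.shape[0]
    px = [sum(p[i][j] for j in range(g)) for i in range(g)]
    py = [sum(p[i][j] for i in range(g)) for j in range(g)]
    mu_x = sum((i + 1) * px[i] for i in range(g))
    mu_y = sum((j + 1) * py[j] for j in range(g))
    var_x = sum((i + 1 - mu_x) ** 2 * px[i] for i in range(g))
    var_y = sum((j + 1 - mu_y) ** 2 * py[j] for j in range(g))

    out = {}
    out["energy"] = sum(p[i][j] ** 2 for i in range(g) for j in range(g))
    out["contrast"] = sum((i - j) ** 2 * p[i][j] for i in range(g) for j in range(g))
    if var_x > 0 and var_y > 0:
        num = sum((i + 1) * (j + 1) * p[i][j] for i in range(g) for j in range(g))
        out["correlation"] = (num - mu_x * mu_y) / math.sqrt(var_x * var_y)
    else:
        out["correlation"] = 0.0
    out["variance"] = var_x
    out["idm"] = sum(p[i][j] / (1 + (i - j) ** 2) for i in range(g) for j in range(g))

    p_sum = {k: 0.0 for k in range(2, 2 * g + 1)}
    p_diff = {k: 0.0 for k in range(0, g)}
    for i in range(g):
        for j in range(g):
            p_sum[i + j + 2] += p[i][j]
            p_diff[abs(i - j)] += p[i][j]
    sa = sum(k * v for k, v in p_sum.items())
    out["sum_average"] = sa
    out["sum_variance"] = sum((k - sa) ** 2 * v for k, v in p_sum.items())
    out["sum_entropy"] = -sum(v * _log2(v) for v in p_sum.values() if v > 0)
    hxy = -sum(
        p[i][j] * _log2(p[i][j]) for i in range(g) for j in range(g) if p[i][j] > 0
    )
    out["entropy"] = hxy
    mu_d = sum(k * v for k, v in p_diff.items())
    out["difference_variance"] = sum((k - mu_d) ** 2 * v for k, v in p_diff.items())
    out["difference_entropy"] = -sum(v * _log2(v) for v in p_diff.values() if v > 0)

    hxy1 = -sum(
        p[i][j] * _log2(px[i] * py[j])
        for i in range(g)
        for j in range(g)
        if p[i][j] > 0 and px[i] * py[j] > 0
    )
    hxy2 = -sum(
        px[i] * py[j] * _log2(px[i] * py[j])
        for i in range(g)
        for j in range(g)
        if px[i] * py[j] > 0
    )
    hx = -sum(v * _log2(v) for v in px if v > 0)
    hy = -sum(v * _log2(v) for v in py if v > 0)
    denom = max(hx, hy)
    out["imc1"] = (hxy - hxy1) / denom if denom > 0 else 0.0
    out["imc2"] = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))
    return out


# --------------------------------------------------------------------------
# Mann-Whitney by exhaustive enumeration
# --------------------------------------------------------------------------

def _u_statistic(a, b):
    """U for group a with 1/2 credit for ties."""
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def mannwhitney_exact(a, b, alternative="two-sided"):
    """(U, p) by enumerating every assignment of the pooled sample."""
    a, b = list(a), list(b)
    pooled = a + b
    n_a = len(a)
    u_obs = _u_statistic(a, b)
    idx = range(len(pooled))
    us = []
    for combo in itertools.combinations(idx, n_a):
        ga = [pooled[i] for i in combo]
        gb = [pooled[i] for i in idx if i not in combo]
        us.append(_u_statistic(ga, gb))
    us = np.array(us)
    eps = 1e-12
    p_greater = float(np.mean(us >= u_obs - eps))
    p_less = float(np.mean(us <= u_obs + eps))
    if alternative == "greater":
        p = p_greater
    elif alternative == "less":
        p = p_less
    else:
        p = min(1.0, 2.0 * min(p_greater, p_less))
    return u_obs, p


# --------------------------------------------------------------------------
# Log-rank by the textbook O-E table
# --------------------------------------------------------------------------

def logrank_bruteforce(times, events, group):
    """Two-group log-rank chi-square from the per-event-time 2x2 tables."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    group = np.asarray(group)
    labels = np.unique(group)
    g1 = group == labels[0]
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = (events & (times == t)).sum()
        d1 = (events & (times == t) & g1).sum()
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


# --------------------------------------------------------------------------
# Pearson chi-square by the definition
# --------------------------------------------------------------------------

def chi2_bruteforce(table):
    table = np.asarray(table, dtype=float)
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    total = table.sum()
    chi2 = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            expected = row[i] * col[j] / total
            chi2 += (table[i, j] - expected) ** 2 / expected
    return chi2
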