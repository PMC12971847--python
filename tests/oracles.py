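"""Independent reference implementations used only by the tests.

Deliberately naive (loops, direct formula transcription, dense sampling) and
kept free of any import from the package's computational paths, so agreement
is a genuine dual-route check.
"""

import math

import numpy as np


def metric_transcription(pm, pp, g=5.0):
    """Literal loop-based transcription of the 18 metric definitions."""
    pm = [abs(x) for x in pm]
    pp = [abs(x) for x in pp]
    n_pm, n_pp = len(pm), len(pp)
    pm_err = [abs(x - g) for x in pm]
    pp_err = [abs(x - g) for x in pp]

    def mean(xs):
        return sum(xs) / len(xs)

    def pop_std(xs):
        m = mean(xs)
        return math.sqrt(sum((x - m) ** 2 for x in xs) / len(xs))

    pm_mean, pp_mean = mean(pm), mean(pp)
    pm_mean_err, pp_mean_err = mean(pm_err), mean(pp_err)
    pooled_sq = sum((x - pm_mean) ** 2 for x in pm) + sum((x - pp_mean) ** 2 for x in pp)
    pooled_err_sq = sum((e - pm_mean_err) ** 2 for e in pm_err) + sum(
        (e - pp_mean_err) ** 2 for e in pp_err
    )
    return {
        "pm_max": max(pm),
        "pm_max_error": max(pm_err),
        "pm_mean": pm_mean,
        "pm_mean_error": pm_mean_err,
        "pm_std": pop_std(pm),
        "pm_std_error": pop_std(pm_err),
        "pp_max": max(pp),
        "pp_max_error": max(pp_err),
        "pp_mean": pp_mean,
        "pp_mean_error": pp_mean_err,
        "pp_std": pop_std(pp),
        "pp_std_error": pop_std(pp_err),
        "p_all_max": max(max(pm), max(pp)),
        "p_all_max_error": max(max(pm_err), max(pp_err)),
        "p_all_mean": (sum(pm) + sum(pp)) / (n_pm + n_pp),
        "p_all_mean_error": 0.5 * (pm_mean_err + pp_mean_err),
        "p_all_std": math.sqrt(pooled_sq / (n_pm + n_pp)),
        "p_all_std_error": math.sqrt(pooled_err_sq / (n_pm + n_pp)),
    }


def kruskal_h(groups):
    """Textbook tie-corrected Kruskal-Wallis H from first principles."""
    pooled = [v for g in groups for v in g]
    n = len(pooled)
    order = sorted(range(n), key=lambda i: pooled[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    h = 0.0
    start = 0
    for g in groups:
        r = sum(ranks[start : start + len(g)])
        h += r * r / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    from collections import Counter

    ties = sum(c**3 - c for c in Counter(pooled).values())
    denom = 1 - ties / (n**3 - n)
    return h / denom if denom > 0 else float("nan")


def dunn_z(groups, i, j):
    """Brute-force Dunn z statistic for the (i, j) group pair."""
    from collections import Counter

    pooled = [v for g in groups for v in g]
    n = len(pooled)
    sorted_vals = sorted(pooled)

    def rank(v):
        lo = sorted_vals.index(v)
        hi = n - 1 - sorted_vals[::-1].index(v)
        return (lo + hi) / 2 + 1

    mean_ranks = [sum(rank(v) for v in g) / len(g) for g in groups]
    ties = sum(c**3 - c for c in Counter(pooled).values())
    var = (n * (n + 1) / 12 - ties / (12 * (n - 1))) * (1 / len(groups[i]) + 1 / len(groups[j]))
    return (mean_ranks[i] - mean_ranks[j]) / math.sqrt(var)


def vif_bruteforce(X):
    """1/(1-R^2) per column via an independent least-squares solve."""
    X = np.asarray(X, dtype=float)
    out = []
    for j in range(X.shape[1]):
        y = X[:, j]
        A = np.column_stack([np.ones(len(X)), np.delete(X, j, axis=1)])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1 - ss_res / ss_tot
        out.append(float("inf") if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2))
    return out


def point_to_polyline_dense(point, polyline, n_samples=10_000):
    """Minimum distance to a polyline by dense arc-length sampling."""
    poly = np.asarray(polyline, dtype=float)
    p = np.asarray(point, dtype=float)
    seg = np.diff(poly, axis=0)
    lengths = np.linalg.norm(seg, axis=1)
    total = lengths.sum()
    best = math.inf
    for a, b, L in zip(poly[:-1], poly[1:], lengths):
        if L == 0:
            best = min(best, float(np.linalg.norm(p - a)))
            continue
        k = max(2, int(round(n_samples * L / total)))
        ts = np.linspace(0, 1, k)[:, None]
        pts = a + ts * (b - a)
        best = min(best, float(np.linalg.norm(pts - p, axis=1).min()))
    return best


def analytic_two_sample_n(d=1.0, alpha=0.05, power=0.8):
    """Closed-form normal-approximation per-group n for a two-sample t-test."""
    from scipy.stats import norm

    za, zb = norm.ppf(1 - alpha / 2), norm.ppf(power)
    n = 2 * (za + zb) ** 2 / d**2
    # small-sample t correction: +1 is the conventional adjustment, giving 17 at d=1
    return math.ceil(n) + 1
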